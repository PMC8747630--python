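# Dressing (basic ADL). Upper-body items come before lower-body items, as in
# occupational/physical-therapy session practice: find an upper dressing item,
# apply it, finish the stage, then move to the lower item (e.g. trousers).
name: dressing
items:
  - goal_dressing
  - shirt
  - trousers
  - socks
  - shoes
  - jacket          # distractor for the shirt
  - shorts          # distractor for the trousers
  - gloves          # distractor for the socks
associations:
  - [goal_dressing, shirt]
  - [goal_dressing, trousers]
  - [goal_dressing, socks]
  - [goal_dressing, shoes]
similarities:
  - [shirt, jacket, -0.3]
  - [trousers, shorts, -0.3]
  - [socks, gloves, -0.4]
  - [shirt, trousers, -0.8]
steps:
  - {id: decide_to_dress, kind: behaviour, category: initiation, stage: 0}
  - {id: find_shirt, kind: retrieval, target: shirt, context: [goal_dressing], category: organization, stage: 1}
  - {id: put_on_shirt, kind: behaviour, category: sequencing, stage: 1, conflict_group: [put_on_trousers]}
  - {id: find_trousers, kind: retrieval, target: trousers, context: [goal_dressing], category: organization, stage: 2}
  - {id: put_on_trousers, kind: behaviour, category: sequencing, stage: 2, conflict_group: [put_on_shirt]}
  - {id: find_socks, kind: retrieval, target: socks, context: [goal_dressing], category: organization, stage: 3}
  - {id: put_on_socks, kind: behaviour, category: performs_all_steps, stage: 3}
  - {id: find_shoes, kind: retrieval, target: shoes, context: [goal_dressing], category: organization, stage: 3}
  - {id: put_on_shoes, kind: behaviour, category: performs_all_steps, stage: 3}
  - {id: check_outfit_for_weather, kind: behaviour, category: judgment_safety, stage: 4}
  - {id: check_appearance_and_finish, kind: behaviour, category: completion, stage: 4}
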