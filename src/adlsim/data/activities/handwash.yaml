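# Washing hands (basic ADL). Step structure follows the occupational-therapy
# task breakdown: approach the sink, gather soap and towel, wet hands, apply
# soap, scrub, rinse, turn the tap off, dry and finish.
name: handwash
items:
  - goal_handwash
  - soap
  - towel
  - shampoo         # distractor for the soap
  - washcloth       # distractor for the towel
associations:
  - [goal_handwash, soap]
  - [goal_handwash, towel]
similarities:
  - [soap, shampoo, -0.3]
  - [towel, washcloth, -0.3]
  - [soap, towel, -0.8]
steps:
  - {id: approach_sink, kind: behaviour, category: initiation, stage: 0}
  - {id: find_soap, kind: retrieval, target: soap, context: [goal_handwash], category: organization, stage: 1}
  - {id: find_towel, kind: retrieval, target: towel, context: [goal_handwash], category: organization, stage: 1}
  - {id: turn_on_tap, kind: behaviour, category: performs_all_steps, stage: 2}
  - {id: wet_hands, kind: behaviour, category: sequencing, stage: 2, conflict_group: [apply_soap]}
  - {id: apply_soap, kind: behaviour, category: sequencing, stage: 2, conflict_group: [wet_hands]}
  - {id: scrub_hands, kind: behaviour, category: performs_all_steps, stage: 3}
  - {id: rinse_hands, kind: behaviour, category: performs_all_steps, stage: 3}
  - {id: turn_off_tap, kind: behaviour, category: judgment_safety, stage: 4, safety_critical: true}
  - {id: dry_hands_and_finish, kind: behaviour, category: completion, stage: 4}
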