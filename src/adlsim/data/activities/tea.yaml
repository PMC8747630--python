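# Tea preparation (IADL, kitchen task). Step structure follows the ordinary
# recipe on a commercial tea package: gather the utensils and ingredients,
# boil the water, combine, let the tea rest 3-4 minutes, serve.
name: tea
items:
  - goal_tea        # the activity goal chunk; context source for retrievals
  - kettle
  - mug
  - teabag
  - water
  - spoon
  - sugar           # distractor: "confuses the teabag with something else"
  - glass           # distractor for the mug
associations:
  - [goal_tea, kettle]
  - [goal_tea, mug]
  - [goal_tea, teabag]
  - [goal_tea, water]
  - [goal_tea, spoon]
similarities:
  - [teabag, water, -0.3]    # the designated similar-item confusion
  - [mug, kettle, -0.3]      # kettle and mug are very similar in this model
  - [teabag, sugar, -0.7]
  - [mug, glass, -0.6]
  - [spoon, sugar, -0.7]
steps:
  - {id: start_tea_preparation, kind: behaviour, category: initiation, stage: 0}
  - {id: find_kettle, kind: retrieval, target: kettle, context: [goal_tea], category: organization, stage: 1}
  - {id: find_mug, kind: retrieval, target: mug, context: [goal_tea], category: organization, stage: 1}
  - {id: find_teabag, kind: retrieval, target: teabag, context: [goal_tea], category: organization, stage: 1}
  - {id: find_spoon, kind: retrieval, target: spoon, context: [goal_tea], category: organization, stage: 1}
  - {id: fill_kettle_with_water, kind: behaviour, category: performs_all_steps, stage: 2}
  - {id: boil_water, kind: behaviour, category: performs_all_steps, stage: 2}
  - {id: put_teabag_in_mug, kind: behaviour, category: sequencing, stage: 3, conflict_group: [pour_water_into_mug]}
  - {id: pour_water_into_mug, kind: behaviour, category: sequencing, stage: 3, conflict_group: [put_teabag_in_mug]}
  - {id: turn_off_kettle, kind: behaviour, category: judgment_safety, stage: 3, safety_critical: true}
  - {id: let_tea_rest_3_4_min, kind: behaviour, category: completion, stage: 4}
  - {id: finish_and_serve, kind: behaviour, category: completion, stage: 4}
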