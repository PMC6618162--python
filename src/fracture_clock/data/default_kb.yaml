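version: default-2017.1
horizon_hours: 2208.0
category_probabilities:
  none: 0.02
  minority: 0.3
  majority: 0.8
  all: 0.98
bins:
- - 0.0
  - 1.0
- - 1.0
  - 2.0
- - 2.0
  - 12.0
- - 12.0
  - 18.0
- - 18.0
  - 24.0
- - 24.0
  - 36.0
- - 36.0
  - 48.0
- - 48.0
  - 72.0
- - 72.0
  - 96.0
- - 96.0
  - 120.0
- - 120.0
  - 168.0
- - 168.0
  - 192.0
- - 192.0
  - 336.0
- - 336.0
  - 360.0
- - 360.0
  - 504.0
- - 504.0
  - 528.0
- - 528.0
  - 672.0
- - 672.0
  - 864.0
- - 864.0
  - 2208.0
features:
- feature_id: haemorrhage
  t_first: 0.0
  t_all_on: null
  t_all_off: null
  t_last: null
  constraint_grade: constraint
  antemortem_marker: true
  inferred_defaults:
  - prevalence_profile
  prevalence_profile:
  - - 0.0
    - majority
  - - 336.0
    - minority
  context_overrides: {}
- feature_id: fibrin
  t_first: 2.0
  t_all_on: 12.0
  t_all_off: 72.0
  t_last: 168.0
  constraint_grade: constraint
  antemortem_marker: false
  inferred_defaults:
  - t_first
  - t_all_off
  - t_last
  prevalence_profile: null
  context_overrides: {}
- feature_id: polymorph_infiltrate
  t_first: 12.0
  t_all_on: 18.0
  t_all_off: 48.0
  t_last: 96.0
  constraint_grade: constraint
  antemortem_marker: false
  inferred_defaults:
  - t_first
  - t_all_off
  - t_last
  prevalence_profile: null
  context_overrides: {}
- feature_id: macrophage_infiltrate
  t_first: 72.0
  t_all_on: null
  t_all_off: null
  t_last: null
  constraint_grade: advisory
  antemortem_marker: false
  inferred_defaults:
  - t_first
  prevalence_profile: null
  context_overrides: {}
- feature_id: granulation_tissue
  t_first: 72.0
  t_all_on: 120.0
  t_all_off: null
  t_last: null
  constraint_grade: constraint
  antemortem_marker: false
  inferred_defaults:
  - t_first
  - t_all_on
  prevalence_profile: null
  context_overrides: {}
- feature_id: osteocyte_loss
  t_first: 1.0
  t_all_on: 168.0
  t_all_off: null
  t_last: null
  constraint_grade: constraint
  antemortem_marker: true
  inferred_defaults:
  - t_all_on
  prevalence_profile: null
  context_overrides: {}
- feature_id: osteoclasis
  t_first: 72.0
  t_all_on: 72.0
  t_all_off: 168.0
  t_last: null
  constraint_grade: constraint
  antemortem_marker: false
  inferred_defaults: []
  prevalence_profile: null
  context_overrides:
    metaphyseal:
      t_first: 24.0
      t_all_on: 36.0
- feature_id: mesenchymal_condensation
  t_first: 72.0
  t_all_on: 120.0
  t_all_off: null
  t_last: null
  constraint_grade: constraint
  antemortem_marker: false
  inferred_defaults:
  - t_first
  - t_all_on
  prevalence_profile: null
  context_overrides: {}
- feature_id: woven_osteoid
  t_first: 96.0
  t_all_on: 120.0
  t_all_off: 2208.0
  t_last: null
  constraint_grade: constraint
  antemortem_marker: false
  inferred_defaults:
  - t_first
  - t_all_off
  prevalence_profile: null
  context_overrides: {}
- feature_id: trabeculae_cartilage
  t_first: 192.0
  t_all_on: 336.0
  t_all_off: null
  t_last: null
  constraint_grade: constraint
  antemortem_marker: false
  inferred_defaults: []
  prevalence_profile: null
  context_overrides: {}
- feature_id: calcification
  t_first: 360.0
  t_all_on: 672.0
  t_all_off: null
  t_last: null
  constraint_grade: constraint
  antemortem_marker: false
  inferred_defaults: []
  prevalence_profile:
  - - 0.0
    - none
  - - 360.0
    - majority
  - - 528.0
    - all
  context_overrides: {}
- feature_id: fracture_union
  t_first: 504.0
  t_all_on: 672.0
  t_all_off: null
  t_last: null
  constraint_grade: constraint
  antemortem_marker: false
  inferred_defaults:
  - t_first
  prevalence_profile: null
  context_overrides: {}
- feature_id: lamellar_bone
  t_first: 672.0
  t_all_on: 864.0
  t_all_off: null
  t_last: null
  constraint_grade: constraint
  antemortem_marker: false
  inferred_defaults: []
  prevalence_profile: null
  context_overrides: {}
- feature_id: restoration
  t_first: 2208.0
  t_all_on: 2208.0
  t_all_off: null
  t_last: null
  constraint_grade: constraint
  antemortem_marker: false
  inferred_defaults: []
  prevalence_profile: null
  context_overrides: {}
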