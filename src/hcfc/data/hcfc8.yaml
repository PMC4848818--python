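name: HCFC-8
n_categories: 5
factors:
- name: psychological_functioning
  label: Psychological functioning
  marker: self_esteem
  items:
  - name: self_esteem
    label: Self-esteem
    reversed: false
  - name: body_image
    label: Body image
    reversed: false
  - name: negative_affects
    label: Negative affects
    reversed: true
- name: physical_functioning
  label: Physical functioning
  marker: health_got_worse
  items:
  - name: feeling_tired
    label: Feeling tired all the time
    reversed: true
  - name: health_got_worse
    label: Health got worse
    reversed: true
- name: self_efficacy_health_services
  label: Self-efficacy towards health services
  marker: confidence_who_to_contact
  items:
  - name: confidence_who_to_contact
    label: Confidence to know who to contact
    reversed: false
  - name: ability_get_information
    label: Ability to get information
    reversed: false
- name: lifestyle_value
  label: Lifestyle value
  marker: want_to_care
  items:
  - name: want_to_care
    label: Want to care
    reversed: false
  - name: enjoy_caring
    label: Enjoy caring
    reversed: false
  - name: caring_feels_good
    label: Caring makes one feel good
    reversed: false
- name: family_support
  label: Family support
  marker: difficulty_getting_help
  items:
  - name: difficulty_getting_help
    label: Difficulty getting help
    reversed: true
  - name: feeling_abandoned
    label: Feeling abandoned by the family
    reversed: true
  - name: family_works_together
    label: Family works together
    reversed: false
- name: social_capital
  label: Social capital
  marker: personal_relationships
  items:
  - name: personal_relationships
    label: Personal relationships
    reversed: false
  - name: sexual_activity
    label: Sexual activity
    reversed: false
  - name: social_support
    label: Social support
    reversed: false
- name: material_conditions_security
  label: Material conditions / security
  marker: financial_resources
  items:
  - name: financial_resources
    label: Financial resources
    reversed: false
  - name: safety_security
    label: Freedom and physical safety and security
    reversed: false
- name: health_services_interactions
  label: Quality of information and healthcare services
  marker: help_received
  items:
  - name: help_received
    label: Help received
    reversed: false
  - name: information_availability
    label: Availability of information
    reversed: false
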