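# Default two-level variable system for evaluating medical and older-adult
# care integration policies. 10 primary dimensions, 39 binary secondary
# indicators; X10 (policy disclosure) is an indicator-only flag with no
# secondaries and is excluded from the index sum.
primaries:
  - id: X1
    label: Policy nature
    secondaries:
      - {id: "X1:1", label: Forecast, criterion: "1 if the policy involves forecast content, 0 if not"}
      - {id: "X1:2", label: Supervision, criterion: "1 if the policy involves supervisory content, 0 if not"}
      - {id: "X1:3", label: Recommendation, criterion: "1 if the policy involves recommended content, 0 if not"}
      - {id: "X1:4", label: Support, criterion: "1 if the policy involves support measures, 0 if not"}
      - {id: "X1:5", label: Guide, criterion: "1 if the policy involves guiding content, 0 if not"}
      - {id: "X1:6", label: Description, criterion: "1 if the policy involves descriptive content, 0 if not"}
  - id: X2
    label: Policy effectiveness
    secondaries:
      - {id: "X2:1", label: Long-term, criterion: "1 if in force more than 5 years, 0 otherwise"}
      - {id: "X2:2", label: Mid-term, criterion: "1 if in force 3 to 5 years, 0 otherwise"}
      - {id: "X2:3", label: Short-term, criterion: "1 if in force less than 3 years, 0 otherwise"}
  - id: X3
    label: Issuing agency
    secondaries:
      - {id: "X3:1", label: State Council and constituent departments, criterion: "1 if issued by the State Council or its constituent departments, 0 otherwise"}
      - {id: "X3:2", label: National Health Commission, criterion: "1 if issued by the National Health Commission, 0 otherwise"}
      - {id: "X3:3", label: Other agencies or departments, criterion: "1 if issued by other agencies or departments, 0 otherwise"}
  - id: X4
    label: Policy instruments
    secondaries:
      - {id: "X4:1", label: Supply-driven, criterion: "1 if the policy uses supply-side tools, 0 otherwise"}
      - {id: "X4:2", label: Environmental, criterion: "1 if the policy uses environmental tools such as planning, 0 otherwise"}
      - {id: "X4:3", label: Demand-driven, criterion: "1 if the policy uses demand-side tools such as guidance, 0 otherwise"}
  - id: X5
    label: Policy content
    secondaries:
      - {id: "X5:1", label: Platform development, criterion: "1 if the policy involves platform development, 0 otherwise"}
      - {id: "X5:2", label: Talent development, criterion: "1 if the policy involves talent development, 0 otherwise"}
      - {id: "X5:3", label: Improved systems, criterion: "1 if the policy involves improved systems, 0 otherwise"}
      - {id: "X5:4", label: Service supervision, criterion: "1 if the policy involves service supervision, 0 otherwise"}
      - {id: "X5:5", label: Safeguards, criterion: "1 if the policy involves safeguards, 0 otherwise"}
  - id: X6
    label: Policy target
    secondaries:
      - {id: "X6:1", label: Administrative departments, criterion: "1 if the policy targets administrative departments, 0 otherwise"}
      - {id: "X6:2", label: Medical institutions, criterion: "1 if the policy targets medical institutions, 0 otherwise"}
      - {id: "X6:3", label: Older-adult care facilities, criterion: "1 if the policy targets older-adult care facilities, 0 otherwise"}
      - {id: "X6:4", label: Social organizations, criterion: "1 if the policy targets social organizations, 0 otherwise"}
      - {id: "X6:5", label: Health industry, criterion: "1 if the policy targets the health industry, 0 otherwise"}
  - id: X7
    label: Policy evaluation
    secondaries:
      - {id: "X7:1", label: Well-founded, criterion: "1 if the policy is well-founded, 0 otherwise"}
      - {id: "X7:2", label: Clear objective, criterion: "1 if the policy has clear objectives, 0 otherwise"}
      - {id: "X7:3", label: Detailed planning, criterion: "1 if the policy has detailed planning, 0 otherwise"}
      - {id: "X7:4", label: Scientific approach, criterion: "1 if the policy takes a scientific approach, 0 otherwise"}
  - id: X8
    label: Policy objectives
    secondaries:
      - {id: "X8:1", label: Promoting industrial development, criterion: "1 if the policy promotes industrial development, 0 otherwise"}
      - {id: "X8:2", label: Improving care quality, criterion: "1 if the policy improves the quality of older-adult medical and nursing care, 0 otherwise"}
      - {id: "X8:3", label: Improving medical standards, criterion: "1 if the policy improves medical standards, 0 otherwise"}
      - {id: "X8:4", label: Promoting policy coordination, criterion: "1 if the policy promotes policy coordination, 0 otherwise"}
      - {id: "X8:5", label: Meeting care needs, criterion: "1 if the policy meets medical and nursing care needs, 0 otherwise"}
  - id: X9
    label: Policy guarantees
    secondaries:
      - {id: "X9:1", label: Policy guarantees, criterion: "1 if the policy involves policy guarantees, 0 otherwise"}
      - {id: "X9:2", label: Talent cultivation, criterion: "1 if the policy involves talent cultivation, 0 otherwise"}
      - {id: "X9:3", label: Financial support, criterion: "1 if the policy involves financial support, 0 otherwise"}
      - {id: "X9:4", label: Departmental collaboration, criterion: "1 if the policy involves departmental collaboration, 0 otherwise"}
      - {id: "X9:5", label: Supervision and evaluation, criterion: "1 if the policy involves supervision and evaluation, 0 otherwise"}
  - id: X10
    label: Policy disclosure
    indicator_only: true
    secondaries: []
scored_ids: [X1, X2, X3, X4, X5, X6, X7, X8, X9]
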