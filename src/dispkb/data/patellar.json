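{
  "axioms": [
    {
      "bearer_type": "Patient",
      "comment": "knee-jerk reflex; triggerable repeatedly, one jerk per tap",
      "disposition_type": "PatellarReflexDisposition",
      "realization_types": [
        "KneeJerk"
      ],
      "surefire": true,
      "trigger_types": [
        "PatellarTap"
      ]
    }
  ],
  "facts": [
    {
      "object": "jerk1",
      "relation": "has_realization",
      "subject": "reflex1"
    },
    {
      "object": "jerk2",
      "relation": "has_realization",
      "subject": "reflex1"
    },
    {
      "object": "tap1",
      "relation": "has_trigger_R",
      "subject": "jerk1"
    },
    {
      "object": "tap2",
      "relation": "has_trigger_R",
      "subject": "jerk2"
    },
    {
      "object": "patient1",
      "relation": "inheres_in",
      "subject": "reflex1"
    }
  ],
  "format_version": "1.0",
  "instances": [
    {
      "name": "jerk1",
      "types": [
        "KneeJerk"
      ]
    },
    {
      "name": "jerk2",
      "types": [
        "KneeJerk"
      ]
    },
    {
      "name": "patient1",
      "types": [
        "Patient"
      ]
    },
    {
      "name": "reflex1",
      "types": [
        "PatellarReflexDisposition"
      ]
    },
    {
      "name": "tap1",
      "types": [
        "PatellarTap"
      ]
    },
    {
      "name": "tap2",
      "types": [
        "PatellarTap"
      ]
    }
  ],
  "types": [
    {
      "kind": "process",
      "name": "KneeJerk",
      "parents": []
    },
    {
      "kind": "disposition",
      "name": "PatellarReflexDisposition",
      "parents": []
    },
    {
      "kind": "process",
      "name": "PatellarTap",
      "parents": []
    },
    {
      "kind": "material_entity",
      "name": "Patient",
      "parents": []
    }
  ]
}
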