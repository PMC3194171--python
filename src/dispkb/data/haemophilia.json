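{
  "axioms": [
    {
      "bearer_type": "Patient",
      "comment": "tendency to bleed on lesion without proper coagulation",
      "disposition_type": "Haemophilia",
      "realization_types": [
        "Bleeding"
      ],
      "surefire": true,
      "trigger_types": [
        "Lesion"
      ]
    }
  ],
  "facts": [
    {
      "object": "patient1",
      "relation": "inheres_in",
      "subject": "h_disp"
    }
  ],
  "format_version": "1.0",
  "instances": [
    {
      "name": "h_disp",
      "types": [
        "Haemophilia"
      ]
    },
    {
      "name": "lesion1",
      "types": [
        "Lesion"
      ]
    },
    {
      "name": "patient1",
      "types": [
        "Patient"
      ]
    }
  ],
  "types": [
    {
      "kind": "process",
      "name": "Bleeding",
      "parents": []
    },
    {
      "kind": "disposition",
      "name": "Haemophilia",
      "parents": []
    },
    {
      "kind": "process",
      "name": "Lesion",
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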