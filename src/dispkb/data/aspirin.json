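{
  "axioms": [
    {
      "bearer_type": "Tablet",
      "comment": "pain relief is essential to aspirin; bearers of the same disposition type may be tablets of different types",
      "disposition_type": "PainReliefDisposition",
      "essential_of": "Aspirin",
      "realization_types": [
        "PainRelief"
      ],
      "surefire": true,
      "trigger_types": [
        "Ingestion"
      ]
    }
  ],
  "facts": [
    {
      "object": "para1",
      "relation": "inheres_in",
      "subject": "pr1"
    }
  ],
  "format_version": "1.0",
  "instances": [
    {
      "name": "asp1",
      "types": [
        "Aspirin"
      ]
    },
    {
      "name": "para1",
      "types": [
        "Paracetamol"
      ]
    },
    {
      "name": "pr1",
      "types": [
        "PainReliefDisposition"
      ]
    }
  ],
  "types": [
    {
      "kind": "material_entity",
      "name": "Aspirin",
      "parents": [
        "Tablet"
      ]
    },
    {
      "kind": "process",
      "name": "Ingestion",
      "parents": []
    },
    {
      "kind": "process",
      "name": "PainRelief",
      "parents": []
    },
    {
      "kind": "disposition",
      "name": "PainReliefDisposition",
      "parents": []
    },
    {
      "kind": "material_entity",
      "name": "Paracetamol",
      "parents": [
        "Tablet"
      ]
    },
    {
      "kind": "material_entity",
      "name": "Tablet",
      "parents": []
    }
  ]
}
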