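{
  "axioms": [
    {
      "base_type": "NaClStructure",
      "bearer_type": "Salt",
      "comment": "solubility grounded in the NaCl molecular structure; base brings the disposition, immersion realizes it",
      "disposition_type": "WaterSolubility",
      "realization_types": [
        "Dissolution"
      ],
      "surefire": true,
      "trigger_types": [
        "Immersion"
      ]
    }
  ],
  "facts": [
    {
      "object": "salt1",
      "relation": "inheres_in",
      "subject": "q1"
    }
  ],
  "format_version": "1.0",
  "instances": [
    {
      "name": "imm1",
      "types": [
        "Immersion"
      ]
    },
    {
      "name": "q1",
      "types": [
        "NaClStructure"
      ]
    },
    {
      "name": "salt1",
      "types": [
        "Salt"
      ]
    }
  ],
  "types": [
    {
      "kind": "process",
      "name": "Dissolution",
      "parents": []
    },
    {
      "kind": "process",
      "name": "Immersion",
      "parents": []
    },
    {
      "kind": "quality",
      "name": "NaClStructure",
      "parents": []
    },
    {
      "kind": "material_entity",
      "name": "Salt",
      "parents": []
    },
    {
      "kind": "disposition",
      "name": "WaterSolubility",
      "parents": []
    }
  ]
}
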