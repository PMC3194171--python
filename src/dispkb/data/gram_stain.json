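{
  "axioms": [
    {
      "bearer_type": "GramPositiveSample",
      "comment": "a Gram-positive sample turns dark blue when Gram-stained",
      "disposition_type": "GramStainability",
      "realization_types": [
        "BlueStaining"
      ],
      "surefire": true,
      "trigger_types": [
        "GramStaining"
      ]
    }
  ],
  "facts": [
    {
      "object": "sample1",
      "relation": "inheres_in",
      "subject": "stain_disp"
    }
  ],
  "format_version": "1.0",
  "instances": [
    {
      "name": "sample1",
      "types": [
        "GramPositiveSample"
      ]
    },
    {
      "name": "stain_disp",
      "types": [
        "GramStainability"
      ]
    },
    {
      "name": "staining1",
      "types": [
        "GramStaining"
      ]
    }
  ],
  "types": [
    {
      "kind": "process",
      "name": "BlueStaining",
      "parents": []
    },
    {
      "kind": "material_entity",
      "name": "GramPositiveSample",
      "parents": []
    },
    {
      "kind": "disposition",
      "name": "GramStainability",
      "parents": []
    },
    {
      "kind": "process",
      "name": "GramStaining",
      "parents": []
    }
  ]
}
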