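{
  "axioms": [
    {
      "bearer_type": "Match",
      "comment": "a match inflames when struck",
      "disposition_type": "Inflammability",
      "realization_types": [
        "Inflammation"
      ],
      "surefire": true,
      "trigger_types": [
        "Striking"
      ]
    }
  ],
  "facts": [
    {
      "object": "match1",
      "relation": "inheres_in",
      "subject": "m_disp"
    }
  ],
  "format_version": "1.0",
  "instances": [
    {
      "name": "m_disp",
      "types": [
        "Inflammability"
      ]
    },
    {
      "name": "match1",
      "types": [
        "Match"
      ]
    },
    {
      "name": "strike1",
      "types": [
        "Striking"
      ]
    }
  ],
  "types": [
    {
      "kind": "disposition",
      "name": "Inflammability",
      "parents": []
    },
    {
      "kind": "process",
      "name": "Inflammation",
      "parents": []
    },
    {
      "kind": "material_entity",
      "name": "Match",
      "parents": []
    },
    {
      "kind": "process",
      "name": "Striking",
      "parents": []
    }
  ]
}
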