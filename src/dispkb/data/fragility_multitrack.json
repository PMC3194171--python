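{
  "axioms": [
    {
      "bearer_type": "Glass",
      "comment": "multi-track, multi-trigger: a fragile glass may break, crack or splinter when struck or thrown",
      "disposition_type": "Fragility",
      "realization_types": [
        "Breaking",
        "Cracking",
        "Splintering"
      ],
      "surefire": true,
      "trigger_types": [
        "Striking",
        "Throwing"
      ]
    }
  ],
  "facts": [
    {
      "object": "glass1",
      "relation": "inheres_in",
      "subject": "frag1"
    }
  ],
  "format_version": "1.0",
  "instances": [
    {
      "name": "frag1",
      "types": [
        "Fragility"
      ]
    },
    {
      "name": "glass1",
      "types": [
        "Glass"
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
      "kind": "process",
      "name": "Breaking",
      "parents": []
    },
    {
      "kind": "process",
      "name": "Cracking",
      "parents": []
    },
    {
      "kind": "disposition",
      "name": "Fragility",
      "parents": []
    },
    {
      "kind": "material_entity",
      "name": "Glass",
      "parents": []
    },
    {
      "kind": "process",
      "name": "Splintering",
      "parents": []
    },
    {
      "kind": "process",
      "name": "Striking",
      "parents": []
    },
    {
      "kind": "process",
      "name": "Throwing",
      "parents": []
    }
  ]
}
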