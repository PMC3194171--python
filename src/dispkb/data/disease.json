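{
  "axioms": [
    {
      "base_type": "PathogenColonization",
      "bearer_type": "Organism",
      "comment": "disorder (colonization quality) as base of the disease disposition, course of disease as realization; with no trigger instance the disease stays dormant",
      "disposition_type": "InfectiousDisease",
      "realization_types": [
        "DiseaseCourse"
      ],
      "surefire": true,
      "trigger_types": [
        "ImmuneChallenge"
      ]
    }
  ],
  "facts": [
    {
      "object": "host1",
      "relation": "inheres_in",
      "subject": "colonization1"
    }
  ],
  "format_version": "1.0",
  "instances": [
    {
      "name": "colonization1",
      "types": [
        "PathogenColonization"
      ]
    },
    {
      "name": "host1",
      "types": [
        "Organism"
      ]
    }
  ],
  "types": [
    {
      "kind": "process",
      "name": "DiseaseCourse",
      "parents": []
    },
    {
      "kind": "process",
      "name": "ImmuneChallenge",
      "parents": []
    },
    {
      "kind": "disposition",
      "name": "InfectiousDisease",
      "parents": []
    },
    {
      "kind": "material_entity",
      "name": "Organism",
      "parents": []
    },
    {
      "kind": "quality",
      "name": "PathogenColonization",
      "parents": []
    }
  ]
}
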