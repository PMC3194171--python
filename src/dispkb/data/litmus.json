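{
  "axioms": [
    {
      "bearer_type": "LitmusPaper",
      "comment": "two-track colour response: blue or red depending on the pH of the contacted solution",
      "disposition_type": "LitmusResponsiveness",
      "realization_types": [
        "BlueShift",
        "RedShift"
      ],
      "surefire": true,
      "trigger_types": [
        "SolutionContact"
      ]
    }
  ],
  "facts": [
    {
      "object": "blue1",
      "relation": "has_realization",
      "subject": "litmus_disp"
    },
    {
      "object": "red1",
      "relation": "has_realization",
      "subject": "litmus_disp"
    },
    {
      "object": "dip_base",
      "relation": "has_trigger_R",
      "subject": "blue1"
    },
    {
      "object": "dip_acid",
      "relation": "has_trigger_R",
      "subject": "red1"
    },
    {
      "object": "paper1",
      "relation": "inheres_in",
      "subject": "litmus_disp"
    }
  ],
  "format_version": "1.0",
  "instances": [
    {
      "name": "blue1",
      "types": [
        "BlueShift"
      ]
    },
    {
      "name": "dip_acid",
      "types": [
        "SolutionContact"
      ]
    },
    {
      "name": "dip_base",
      "types": [
        "SolutionContact"
      ]
    },
    {
      "name": "litmus_disp",
      "types": [
        "LitmusResponsiveness"
      ]
    },
    {
      "name": "paper1",
      "types": [
        "LitmusPaper"
      ]
    },
    {
      "name": "red1",
      "types": [
        "RedShift"
      ]
    }
  ],
  "types": [
    {
      "kind": "process",
      "name": "BlueShift",
      "parents": []
    },
    {
      "kind": "material_entity",
      "name": "LitmusPaper",
      "parents": []
    },
    {
      "kind": "disposition",
      "name": "LitmusResponsiveness",
      "parents": []
    },
    {
      "kind": "process",
      "name": "RedShift",
      "parents": []
    },
    {
      "kind": "process",
      "name": "SolutionContact",
      "parents": []
    }
  ]
}
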