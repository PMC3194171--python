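{
  "axioms": [
    {
      "bearer_type": "Patient",
      "comment": "hypersensitivity; the trigger is the exposure event between patient and allergen, not the substance",
      "disposition_type": "PenicillinAllergy",
      "realization_types": [
        "AllergicReaction"
      ],
      "surefire": true,
      "trigger_types": [
        "PenicillinExposure"
      ]
    }
  ],
  "facts": [
    {
      "object": "patient1",
      "relation": "inheres_in",
      "subject": "allergy1"
    }
  ],
  "format_version": "1.0",
  "instances": [
    {
      "name": "allergy1",
      "types": [
        "PenicillinAllergy"
      ]
    },
    {
      "name": "exposure1",
      "types": [
        "PenicillinExposure"
      ]
    },
    {
      "name": "patient1",
      "types": [
        "Patient"
      ]
    },
    {
      "name": "patient2",
      "types": [
        "Patient"
      ]
    }
  ],
  "types": [
    {
      "kind": "process",
      "name": "AllergicReaction",
      "parents": []
    },
    {
      "kind": "material_entity",
      "name": "Patient",
      "parents": []
    },
    {
      "kind": "disposition",
      "name": "PenicillinAllergy",
      "parents": []
    },
    {
      "kind": "process",
      "name": "PenicillinExposure",
      "parents": []
    }
  ]
}
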