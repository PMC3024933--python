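{
  "metabolites": [
    {
      "id": "glutamate",
      "name": "L-glutamate"
    },
    {
      "id": "oxoglutarate",
      "name": "2-oxoglutarate"
    },
    {
      "id": "pyruvate",
      "name": "pyruvate"
    },
    {
      "id": "alanine",
      "name": "L-alanine"
    },
    {
      "id": "leucine",
      "name": "L-leucine"
    },
    {
      "id": "methyloxopentanoate",
      "name": "4-methyl-2-oxo-pentanoate"
    },
    {
      "id": "valine",
      "name": "L-valine"
    },
    {
      "id": "methyloxobutanoate",
      "name": "3-methyl-2-oxo-butanoate"
    },
    {
      "id": "aspartate",
      "name": "L-aspartate"
    },
    {
      "id": "oxaloacetate",
      "name": "oxaloacetate"
    },
    {
      "id": "fumarate",
      "name": "fumarate"
    },
    {
      "id": "malate",
      "name": "L-malate"
    },
    {
      "id": "nad",
      "name": "NAD+"
    },
    {
      "id": "nadh",
      "name": "NADH"
    },
    {
      "id": "h2o",
      "name": "H2O"
    },
    {
      "id": "nh4",
      "name": "NH4+"
    },
    {
      "id": "h",
      "name": "H+"
    }
  ],
  "reactions": [
    {
      "id": "ALT",
      "name": "alanine transaminase",
      "reversible": false,
      "stoichiometry": {
        "alanine": "1",
        "glutamate": "-1",
        "oxoglutarate": "1",
        "pyruvate": "-1"
      }
    },
    {
      "id": "ALD",
      "name": "alanine dehydrogenase (Ald)",
      "reversible": false,
      "stoichiometry": {
        "alanine": "-1",
        "h": "1",
        "h2o": "-1",
        "nad": "-1",
        "nadh": "1",
        "nh4": "1",
        "pyruvate": "1"
      }
    },
    {
      "id": "BCAT_leu",
      "name": "branched-chain transaminase, leucine (YbgE/YwaA)",
      "reversible": false,
      "stoichiometry": {
        "glutamate": "-1",
        "leucine": "1",
        "methyloxopentanoate": "-1",
        "oxoglutarate": "1"
      }
    },
    {
      "id": "BCD_leu",
      "name": "leucine dehydrogenase (Bcd)",
      "reversible": false,
      "stoichiometry": {
        "h": "1",
        "h2o": "-1",
        "leucine": "-1",
        "methyloxopentanoate": "1",
        "nad": "-1",
        "nadh": "1",
        "nh4": "1"
      }
    },
    {
      "id": "BCAT_val",
      "name": "branched-chain transaminase, valine (YbgE/YwaA)",
      "reversible": false,
      "stoichiometry": {
        "glutamate": "-1",
        "methyloxobutanoate": "-1",
        "oxoglutarate": "1",
        "valine": "1"
      }
    },
    {
      "id": "BCD_val",
      "name": "valine dehydrogenase (Bcd)",
      "reversible": false,
      "stoichiometry": {
        "h": "1",
        "h2o": "-1",
        "methyloxobutanoate": "1",
        "nad": "-1",
        "nadh": "1",
        "nh4": "1",
        "valine": "-1"
      }
    },
    {
      "id": "ASPB",
      "name": "aspartate aminotransferase (AspB)",
      "reversible": false,
      "stoichiometry": {
        "aspartate": "1",
        "glutamate": "-1",
        "oxaloacetate": "-1",
        "oxoglutarate": "1"
      }
    },
    {
      "id": "ANSB",
      "name": "aspartase (AnsB)",
      "reversible": false,
      "stoichiometry": {
        "aspartate": "-1",
        "fumarate": "1",
        "nh4": "1"
      }
    },
    {
      "id": "CITG",
      "name": "fumarase (CitG)",
      "reversible": false,
      "stoichiometry": {
        "fumarate": "-1",
        "h2o": "-1",
        "malate": "1"
      }
    },
    {
      "id": "MDH",
      "name": "malate dehydrogenase (Mdh)",
      "reversible": false,
      "stoichiometry": {
        "h": "1",
        "malate": "-1",
        "nad": "-1",
        "nadh": "1",
        "oxaloacetate": "1"
      }
    }
  ]
}
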