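{
  "comment": "SYNTHETIC word lists. Three parallel 15-item Dutch-style monosyllabic noun lists with disjoint recognition foils, standing in for the proprietary clinical lists, which are not redistributable. Structure only; no normative equivalence claimed.",
  "lists": [
    {
      "list_id": "synthetic-nl-a",
      "targets": ["boot", "zon", "kat", "brood", "stoel", "muur", "vis", "lamp", "boek", "touw", "kaas", "berg", "hond", "raam", "zout"],
      "foils": ["deur", "tuin", "melk", "schoen", "bril", "klok", "mes", "jas", "bloem", "trein", "glas", "steen", "vuur", "zand", "bed"]
    },
    {
      "list_id": "synthetic-nl-b",
      "targets": ["pen", "wolk", "paard", "brug", "kast", "veer", "slot", "bank", "knoop", "draad", "plant", "ring", "dak", "voet", "ijs"],
      "foils": ["stad", "peer", "mand", "hek", "zwaan", "krant", "doek", "pad", "fles", "hoed", "muis", "poort", "graf", "wiel", "net"]
    },
    {
      "list_id": "synthetic-nl-c",
      "targets": ["zee", "boom", "licht", "tand", "vork", "kin", "gras", "nest", "lijm", "spoor", "hoorn", "bal", "duin", "wand", "riem"],
      "foils": ["maan", "schip", "roos", "tak", "zak", "kool", "veld", "strand", "mist", "pop", "graan", "buis", "zaag", "turf", "kruk"]
    }
  ]
}
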