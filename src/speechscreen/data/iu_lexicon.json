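{
  "description": "Default Cookie-Theft information-unit inventory: 3 people, 2 places, 12 objects, 7 actions. Entity concepts carry literal surface patterns (single tokens or space-separated token sequences); action concepts carry agent patterns and action patterns matched as ordered co-occurrence within a token window. Patterns are English-keyed; Chinese surface forms can be appended to any pattern list.",
  "action_window": 10,
  "concepts": {
    "boy": {"category": "people", "patterns": ["boy"]},
    "girl": {"category": "people", "patterns": ["girl"]},
    "mother": {"category": "people", "patterns": ["mother", "mom", "woman"]},
    "kitchen": {"category": "places", "patterns": ["kitchen"]},
    "exterior": {"category": "places", "patterns": ["exterior", "outside", "garden", "yard"]},
    "cupboard": {"category": "objects", "patterns": ["cupboard", "cabinet"]},
    "cookie": {"category": "objects", "patterns": ["cookie", "cookies", "biscuit"]},
    "curtains": {"category": "objects", "patterns": ["curtain", "curtains"]},
    "jar": {"category": "objects", "patterns": ["jar"]},
    "dishes": {"category": "objects", "patterns": ["dish", "dishes", "plate", "plates"]},
    "sink": {"category": "objects", "patterns": ["sink"]},
    "stool": {"category": "objects", "patterns": ["stool"]},
    "water": {"category": "objects", "patterns": ["water"]},
    "window": {"category": "objects", "patterns": ["window"]},
    "dishcloth": {"category": "objects", "patterns": ["dishcloth", "towel", "cloth"]},
    "faucet": {"category": "objects", "patterns": ["faucet", "tap"]},
    "floor": {"category": "objects", "patterns": ["floor"]},
    "boy_takes_cookie": {
      "category": "actions",
      "agent_patterns": ["boy"],
      "action_patterns": ["take", "takes", "taking", "took", "steal", "steals", "stealing", "stole", "grab", "grabs", "grabbing", "reach", "reaches", "reaching"]
    },
    "boy_or_stool_falls": {
      "category": "actions",
      "agent_patterns": ["boy", "stool"],
      "action_patterns": ["fall", "falls", "falling", "fell", "tip", "tips", "tipping", "topple", "toppling", "wobble", "wobbling"]
    },
    "mother_washes_dishes": {
      "category": "actions",
      "agent_patterns": ["mother", "mom", "woman"],
      "action_patterns": ["wash", "washes", "washing", "dry", "dries", "drying", "wipe", "wipes", "wiping"]
    },
    "water_overflows": {
      "category": "actions",
      "agent_patterns": ["water", "sink"],
      "action_patterns": ["overflow", "overflows", "overflowing", "spill", "spills", "spilling", "run", "runs", "running"]
    },
    "girl_asks_cookie": {
      "category": "actions",
      "agent_patterns": ["girl"],
      "action_patterns": ["ask", "asks", "asking", "asked", "request", "requests", "requesting", "want", "wants", "wanting"]
    },
    "mother_unaware": {
      "category": "actions",
      "agent_patterns": ["mother", "mom", "woman"],
      "action_patterns": ["unaware", "unconcerned", "oblivious", "ignore", "ignores", "ignoring", "notice", "notices", "noticing"]
    },
    "children_steal_cookies": {
      "category": "actions",
      "agent_patterns": ["children", "kids"],
      "action_patterns": ["steal", "steals", "stealing", "stole", "take", "takes", "taking", "took"]
    }
  }
}
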