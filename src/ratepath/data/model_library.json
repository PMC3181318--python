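[
  {
    "name": "A-DAG1",
    "scenario": "replacement",
    "edges": [["dRES", "dBCC"], ["dBCC", "dSCC"], ["dSCC", "dPS"], ["dPS", "dBA"], ["dBA", "dBCM"]]
  },
  {
    "name": "A-DAG2",
    "scenario": "replacement",
    "edges": [["dRES", "dBCC"], ["dRES", "dSCC"], ["dBCC", "dSCC"], ["dSCC", "dPS"], ["dPS", "dBA"], ["dBA", "dBCM"]]
  },
  {
    "name": "A-DAG3",
    "scenario": "replacement",
    "edges": [["dRES", "dBCC"], ["dBCC", "dSCC"], ["dSCC", "dPS"], ["dPS", "dBA"], ["dPS", "dBCM"], ["dBA", "dBCM"]]
  },
  {
    "name": "A-DAG4",
    "scenario": "replacement",
    "edges": [["dRES", "dBCC"], ["dBCC", "dBA"], ["dBCC", "dSCC"], ["dSCC", "dPS"], ["dBA", "dPS"], ["dPS", "dBCM"], ["dBA", "dBCM"]]
  },
  {
    "name": "B-DAG1",
    "scenario": "adjustment",
    "edges": [["dRES", "dSCC"], ["dSCC", "dBCC"], ["dSCC", "dPS"], ["dPS", "dBA"], ["dBA", "dBCM"]]
  },
  {
    "name": "B-DAG2",
    "scenario": "adjustment",
    "edges": [["dRES", "dSCC"], ["dSCC", "dBCC"], ["dSCC", "dPS"], ["dPS", "dBA"], ["dBA", "dBCM"], ["dBCC", "dBCM"]]
  },
  {
    "name": "B-DAG3",
    "scenario": "adjustment",
    "edges": [["dRES", "dSCC"], ["dSCC", "dPS"], ["dPS", "dBA"], ["dBA", "dBCM"]]
  },
  {
    "name": "B-DAG4",
    "scenario": "adjustment",
    "edges": [["dRES", "dSCC"], ["dSCC", "dPS"], ["dSCC", "dBA"], ["dPS", "dBCM"], ["dBA", "dBCM"], ["dBCC", "dPS"], ["dBCC", "dBCM"]]
  },
  {
    "name": "B-DAG5",
    "scenario": "adjustment",
    "edges": [["dRES", "dSCC"], ["dSCC", "dPS"], ["dPS", "dBA"], ["dBA", "dBCM"], ["dBCC", "dPS"], ["dBCC", "dBCM"]]
  }
]
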