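{
  "states": [
    "C1",
    "C2",
    "C3",
    "C4",
    "C5",
    "O6"
  ],
  "transitions": [
    {
      "from": "C1",
      "to": "C2",
      "k0": 800.0,
      "kv": 0.055,
      "kp": 0.0,
      "multiplicity": 4
    },
    {
      "from": "C2",
      "to": "C3",
      "k0": 800.0,
      "kv": 0.055,
      "kp": 0.0,
      "multiplicity": 3
    },
    {
      "from": "C3",
      "to": "C4",
      "k0": 800.0,
      "kv": 0.055,
      "kp": 0.0,
      "multiplicity": 2
    },
    {
      "from": "C4",
      "to": "C5",
      "k0": 800.0,
      "kv": 0.055,
      "kp": 0.0,
      "multiplicity": 1
    },
    {
      "from": "C5",
      "to": "O6",
      "k0": 70.0,
      "kv": 0.0,
      "kp": -0.05,
      "multiplicity": 1
    },
    {
      "from": "C2",
      "to": "C1",
      "k0": 0.1,
      "kv": -0.055,
      "kp": 0.0,
      "multiplicity": 1
    },
    {
      "from": "C3",
      "to": "C2",
      "k0": 0.1,
      "kv": -0.055,
      "kp": 0.0,
      "multiplicity": 2
    },
    {
      "from": "C4",
      "to": "C3",
      "k0": 0.10000000000000002,
      "kv": -0.055,
      "kp": 0.0,
      "multiplicity": 3
    },
    {
      "from": "C5",
      "to": "C4",
      "k0": 0.1,
      "kv": -0.055,
      "kp": 0.0,
      "multiplicity": 4
    },
    {
      "from": "O6",
      "to": "C5",
      "k0": 55.0,
      "kv": 0.0,
      "kp": -0.005,
      "multiplicity": 1
    }
  ],
  "variant": "MSO"
}
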