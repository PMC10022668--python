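{
  "labels": [
    "no sensation",
    "faint",
    "very weak",
    "weak",
    "very mild",
    "mild",
    "moderate",
    "barely strong",
    "slightly intense",
    "strong",
    "intense",
    "very intense",
    "extremely intense"
  ],
  "relative_magnitude": {
    "fatigue": {
      "faint": 0.4419,
      "very weak": 0.4435,
      "weak": 0.5402,
      "very mild": 0.5514,
      "mild": 0.7484,
      "moderate": 1.1099,
      "barely strong": 1.1094,
      "slightly intense": 1.2076,
      "strong": 1.6716,
      "intense": 1.7502,
      "very intense": 2.1735,
      "extremely intense": 2.4191
    },
    "pain": {
      "faint": 0.426,
      "very weak": 0.3699,
      "weak": 0.5032,
      "very mild": 0.53,
      "mild": 0.752,
      "moderate": 1.1484,
      "barely strong": 1.2524,
      "slightly intense": 1.2856,
      "strong": 1.6476,
      "intense": 1.8163,
      "very intense": 2.196,
      "extremely intense": 2.6018
    }
  }
}
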