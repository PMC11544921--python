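{
  "skin": {
    "young_modulus": 10.69,
    "tangent_modulus": null,
    "bio_yield_stress": 0.53,
    "density": 960.0,
    "poisson_ratio": 0.30,
    "spread": {"young_modulus": 0.46, "bio_yield_stress": 0.12, "density": 30.0}
  },
  "flesh": {
    "young_modulus": 1.57,
    "tangent_modulus": 0.92,
    "bio_yield_stress": 0.26,
    "density": 1030.0,
    "poisson_ratio": 0.40,
    "spread": {"young_modulus": 0.12, "tangent_modulus": 0.06, "bio_yield_stress": 0.07, "density": 45.0}
  },
  "core": {
    "young_modulus": 5.11,
    "tangent_modulus": 0.83,
    "bio_yield_stress": 1.12,
    "density": 1120.0,
    "poisson_ratio": 0.40,
    "spread": {"young_modulus": 0.28, "tangent_modulus": 0.04, "bio_yield_stress": 0.23, "density": 70.0}
  },
  "steel": {
    "young_modulus": 210000.0,
    "tangent_modulus": null,
    "bio_yield_stress": 235.0,
    "density": 7850.0,
    "poisson_ratio": 0.33,
    "spread": {}
  },
  "pvc": {
    "young_modulus": 70.0,
    "tangent_modulus": null,
    "bio_yield_stress": null,
    "density": 60.0,
    "poisson_ratio": 0.30,
    "spread": {}
  },
  "neoprene": {
    "young_modulus": 7.8,
    "tangent_modulus": null,
    "bio_yield_stress": null,
    "density": 930.0,
    "poisson_ratio": 0.47,
    "spread": {}
  }
}
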