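{
  "version": "1.0",
  "description": "Simplified nearest-neighbor free-energy parameters (kcal/mol, 37C) for intermolecular RNA duplexes. Watson-Crick stack values follow the standard published nearest-neighbor set; stacks involving G:U wobble pairs are collapsed to a single generic value (two wobbles: a weaker one). Loop penalties are affine in the number of unpaired nucleotides. All predictions in this package are defined relative to THIS table.",
  "units": "kcal/mol",
  "initiation": 4.09,
  "stacks_wc": {
    "AU/AU": -0.93,
    "AU/UA": -1.10,
    "AU/CG": -2.24,
    "AU/GC": -2.08,
    "UA/AU": -1.33,
    "UA/UA": -0.93,
    "UA/CG": -2.35,
    "UA/GC": -2.11,
    "CG/AU": -2.11,
    "CG/UA": -2.08,
    "CG/CG": -3.26,
    "CG/GC": -2.36,
    "GC/AU": -2.35,
    "GC/UA": -2.24,
    "GC/CG": -3.42,
    "GC/GC": -3.26
  },
  "stack_one_gu": -1.0,
  "stack_two_gu": -0.3,
  "bulge_base": 3.2,
  "bulge_per_nt": 0.6,
  "interior_base": 1.6,
  "interior_per_nt": 0.5,
  "max_loop_per_side": 15
}
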