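t4 = 3.69% reduction of free-PKAc AUC (n = 5 seed-matched trials, 706 s)
wrote results/acceptance.json
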