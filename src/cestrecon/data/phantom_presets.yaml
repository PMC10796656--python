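# Digital-phantom tissue presets.  Units: SI (fs absolute fraction, times
# in seconds).  Every value lies inside the default uniform sampling
# bounds so phantoms stay within the training domain.  Solute T1 is 1 s
# and water fs is 1 by convention and omitted here.
gm_like:
  water: {t1: 1.9, t2: 0.070}
  amide: {fs: 0.0018, ksw: 30.0, t2: 0.010}
  guanidyl_amine: {fs: 0.0010, ksw: 500.0, t2: 0.002}
  hydroxyl: {fs: 0.0040, ksw: 800.0, t2: 0.002}
  noe_m1p6: {fs: 0.0030, ksw: 20.0, t2: 0.0005}
  mt: {fs: 0.060, ksw: 25.0, t2: 0.00005}
  noe_m3p5: {fs: 0.025, ksw: 15.0, t2: 0.005}
wm_like:
  water: {t1: 1.4, t2: 0.050}
  amide: {fs: 0.0015, ksw: 25.0, t2: 0.010}
  guanidyl_amine: {fs: 0.0008, ksw: 450.0, t2: 0.002}
  hydroxyl: {fs: 0.0030, ksw: 700.0, t2: 0.002}
  noe_m1p6: {fs: 0.0040, ksw: 18.0, t2: 0.0006}
  mt: {fs: 0.120, ksw: 30.0, t2: 0.00005}
  noe_m3p5: {fs: 0.035, ksw: 12.0, t2: 0.006}
tumor_like:
  water: {t1: 2.5, t2: 0.090}
  amide: {fs: 0.0026, ksw: 60.0, t2: 0.012}
  guanidyl_amine: {fs: 0.0015, ksw: 700.0, t2: 0.002}
  hydroxyl: {fs: 0.0060, ksw: 1200.0, t2: 0.003}
  noe_m1p6: {fs: 0.0020, ksw: 15.0, t2: 0.0005}
  mt: {fs: 0.030, ksw: 15.0, t2: 0.00006}
  noe_m3p5: {fs: 0.015, ksw: 10.0, t2: 0.004}
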