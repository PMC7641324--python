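# chirace

A simulate → measure → infer pipeline for the two-helicase race model of
RecBCD, the bacterial helicase–nuclease that initiates double-strand-break
repair, under small-molecule sensitization.

## The problem

RecBCD enters a linear duplex at a blunt end and unwinds it with two motors
of unequal speed: RecD (fast, velocity *y*) on the 5′-ended strand and RecB
(slow, velocity *x*) on the 3′-ended strand. Normally the nuclease cuts only
when RecB traverses a correctly oriented Chi hotspot (5′-GCTGGTGG-3′). The
sulfanyltriazolobenzimidazole NSAC1003 changes this in two coupled ways:

1. it competes with ATP at RecB's nucleotide-binding site, slowing RecB
   relative to RecD in a concentration-dependent way (competitive
   inhibition: v = v_max·[ATP]/(Km·(1+[I]/Ki) + [ATP]), hence
   IC50 = Ki·(1+[ATP]/Km));
2. it sensitizes the enzyme to cut at a Chi-*independent* position: when
   RecD stops at the far end of the DNA, RecB cuts where it is at that
   moment, i.e. at *x/y* of the substrate length *S* from the entry point
   (plus a few hundred nucleotides of advance while the tethered nuclease
   domain slowly swings into place).

The labeled product measured on a gel is therefore S·(1 − x/y) − advance
for end-stop cuts, linear in S across substrate lengths; the slope gives
the velocity ratio and the (negative) intercept gives the swing advance.
Chi-triggered cuts, by contrast, follow a fast (~1 ms) swing and land
within a ~3-nt window at the Chi position.

The package implements this model end to end: competitive-inhibition
kinetics with a two-condition (Ki, Km) solver; an event-driven single-
molecule race simulator (Chi vs end-stop trigger, Gamma-distributed swing
delays); a gel-readout layer (log-length migration, Gaussian bands, band
detection, marker-ladder interpolation); the inference stage (per-
concentration OLS, parameter inversion, four-parameter logistic
dose-response); and seeded generators of complete synthetic experiments.

## Worked example

```python
from chirace import *
from chirace.defaults import default_config

cfg = default_config()

# Ki and Km from the two-condition IC50 pair (10 uM at 25 uM ATP,
# 100 uM at 4 mM ATP):
ki, km = solve_ki_km(list(cfg.ic50_observations))
print(ki, km)                  # 9.434 416.67

# one uninhibited molecule of the 4350-nt Chi-bearing substrate:
sub = make_default_substrates()[0]            # 4350_chi+
cond = ReactionConditions(inhibitor_uM=0.0, mode="table")
frags = simulate_population(5000, sub, cfg.enzyme, cond, seed=1)
lane = render_lane(frags, cfg.gel, cfg.markers())
bands = [b for b in estimate_band_lengths(lane) if not b.is_full_length]
print(bands[0].length_nt)      # 970.0  (Chi cut, 970 nt from the label)
```

Running the numbered drivers reproduces the whole study:

```bash
python analysis/01_calibrate_kinetics.py   # Ki = 9.434 uM, Km = 416.7 uM
python analysis/02_generate_experiments.py # 36 lanes + dose-response table
python analysis/03_infer_parameters.py     # per-concentration recovery
python analysis/04_figures.py              # optional PNGs
```

Step 3 prints, for the seeded default experiment (2000 molecules/lane,
Gamma swing noise cv = 0.2):

```
  [I] uM   slope   intercept   ratio(true)      advance(true)   tau_ms
      25   0.295     -235.6   0.705 (0.70)    235.6 (250)    235.6
      50   0.401     -254.8   0.599 (0.60)    254.8 (250)    254.8
     100   0.501     -379.5   0.499 (0.50)    379.5 (370)    379.5
     200   0.601     -293.7   0.399 (0.40)    293.7 (290)    293.7
     400   0.700     -201.6   0.300 (0.30)    201.6 (200)    201.6
Dose response: IC50 = 5.87 uM (generator setting 6.3), Hill = 1.06, ...
```

i.e. the inhibitor drops the cut position from ~70% to ~30% of the
substrate length across the titration, the recovered swing advances sit at
200–370 nt (≈ 200–370 ms at RecB's ~1 nt/ms), and the solubilization IC50
comes back at the generating value within sampling error.

There is also a small CLI: `chirace generate | simulate | infer | scan |
report` (`chirace scan genome.fa --entry right` lists oriented Chi cut
sites in a FASTA sequence).

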