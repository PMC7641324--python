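# Methods

## Model

One RecBCD complex enters a linear duplex of length *S* (nt) at one blunt
end; coordinates are 0-based nucleotide distances from the entry end, and
the radiolabeled 5′ end is always distal to entry, so a cut at position *p*
releases a labeled single strand of length *S − p*. Two motors translocate
simultaneously: RecB at v_B and RecD at v_D ≥ v_B, each obeying the
single-substrate competitive-inhibition law

    v([ATP], [I]) = v_max · [ATP] / ( Km · (1 + [I]/Ki) + [ATP] ).

This functional form is the minimal one consistent with ATP-competitive
inhibition; its signature, the Cheng–Prusoff shift IC50 = Ki·(1+[ATP]/Km),
lets the two-condition solver (`solve_ki_km`) convert a pair of
(ATP, IC50) observations into (Ki, Km) exactly: the packaged pair
(25 μM → 10 μM, 4000 μM → 100 μM) gives Ki = 9.434 μM, Km = 416.7 μM.

Two events can trigger the nuclease:

* **Chi trigger.** If RecB traverses an active Chi site at distance d_chi
  from entry before RecD reaches the far end (d_chi/v_B < S/v_D), and the
  site is recognized (Bernoulli p_chi_recognition, default 1), the nuclease
  swings fast (mean 1 ms) and the cut is pinned at d_chi with ±1 nt uniform
  jitter. We pin the position rather than advancing RecB during the swing:
  at ~1 nt/ms a 1-ms swing moves RecB ≤ 1 nt, and both published
  interpretations of the sharp Chi band (fast swing, or DNA kinked at Chi)
  place the cut essentially at Chi. The resulting population span is ≤ 3 nt.
* **End-stop trigger.** When RecD reaches the far end first, a sensitized
  enzyme (probability p_sens = [I]/([I]+k_sens), zero without drug) cuts at
  RecB's position after a slow swing: p = S·(v_B/v_D) + v_B·τ, with τ drawn
  from a Gamma distribution of mean tau_stop_ms and coefficient of
  variation cv. If p ≥ S the slow motor finishes first and no internal cut
  is made (consistent with the closed form `predicted_cut_position`
  returning "none"). Unsensitized molecules release a full-length strand.

Across substrates the labeled end-stop product is S·(1 − v_B/v_D) − advance:
linear in S. OLS of product length on substrate length therefore recovers
the velocity ratio (1 − slope) and the swing advance (−intercept), and
dividing by v_B ≈ 1 nt/ms converts the advance to a swing time.

## Parameters, units, defaults

| parameter | default | unit | why |
|---|---|---|---|
| recD.v_max | 1.0 | nt/ms | makes nt and ms numerically interchangeable at the enzyme's ~1 bp/ms unwinding rate |
| recB.v_max | 0.8 | nt/ms | drug-free ratio 0.80 (see below) |
| Km(ATP) | 416.7 | μM | solved from the two-condition IC50 pair |
| Ki(RecB) | 9.434 | μM | same solve |
| Ki(RecD) | 68.87 | μM | 7.3 × Ki(RecB), the predicted binding-affinity ratio of the two ATP sites; only the direction (RecD less inhibited) matters |
| tau_chi_ms | 1.0 | ms | fast swing; sharp Chi band |
| tau_stop_ms | 250 | ms | middle of the 200–300 ms range implied by the smear and the intercepts |
| cv | 0.2 | — | Gamma swing-time spread giving a 200–300 nt smear at ~1 nt/ms; distribution family is our choice, only the mean is constrained |
| chi_offset_nt | 5 | nt | cut 4–6 nt 3′ of the Chi octamer |
| k_sens_uM | 75 | μM | midpoint of the ~50–100 μM half-maximal sensitization |
| p_chi_recognition | 1.0 | — | per-encounter cutting efficiency is not quantified; 1.0 for reproduction targets, configurable |

**Table vs kinetic mode.** The published analysis reports per-concentration
fits, not motor velocities, so the default "table" mode looks the velocity
ratio and advance up directly in a calibration table:
{0: (0.80, 0), 25: (0.70, 250), 50: (0.60, 250), 100: (0.50, 370),
200: (0.40, 290), 400: (0.30, 200)} (μM → ratio, nt). The 25 and 400 μM
ratios and the 50–400 μM advances are the reported operating points; the
50/100/200 μM ratios are interpolated on a uniform grid, and the 25 μM
advance reuses the neighboring 250 nt since no intercept is reported there.
"Kinetic" mode computes the ratio from the two rate laws instead; with the
default constants it tracks the table within ~0.03 across the titration
(analysis step 1 prints the comparison), which is a genuine consistency
check, not a fit.

**Drug-free ratio 0.80.** The race rule means a Chi site is only cut when
RecB reaches it before RecD reaches the end, i.e. when v_B/v_D exceeds
d_chi/S (= 3380/4350 = 0.777 on the longest packaged substrate). The
uninhibited enzyme does cut at Chi on that substrate, so the drug-free
ratio must exceed 0.777; we use 0.80, consistent with the titration
monotonically lowering the ratio from its drug-free value to 0.70 at 25 μM.

**Reaction duration.** The 60-s reaction is treated as run-to-completion:
at ~1 nt/ms even the longest substrate is traversed in < 5 s, so the
duration field is carried as metadata only.

## Gel readout

Forward: migration d = a − b·log10(L) with a = 120 mm, b = 30 mm/decade
(a chosen so the whole 100–5000 nt validity range maps to positive
distances on the lane grid), Gaussian point-spread σ = 0.8 mm, band area
proportional to molecule count (end labels are molar). Species outside the
validity range run off the gel and are not rendered. Inverse: local-maxima
band detection above a relative threshold (default 5% of the lane maximum),
centroid band centers ("middle of the band"), then piecewise-linear
interpolation of log10(length) against the marker ladder — exact at marker
points, and refusing to extrapolate outside the ladder span. Bands closer
than about one point-spread merge into one detected band. The default
ladder {4350, 2270, 1340, 1000, 500, 250, 100} nt adds a 100-nt standard
below the three boiled substrates and round-number markers so that the
shortest end-stop product in the design (≈150 nt: 25 μM on the 1340-nt
substrate) stays inside the interpolation span; the real digest-marker
lengths are not available.

## Inference

Product-vs-substrate fits are ordinary least squares with classical
standard errors, one fit per concentration, matching the three-substrate
design (no errors-in-variables, uniform weights; band-position uncertainty
is similar across lanes). The full-length band — any band within 2% of the
substrate length — is excluded from product fitting, and fits use the
Chi-less lanes by default so the end-stop product is unambiguous. A
positive fitted intercept is unphysical (the nuclease cannot cut behind the
slow motor) and clamps the advance to zero with a flag.

The dose-response is a four-parameter logistic (top, bottom, IC50, Hill
free; Hill initialized at 1, IC50 at the concentration nearest half-max)
fitted by nonlinear least squares. Solubilization replicates scatter in
proportion to their mean (the generator applies multiplicative Gaussian
noise of CV 5%), so the fit iteratively reweights residuals by the fitted
response (three passes); an unweighted fit is available via
`proportional_error=False`. Under the default assay design (8 levels in
0–80 μM, 3 replicates, CV 5%) the single-assay IC50 estimate has a
sampling SD of roughly 0.4–0.5 μM around the generating value — the
information limit of that design — so a single synthetic assay reproduces
the generating IC50 only to within about half a micromolar, while the
estimator mean over seeds is accurate to better than ±0.2 μM.

## What the generator does and does not emulate

The synthetic experiment reproduces the design (three substrate lengths ×
with/without Chi × six concentrations, 36 lanes), molar band intensities,
the sharp-vs-smeared band contrast, the Chi/end-stop race switch on the
mid-length substrate, and seeded reproducibility (one spawned RNG stream
per lane). It does not emulate: partial reaction (every molecule is
unwound; real gels retain native substrate), Chi recognition failure at
the default p = 1 (real lanes show Chi and end-stop bands coexisting on
the short substrate; lowering p_chi_recognition reproduces this), enzyme
dissociation or re-initiation, loop/tail annealing products,
substrate-sequence-specific markers, or scintillation-counting statistics
beyond the CV knob. Passing tests therefore validate the model's internal
consistency and the inference pipeline's correctness, not gel artifacts or
enzyme heterogeneity in real data. One known qualitative difference,
inherited from the model itself: at 25 μM the generator produces a (weak)
end-stop band on the longest substrate, where the wet experiment detected
none at that concentration.

## Numerical choices and degenerate inputs

Lane profiles are rendered on a 0.05-mm grid (point-spread 16× the step).
Gamma delays degenerate to their exact mean at cv = 0, which is what makes
the cv = 0 simulator agree exactly with the closed forms (the oracle
equivalence the tests exploit). Fragment lengths round to the nearest
integer nucleotide and clamp to ≥ 1. The two-condition solver rejects equal
ATP levels, equal IC50s, and parameter pairs implying non-positive Ki or
Km. `chi_scan` clamps cut distances that would fall before the entry end to
zero. Interpolation requires ≥ 2 markers with distinct distances. OLS with
exactly two points returns the exact line with NaN standard errors.
Problem sizes in tests and the acceptance script (1500–10000 molecules per
lane, 200 Monte-Carlo replicates) were chosen so every law-of-large-numbers
check sits several standard errors inside its tolerance.

## Known limitations

The sensitization probability and the velocity-ratio titration are
independent knobs here; in the enzyme both presumably derive from the same
binding event. Whether solubilization activity is proportional to RecB
velocity alone is an interpretation (the assay shows competition, not
attribution), and whether RecD ATPase is partially inhibited in solution is
unknown — the kinetic defaults encode "less inhibited", not "uninhibited".
Whether RecB translocates at its pre-stop velocity during the slow swing is
assumed, as the ~1 nt/ms arithmetic implies. Chi traversal without
recognition is assumed to leave the end-stop pathway available.
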