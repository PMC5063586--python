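# Methods

## The kinetic model

The model tracks the nicotinamide-moiety species of the axonal NAD⁺ salvage
pathway — Nam, NMN, NaMN, NAD⁺, NaAD — each resolved into D0/D3/D4
isotopologues, plus the adenylates (ATP, ADP, AMP) and nicotinamide
riboside (NR). Units are µM and hours throughout. Reactions:

| step | law | notes |
|---|---|---|
| Nam → NMN (NAMPT) | `vmax · Nam/(Km+Nam) · Kiʰ/(Kiʰ+NADʰ) · ATP/ATP₀` | label split follows the Nam pool |
| NR → NMN (NRK1) | `k_nrk · NR · Km_nrk/(Km_nrk+NR)` | product unlabeled; saturates at mM NR |
| NMN → NAD⁺ (NMNAT) | `a(t) · k_nmnat · NMN` | label preserving |
| NaMN → NaAD (NMNAT) | `a(t) · k_nmnat_namn · NaMN` | label preserving |
| NaAD → NAD⁺ (NAD synthetase) | `k_nadsyn · NaAD` | NMNAT-independent |
| NMN ⇌ NaMN (deamidase / synthetase) | first order | bacterial enzymes, off in control |
| NMN clearance | `k_nmn_leak · NMN` | NMNAT-independent (nucleotidase/export); routed to NR in the closed variant |
| NAD⁺ consumption | `(k_cons_basal + 1{t≥t_ax} · m · k_cons_sarm1) · NAD` | cleavage returns ring-labeled Nam to the medium |
| D4-NAD⁺ → D3-NAD⁺ | `k_exchange · NAD_D4` | C4 hydride exchange via NAD⁺/NADH cycling; applies to the NAD⁺ pool only |

`a(t)` is the NMNAT activity: 1 before axotomy, and after a latency
`nmnat_decay_delay_h` it decays exponentially with half-life
`t_half_nmnat2` (axotomy-resistant in the cytNMNAT1 scenario). The
delay-then-collapse shape encodes two observations simultaneously: heavy
NAD⁺ still accumulates briskly during the first two hours after injury, and
synthesis is essentially gone thereafter. A single 2 h exponential
half-life can satisfy neither.

`m` is a per-scenario SARM1 engagement factor: 1 in control and
synthetase-only axons, 0 in the strongly protected genotypes (cytNMNAT1,
deamidase combinations) and in the FK866/NAMPT/NRK1+NR conditions, and the
knockout sets `k_cons_sarm1 = 0` outright. The quantitative mapping from
genotype to SARM1 engagement is not an experimentally measured curve; the
factor encodes the observed pattern that injury-induced consumption (and
the downstream energy failure) appears only where axons go on to
degenerate rapidly.

The adenylate pool is constant in uninjured axons and declines first-order
(`k_adenylate_decay`) after axotomy, but only when SARM1 is engaged — the
energy failure is downstream of SARM1-driven NAD⁺ loss, and protected
genotypes show no post-injury metabolite changes. NAMPT activity is scaled
by ATP/ATP₀ (its substrate PRPP requires ATP regeneration), which is what
pulls the post-injury NMN transient back toward baseline once the pool
collapses.

The medium is an infinite reservoir: Nam (30 µM unlabeled; plus 300 µM
D4-Nam from `tracer_start`, a 10-fold excess) and NR concentrations are
held fixed and Nam released by NAD⁺ cleavage is discarded. A
`closed_medium` variant makes both finite so the total nicotinamide moiety
(five species × three labels, plus NR) is strictly conserved; the property
suite integrates it to verify mass balance.

**Integrator.** `scipy.integrate.solve_ivp` (LSODA), rtol 1e-8, atol
1e-10 µM, integrated piecewise between the discontinuities (tracer
addition, axotomy, end of the NMNAT latency). Any state below −1e-9 µM
aborts the run; smaller negatives are clipped to zero on output. Scenarios
with expressed enzymes or NR are first equilibrated for 96 h (no tracer, no
injury) so their baselines are the scenario's own quasi-steady state.

## Calibration of the defaults

Six rate constants plus the feedback parameters were fixed by weighted
least squares (`analysis/00_calibrate_defaults.py`) so that the *pipeline
itself* — noiseless simulation, quantitation, then the interval-average
estimators — reproduces the reported values: uninjured consumption and
synthesis (8.2 and 6.9 % h⁻¹), post-axotomy consumption and synthesis
(21.7 and 14.0 % h⁻¹), post-axotomy SARM1-KO consumption (7.9 % h⁻¹), a
~2-fold NMN transient that returns to baseline by 6 h, and a deamidase
steady-state NAD⁺ at 11 % of control that is stable after axotomy. The
frozen result ships as `src/nadflux/data/default_params.json`; the achieved
noiseless values are printed by the script (all within the reported
standard deviations; post-axotomy synthesis lands at ~10.8 vs 14.0 ± 6.9).

Two structural points the calibration forced, worth knowing:

- **Ultrasensitive feedback.** The uninjured estimates demand a sluggish
  NMN pool (the 2 h heavy-NAD⁺ readout must lag the 4 h light readout),
  while the post-injury synthesis rise demands that NAMPT output roughly
  double while NAD⁺ has only fallen ~40 %. A hyperbolic `Ki/(Ki+NAD)` law
  cannot do both (its maximal relief is bounded by NAD₀/NAD). The feedback
  is therefore a Hill function; the fit runs the exponent to its bound
  (h = 12), i.e. a switch-like release around 0.85 µM. This is a
  phenomenological stand-in for whatever cooperative regulation acts on
  NAMPT in axons.
- **The deamidase reservoir.** With deamidase expressed, nearly all NAMPT
  flux shunts through NaMN into a large, slowly-draining NaAD pool
  (`k_nadsyn` ≈ 2e-4 h⁻¹). The residual NAD⁺ (11 % of control) is fed
  mostly by that reservoir through NAD synthetase, which survives NMNAT2
  loss — this is why the deamidase scenario's NAD⁺ barely moves after
  axotomy and why it stays above the degeneration threshold indefinitely.

Pool scale is arbitrary (rates are percentages): baseline NAD⁺ is set to
1 µM. The fitted NMN/NAD⁺ ratio (~0.5) is well above the published axonal
ratio; it is the price of making the 2 h/4 h estimator asymmetry
quantitative and does not affect any relative readout.

## Synthetic measurement layer

Per-well error is multiplicative lognormal with mean 1; the default CV of
0.15 is a modeling choice (the source assay's CV is not stated) picked to
give per-well rate spreads of the same magnitude as the reported ± s.d.
Each quantified transition (D0/D3/D4 NAD⁺, D0/D4 NMN, totals for NaMN,
NaAD, ATP, ADP, AMP) draws independent noise; the per-well "total" row is
the sum of its label rows, so label additivity holds exactly in the
tables. Standard curves are 2-fold serial dilutions fit by ordinary least
squares, with the LOD at the lowest level exceeding 3× the blank s.d.;
values back-calculating below the LOD are censored. By default `quantify`
uses an ideal identity calibration with LOD 0, because the published
standard ranges (top 25 µM, lowest ~0.2 µM) sit above genuine axonal
concentrations (~0.01 µM NMN) — the standards describe injected extract
responses, not in-axon molarity. Wells are longitudinal (the same well id
is sampled at every design time), which is what the per-well interval
estimators require.

## Flux estimators

Exactly the bench arithmetic, per well, then mean ± s.d. over wells:
consumption `100·(L(t₀)−L(t₀+4))/(L(t₀)·4)` on light NAD⁺, synthesis
`100·(H(t₀+2)−H(t₀))/(T(t₀)·2)` with H = D3+D4 and T = total at t₀. These
are interval averages of a decaying process, not instantaneous rate
constants: on a pure exponential with rate k the consumption estimator
returns `100·(1−e^(−4k))/4`, which the tests verify to 1e-8 and which
approaches `100·k` as k → 0. Consumption is referenced to the light pool
and synthesis to the total pool so that a balanced steady state yields
comparable numbers under a near-complete tracer swap. ATP normalization
(divide same-well NAD⁺ by ATP) is exposed for both estimators; it is
neutral in uninjured axons (constant ATP) and both modes are available
post-injury since the adenylate pool itself declines there.

## Degeneration

`degeneration_index` contrast-stretches, Otsu-binarizes, labels connected
components (8-connectivity, ≥5 px), and classifies particles with
circularity `4πA/P² > 0.2` as fragments; DI is fragment area over total
foreground area. The perimeter is the Crofton estimator — the weighted
pixel-count perimeter collapses on diagonal fibers and would misclassify
intact axons as round. The synthetic generator draws quadratic-Bézier
fibers and replaces a ground-truth fraction of each fiber's path with
well-separated disks; measured DI tracks the ground truth with rank
correlation > 0.95, which is what validates the operator in the absence of
micrographs.

`threshold_onset_model` is an explicit artifact-level construct, not a
measured dose-response: DI stays 0 until NAD⁺ falls below
`threshold_fraction` (default 0.5) of its pre-injury baseline, then rises
logistically (lag 5 h, rate 1 h). Degeneration additionally requires the
SARM1 executioner (`sarm1_present=False` for the knockout, whose NAD⁺
does fall after injury without fragmentation). With the calibrated
trajectories this reproduces the protection ordering — control crosses
DI 0.3 at ~7 h (< 9 h), FK866 later, NAMPT/NRK1+NR later still, and
cytNMNAT1 / deamidase / SARM1-KO never within 72 h.

## Statistics

One-way ANOVA (between/within sum-of-squares), Holm–Bonferroni step-down,
pooled-variance Student t and box summaries are implemented from their
formulas so the suite can verify them against brute-force oracles (to
1e-10) and a 2000-replicate null simulation (type-I error within
[0.04, 0.06] at α = 0.05). Only tail probabilities come from scipy's F and
t distributions. Quartiles interpolate linearly between closest ranks;
whiskers sit at the most extreme observations within 1.5 × IQR.

## What the synthetic data do and do not show

The generator emulates per-well quantified metabolite tables with
realistic replicate structure (n = 3–12), measurement noise, censoring,
isotopologue bookkeeping, and brightfield-like axon fields at known
fragmentation. It does not emulate chromatography, peak integration,
isotope envelopes, biological well-to-well heterogeneity beyond lognormal
noise, spatial axon structure, or stochastic single-axon commitment.
Passing tests therefore certify the estimators, the bookkeeping and the
model's internal consistency against the published rates — not that the
ODE model is a validated mechanism for real axons.

Known limitations:

- Absolute protection times of the intermediate group are compressed
  (FK866 ~10 h, NAMPT/NRK1+NR ~11 h to DI 0.3, versus ~15–50 h observed);
  only the ordering is calibrated. First-order consumption from a pool
  ~1.4× baseline cannot stretch survival to 24–48 h without contradicting
  the measured flux rates.
- The deamidase+synthetase scenario loses the NaAD reservoir and so
  crosses the NAD⁺ threshold in the DI construct, although such axons are
  protected in the assay; the construct should not be used for that
  condition.
- Post-injury NMN in scenarios that keep NAMPT running without NMNAT
  (e.g. NAMPT overexpression, SARM1-KO) accumulates strongly; those NMN
  levels were not measured and should be treated as unconstrained model
  output.
- The adenylate decline needed to return NMN to baseline by 6 h is faster
  than the measured pool decline; the two observations trade off through
  the ATP-coupling of NAMPT.
- The tracer's deuterium positions are not modeled beyond single-step
  D4 → D3 exchange on NAD⁺ (the two printed position lists for D4-Nam
  differ; neither affects nominal masses).
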