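# Methods

## Model

The unit of analysis is a *temporal sequence*: one simulated history of a
group's expert pool over a horizon of L years. The pool starts full at
η_max, decays exponentially between uses with e-folding (forgetting) time τ,
and resets instantly and completely to η_max at every use. Loss is
irreversible: once the continuous expert count falls below the retention
threshold (default one person), the sequence ends. Because decay is
deterministic given the gap length, "some interval exceeds
Δt_max = τ·ln(η_max / threshold)" is exactly equivalent to "the expert count
crosses the threshold"; the engine uses the interval form and the test suite
asserts the equivalence against the decay law directly.

Use intervals are independent draws from Normal(θ, (νθ)²) conditioned on
positivity. Conditioning is implemented by rejection (redraw non-positive
values in vectorized batches), which reproduces the truncated law exactly;
clipping or absolute-value folding would pile probability mass at short
intervals and bias the process toward retention. At ν = 0 the distribution
degenerates to a point mass at θ.

Assumptions worth keeping in mind:

- Recovery is instantaneous and complete. This is deliberately conservative:
  any slower re-learning process could only make loss more likely.
- Experts are not lost to death or migration, and groups cannot re-acquire
  the skill from neighbours. Both extensions change the qualitative picture
  and are out of scope.
- The four parameters (θ, ν, η_max, τ) are treated as independent.

## Parameters

| Parameter | Meaning | Units | Default / canonical sweep |
|---|---|---|---|
| θ | mean interval between uses | years | sweep 1–20 |
| ν | interval sd as a fraction of θ | — | sweep 0.1–2.0 |
| η_max | expert pool at full strength | individuals | sweep 3–60 |
| τ | forgetting time (pool → η_max/e) | years | sweep 1–16 |
| L | modeled horizon | years | 1000 |
| K | sequences per Monte-Carlo estimate | — | 111 |
| threshold | minimum experts for survival | individuals | 1 |

Validation errors only on mathematical impossibilities (θ ≤ 0, η_max < 1,
…); values outside the sweep box raise a `ParameterRangeWarning` instead,
because the box marks the studied regime, not a constraint of the
mathematics.

The default ν axis runs from 0.1, the lower end of the canonical sweep (10%
relative variability, a fairly predictable event regime), to 2.0 (highly
erratic). Grids accept any explicit axes, including ν = 0, where both
engines become deterministic step functions at θ = Δt_max.

## Numerical engine

Each sequence draws ceil(2L/θ) intervals up front — twice the expected
number needed — and extends by further batches in the rare event that their
sum still falls short of L without a loss. Termination rules, in order per
interval: (1) interval > Δt_max → loss, with the loss instant recorded as
the last use time plus Δt_max (where the decay curve crosses the threshold);
(2) cumulative time > L → retention. Ties (interval exactly Δt_max) retain,
since the pool sits exactly at the threshold and the loss rule is a strict
inequality. Uses are counted only at times within the horizon.

Randomness: one master integer seed per estimate; each of the K sequences
runs on its own child stream spawned via `numpy.random.SeedSequence`, so
estimates are bit-for-bit reproducible and independent of execution order.
The estimate carries its exact loss count and the binomial standard error
√(p(1−p)/K); at K = 111 the worst-case standard error is ≈ 0.047.

## Closed form

P_d is the *untruncated* upper-tail mass of Normal(θ, (νθ)²) beyond Δt_max,
evaluated with `scipy.special.erfc`. Two deliberate choices:

- **Exponent form.** P_r = (1 − P_d)^(L/θ), the probability that none of
  the L/θ intervals (a real-valued count; no flooring) exceeds Δt_max. The
  alternative reading 1 − P_d^(L/θ) is not a retention probability and does
  not reproduce the phase-diagram boundary positions the package's tests
  check (ν = 0.32 → ≈ 8.3 yr, ν = 0.88 → ≈ 4.4 yr, ν = 2 → ≈ 2.2 yr).
- **No truncation correction by default.** The Monte-Carlo engine samples
  the truncated law, whose conditional tail mass is larger by a factor
  1/Φ(1/ν) — about 1.45 at ν = 2, negligible below ν ≈ 1. A
  `truncation_corrected=True` mode divides the tail by Φ(1/ν) for
  sensitivity analysis. The residual discrepancy between engines at large ν
  (also driven by the truncated mean exceeding θ, which lowers the realized
  interval count below L/θ) is surfaced by `cross_validate` rather than
  silently absorbed; at K = 111 it stays within the 3·SE + 0.02 band at
  ≥ 95% of random sweep points.

P_r is evaluated in log space (`log1p`), so a tail of 10⁻⁹ over thousands of
intervals does not round to 1. At ν = 0, P_d is the degenerate limit: 0 for
θ ≤ Δt_max, 1 beyond.

## Sweeps and classification

Grids are evaluated exactly per cell (no interpolation of the P_r surface).
Default resolution is 50×50 over θ∈[1,20] × ν∈[0.1,2]; the loss-majority
panel tally over τ∈{1,2,4,8,16} × η_max∈{3,6,12,24,48,60} is 25/30 and is
unchanged at 25×25 and 100×100. Cells are classified loss when P_r < 0.5 —
the symmetric dichotomy point — with cells at 0.05 < P_r < 0.95 additionally
counted as a transition zone. The retention/loss boundary per ν row is the
linear interpolation in θ between the cells bracketing the chosen level
(default 0.5); non-monotone Monte-Carlo rows use the first crossing and are
flagged.

A note on transition-zone geometry: the zone's *τ-span* at fixed θ widens
monotonically as ν grows (stochasticity matters more), and tests assert
this. Its *θ-span* at fixed ν is not monotone — it first widens and then
narrows as the boundary θ itself contracts — so no such claim is made.

## Forgetting-time fitting

`fit_forgetting_time` fits r(t) = A·exp(−t/τ) by nonlinear least squares on
the original scale (scipy `curve_fit`, trust-region with τ bounded positive),
with A fixed at 1 unless `fit_amplitude=True`. A log-linear regression
supplies the initial τ; fitting on the original scale keeps noisy
near-zero retention values from dominating, which a log-scale fit would
amplify. Constant or increasing retention raises `NonIdentifiableError`.
Confidence intervals come from a seeded case-resampling bootstrap (1000
replicates by default, 2.5/97.5 percentiles); bootstrap replicates that are
themselves degenerate are dropped.

The synthetic generator emulates the structure of published skill-retention
studies: a known exponential decay sampled at a handful of follow-up times
with additive Gaussian measurement error, clamped to (0, 1]. It does not
emulate heteroscedastic error, floor effects from chance-level performance,
or participant dropout, so parameter-recovery results bound what the fitter
can do on clean data rather than guarantee performance on any particular
published study. Recovery tests use τ* = 2 years, 20 time points over
[0, 8] years (four forgetting times, the decayed fraction still well above
the clamp), and noise sd 0.05; the median recovered τ over 200 replicates is
within 10% of truth.

## Problem sizes and determinism

Monte-Carlo estimates default to K = 111 sequences; cross-validation uses 50
random parameter points at that K. Phase-diagram checks use the
deterministic closed form (1000-point θ axes for boundary extraction,
50–100 point axes for grids), so the headline quantities reported by
`scripts/acceptance.py` are seed-independent. All stochastic paths take
integer seeds and reproduce bit-for-bit.

## Known limitations

- The closed form treats the interval count as the fixed ratio L/θ; the true
  count is random, and at large ν the positive-truncation bias shifts the
  realized mean interval above θ. Cross-validation quantifies the resulting
  gap instead of correcting it, since the fixed-ratio expression *is* the
  model.
- The loss clock stops at the first cumulative time strictly beyond L;
  whether a use lands exactly on L is a measure-zero event under continuous
  intervals and is resolved in favour of retention.
- No spatial structure, inter-group exchange, or demographic turnover of
  experts.
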