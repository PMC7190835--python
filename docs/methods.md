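# Methods

This note records the scientific and numerical choices behind `tunedev`,
in enough detail to reproduce or audit any result the package computes.

## Model

The tunable expression system (TES) couples two transcription units: an
input promoter transcribes a toehold-switch mRNA `m` at `u_in`
transcripts/min, and a tuner promoter transcribes a trigger sRNA `s` at
`booster_factor * u_tun` transcripts/min. The sRNA opens the switch
hairpin by toehold-mediated branch migration, forming the complex `c`
that translates the reporter `p` efficiently; the closed switch
translates only at a leak rate. The mass-action network has ten
reactions:

```
∅ → m                u_in
∅ → s                booster_factor · u_tun
m + s → c            k_on
c → m + s            k_off
m → m + p            k_leak
c → c + p            k_act        (k_act ≥ k_leak)
x → ∅                δ_x + φ      for x in {m, s, c, p}
```

`δ_x` are first-order decay rates and `φ` is dilution by growth. Default
rates correspond to a 5-min mRNA half-life, fast sRNA turnover, a stable
reporter (removed only by dilution at a 30-min doubling time), and a
100-fold leak-to-activated translation span.

Promoter activities are expressed either in transcripts/min (RNAP/min)
or in relative promoter units (RPU); the configurable bridge factor is
79 RNAP/min per RPU.

### Parameter regimes

Three named presets cover the distinct operating regimes of the device;
they were fixed at design time, before the test suite existed:

- **`NOMINAL`** — weak binding (`k_on = 1e-4`), fast sRNA turnover
  (`δ_s = 0.693`/min). Sequestration stays sub-saturating across the
  whole tuner activity range (half-saturation of capture at
  `δ_m_tot · δ_s_tot / k_on ≈ 1100` RNAP/min, above the top of the
  standard tuner grid), so the deterministic response to the tuner is
  graded and the on/off fold change shrinks monotonically as the tuner
  rises.
- **`LOW_COPY`** — strong binding (`k_on = 0.05`, `δ_s = 0.231`/min) at
  copy numbers of a few molecules per cell. Output is dominated by
  translation from the bound complex, fluctuations are large, and
  raising the tuner both reduces cell-to-cell variability and makes
  nearby inputs more distinguishable. Used for single-cell (stochastic)
  studies.
- **`CHARACTERIZATION`** — intermediate binding (`k_on = 0.002`), used
  by the synthetic-data generator: the capture half-saturation sits in
  the middle of the standard input grid, so per-tuner response curves
  saturate within the measured range and their Hill transition points
  are identifiable from grid data.

The regimes are genuinely different operating points of the same model
class: no single parameter set exhibits all three behaviors — graded
fold-change monotonicity requires weak binding, while the single-cell
separability effect requires strong binding at low copy number.

## Deterministic solutions

**Steady state.** Summing the `m` and `s` balances eliminates the
bilinear binding term and gives `s` as an affine function of `m`.
Eliminating `c` through its own balance yields an effective irreversible
capture rate `k_eff = k_on · δ_c_tot / (k_off + δ_c_tot)` and reduces
the system to one scalar equation in `m` with a provable bracket
`[max(0, (u_in − u_s)/δ_m_tot), u_in/δ_m_tot]`. Brent's method solves
it, followed by four analytic Newton steps that push the residual to
machine level (~1e-13 relative); the remaining species follow in closed
form. A long-time stiff integration (LSODA) is the fallback whenever
the residual exceeds 1e-9 copies/min. The configuration
`k_on > 0, k_off + δ_c_tot = 0` is rejected: the complex would
accumulate without bound.

**Time courses.** ODE integration uses LSODA with tight tolerances
(rtol 1e-10). The delay-differential variant adds fixed maturation lags
on transcription and translation, solved with fixed-step RK4 and linear
interpolation into the stored history; with zero delays it reduces to
plain RK4.

**Gates.** The NOT gate reads the TES protein as repressor copies and
maps them through a repression Hill function onto the output promoter
(activity in RPU); `kappa_rt` models transcriptional read-through from
an upstream tuner unit. The tandem-promoter NOR gate is the NOT gate at
effective input `u_a + u_b`, symmetric by construction.

**Ribosome coupling.** The resource-coupled variant scales both
translation rates by `f = R_free/(K_rib + R_free)` where the free pool
solves `R_free = R_total − f·(host_demand + w·flux·f)` by damped
fixed-point iteration; only protein output shrinks, RNA species are
unaffected.

## Stochastic simulation

The exact engine is Gillespie's direct method over the same network,
with propensities using falling factorials. The approximate engine is
adaptive tau-leaping with the bounded-relative-change criterion on both
the mean and the variance of each species' propensity drift
(`ε = 0.03`), Poisson reaction counts, and step-halving on negative
excursions (states are never clipped). Near low-copy steady states the
selected leap can shrink below single-event spacing; when the chosen
`τ < 10/a₀` the engine takes a short batch of exact SSA steps instead
(the standard hybrid rule), which keeps low-copy ensembles ~15× faster
without biasing them. Paired tau-leap/SSA ensembles agree in all
species means within sampling error.

Ensembles start each cell at the deterministic steady state rounded to
integers, simulate 100 min, and collect either terminal protein copies
or the terminal instantaneous production rate
`k_leak·m + k_act·c` — the latter is the natural analogue of a
short-maturation fluorescence readout. Per-cell seeds are spawned from
one master seed via `numpy.random.SeedSequence`, masked to 31 bits.

## Distribution overlap

Distinguishability of two fluorescence (or ensemble) distributions is
the histogram intersection fraction: both samples are histogrammed on
shared edges — 256 bins spanning the pooled 0.1–99.9 percentile range,
log-spaced when strictly positive — normalized to unit mass, and the
overlap is `Σ_i min(x_i, y_i)` (1 for identical distributions, 0 for
disjoint). A literal per-bin quotient form `Σ_i min(x_i, y_i)/x_i` is
kept behind a flag for auditability; it is not bounded by 1 and is not
the default.

## Cytometry pipeline

Density gating bins asinh-transformed scatter channels (cofactor 150)
on a 1024×1024 histogram, smooths with a Gaussian kernel (σ = 10 bins),
scores each event by its bin's smoothed density, and keeps the top
`round(fraction · n)` events with stable tie-breaking, so gating is
deterministic. Autofluorescence correction subtracts the mean control
median and clamps non-positive results to a floor (0.01 a.u.) with a
flag. RPU conversion divides by the corrected median of the 1-RPU
standard.

Hill fits minimize least-squares residuals in log10(output) — medians
span decades, so this weights each decade equally. Fits are flagged
unreliable when the optimizer fails, the transition point leaves the
identifiable window `[min(x)/10, 10·max(x)]`, the data's monotonic
trend contradicts the requested orientation (Spearman check), or the
curve is too flat to constrain `K`; the `K`-range summary uses reliable
fits only and reports exclusions.

## Synthetic data generator

Event-level fluorescence is log-normal around the condition median
(`median · exp(N(0, log_sd))`, default `log_sd = 0.45`), so the
distribution median is exact; condition medians compose additively as
`true signal + autofluorescence` (default 3 a.u.). True signal medians
are the mechanistic model outputs under the `CHARACTERIZATION` preset,
bridged from RPU grids and scaled by a global gain (1 a.u. per protein
copy). Replicate noise is a batch effect: one multiplicative log-normal
factor (default CV 10%) per biological replicate, shared across the
grid, as when one culture day produces the whole condition grid.
Scatter channels come from a two-component Gaussian mixture in asinh
space (85% dominant cluster), with per-event cluster labels kept in the
truth manifest for gating-purity checks. Design variants are parameter
transforms: `booster` multiplies tuner transcription by 5,
`noninsulated` adds 0.5 RNAP/min of read-through flux to the input,
`combined` applies both.

The manifest records, per condition, the noise-free model output, the
replicate factor, the realized event median, the child seed, and — per
tuner level — the Hill fit of the noise-free response (the
identifiability target for recovery tests). The same spec and seed
always regenerate dataset and manifest bit-identically.

## Problem sizes and tolerances

Headline property checks use: closed-form limits at 1e-9 relative;
ensemble-vs-ODE species means at n = 2000 within 3 SEM; tau-leap vs
exact SSA at n = 500 paired runs within 3 SEM; single-cell separability
at n = 4000 cells per condition; the overlap oracle at 1e-12 absolute
over 1000 random histogram pairs; Hill-`K` recovery within 10% over 20
seeded datasets (3 replicates, 5% replicate noise, 10⁴ events per
condition), restricted to tuner levels whose noise-free truth fit is
itself identifiable; and the gating contract (`round(0.5·n) ± 1`
retained, ≥99% dominant-cluster purity) on two-cluster samples.
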