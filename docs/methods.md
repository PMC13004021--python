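# Methods

This note documents the models implemented in `kodep`, the assumptions
behind them, parameter defaults and their rationale, what the synthetic
generators do and do not emulate, the numerical choices, and the known
limitations. All quantitative statements here are properties the test
suite or `scripts/acceptance.py` actually computes.

## 1. Dilution model and the definition of overabundance

After an essential gene is knocked out, its protein is assumed stable
(no active degradation) and conserved through divisions, so the only
route to lower concentration is dilution by growth:

```
C(t) / C0 = V0 / V(t)
```

where `V(t)` is the total progeny volume (measured as area in microscopy)
and `V0` the progenitor volume at the knockout. Growth arrests sharply
when `C` crosses a functional threshold `CA`. The **overabundance**
`o = C0 / CA` measures the fold-excess the unperturbed cell keeps over
that threshold. Under steady exponential growth at rate `k0`,
`V(t) = V0 * exp(k0 t)`, so arrest occurs at `T = ln(o) / k0`, or
equivalently `o = exp(k0 T)`. Three phenotypic classes follow:

- **no effect** — nonessential under the growth condition; abundance in a
  pooled library tracks the library (`r(t) = 1`);
- **sufficiency** — essential with no spare capacity; depletion starts
  immediately (`r(t) = exp(-delta t)`);
- **overabundance** — essential with spare capacity; `r(t) = 1` until the
  arrest lag `T`, then `exp(-delta (t - T))`.

The three models are strictly nested with 0, 1 and 2 free parameters.

## 2. Pooled-library trajectory inference (`kodep.tfnseq`)

### 2.1 Data model and the shape likelihood

The input is a gene × timepoint read-count matrix with known column
totals. Naively, counts at time `t` are binomial with expected fraction
`f0 * r(t) / Z(t)` (`f0` the gene's initial library fraction, `Z(t)` the
library-wide normalization). But `f0` is a nuisance parameter whose
sampling noise at `t = 0` masquerades as a coherent shift of the whole
trajectory and inflates the no-effect test's type-I error far above its
nominal level. We therefore condition on the gene's **total** read count
across timepoints, which removes `f0` exactly: the conditional
distribution of the count vector is multinomial with weights
`totals(t) * r(t) / Z(t)`. The resulting "shape" likelihood has exactly
the stated 0/1/2 free parameters per model, and the no-effect null is
calibrated by construction (verified against exhaustive small-sample
oracles in the tests).

Genes whose `t = 0` count falls below `min_count0` (default 20) are
dropped and reported with a reason, never silently: their arrest lag is
unidentifiable at the library's depth.

### 2.2 Two-pass library normalization

Relative abundances are only defined up to the library composition: as
depleted genes vanish, the surviving genes' fractions rise even at
constant cell number. `fit_library` therefore runs two passes. Pass 1
fits all genes unnormalized; the genes retained as no-effect define
`Z(t)` as the inverse median of their observed relative abundance
(`Z(0) = 1`). Pass 2 refits every gene against `f0 * r(t) / Z(t)` and
makes the final calls. If no no-effect gene survives pass 1 — possible
when every retained gene depletes, since fractions sum to one and the
slowest depleter then looks flat — a warning is emitted and `Z = 1` is
used.

### 2.3 Model selection

Two successive likelihood-ratio tests at thresholds `alpha1`, `alpha2`
(both default `1e-4`, chosen so that a ~4000-gene genome yields less
than one expected false positive per stage):

1. no-effect null vs. the overabundance alternative. Because `delta = 0`
   lies on the boundary and `T` is then unidentified, the chi-squared(2)
   reference is wrong; we use the mixture `0.5 chi2(1) + 0.5 chi2(2)`,
   which is conservative relative to the exact chi-bar-squared weights.
2. sufficiency null vs. overabundance. Here the boundary is `T = 0`, and
   the null distribution is `0.5 chi2(0) + 0.5 chi2(1)` (a point mass at
   zero plus a half-chi-squared).

Retained nulls give `no_effect`; rejection of both gives
`overabundance` with `o = exp(k0 * T_hat)`. `k0` is a **required user
input** for absolute overabundances: relative abundances carry no
information about the absolute growth rate. Fits whose inner optimizer
fails are reported `unclassifiable`, never coerced. An estimated `T` at
the end of the sampled window is flagged `censored` (a lower bound).
An optional Benjamini–Hochberg adjustment can be applied to the
stage-1 p-values across the library; it is conservative (never produces
more no-effect rejections than the raw thresholds).

A model-free `halving_time` (first crossing of relative abundance 0.5,
log-linear interpolation between straddling timepoints) is reported
alongside the model-based quantities as a sanity check.

`replicate_error` merges per-replicate calls into per-gene mean and
spread of `log10 o`; genes missing from a replicate or discordant in
class are flagged, never imputed.

## 3. Single-cell landscape reconstruction (`kodep.singlecell`)

Microcolony movies are represented as a `LineageTree` of `CellTrack`s
(areas, optional fluorescence, strictly increasing times; division edges
checked for temporal consistency).

- `areal_growth_rate` is the windowed least-squares slope of `ln A(t)`
  (default window 5 frames, one-sided at track ends). It is exact on
  exponential tracks, which the tests verify to round-off.
- `relative_concentration` evaluates the dilution law `C/C0 = V0/V(t)`
  on the colony frame grid. With fluorescence recorded, the prediction
  matches the measured mean fluorescence concentration within the
  division-partitioning spread.
- `fitness_landscape` pairs every cell-frame growth rate with the
  colony dilution coordinate `C/C0` at that frame and fits a two-level
  changepoint model (growth plateau above the arrest concentration,
  arrest floor below) by least squares over the changepoint grid;
  `o_hat = 1 / c_hat`. If the movie ends before arrest, `o_hat` is the
  censored lower bound `V(t_end)/V0`. The reported plateau slope — the
  flatness diagnostic for the threshold model — is fitted only over
  `C/C0 >= 1.5 * c_hat`: rates within about half a smoothing window of
  the arrest frame average pre- and post-arrest growth and would bias
  the slope even under a perfectly flat plateau.
- `arrest_time` estimates arrest from either the total-area log-slope
  (**elongation**) or the cell-count log-slope (**septation**): the
  first time the rate falls below `frac * k0` (default 0.5) and stays
  below for `persist` frames (default 3). The count series is a
  staircase, so the septation slope uses a trailing window of one
  generation (`ln 2 / k0`) with the window lag subtracted; a colony
  whose divisions stop while elongation continues yields a septation
  arrest earlier than the elongation arrest, which the tests exercise
  on a handcrafted lineage.

## 4. Robustness–load trade-off (`kodep.rlto`)

Expression noise is modelled as a gamma-distributed protein level with
shape equal to the message number `mu_m` (the bursty-expression limit,
`CV^2 = 1/mu_m`). With mean expression `o` times the arrest threshold,
the per-cycle probability of falling below threshold is scale-free:

```
P_a(mu_m, o) = gammainc(mu_m, mu_m / o)      (regularized lower)
```

Fitness trades the metabolic load of expression against arrest risk:

```
F(o) = (1 - epsilon * o) * (1 - P_a(mu_m, o))
```

with `epsilon` the relative cost per unit of threshold-level expression
(default `1e-4`, the order of a low-expression essential gene's share of
the proteome; predictions are nearly insensitive to it — the tests show
the optimum moves by far less than a decade across three decades of
`epsilon`). `optimal_overabundance` maximizes `F` per grid point and
reports `mu_m_min`, the smallest admissible transcription level: the
smallest `mu_m` at which (a) the optimal strategy sustains the lineage
(`2 F(o*) > 1`, i.e. a division yields on average more than one
proliferating daughter) and (b) the noise model's cell-to-cell variation
does not exceed the mean (`CV <= 1`, the one-message threshold).

Two structural predictions are what the package quantitatively claims
(see §7): `o*` declines monotonically toward 1 as expression rises, and
at the lowest admissible expression the optimum exceeds a tenfold
excess. `overabundance_floor` (and `scripts/acceptance.py`) computes the
latter as the minimum `o*` over `mu_m` in [1, 2] and `epsilon` in
[1e-6, 1e-3].

## 5. Genome-scale synthesis (`kodep.compare`)

- `message_number` converts RNA-seq counts to messages per cell cycle by
  proportional allocation of a calibration total `M_total`; the
  estimates conserve `M_total` exactly.
- `merge_records` joins calls, message numbers and annotation; genes
  called sufficiency enter the overabundance distributions at `o = 1`
  exactly, no-effect genes carry none.
- `trend_bins` reports binned medians of the `(mu_m, o)` cloud with
  bootstrap percentile intervals (500 resamples, seeded), using either
  equal-count (quantile) or equal-log-width bins; empty log-width bins
  are dropped with a warning.
- `group_test` compares a gene subgroup's `log10 o` distribution to the
  reference by a two-sample Kolmogorov–Smirnov test (exact null for
  small samples; verified against full enumeration in the tests).
- `summary_stats` reports the median overabundance over essential genes
  with calls and the expression-weighted (`w = mu_m_hat`) mean — the
  metabolic-load view. A large median alongside a near-unity weighted
  mean is the signature of expression-dependent overabundance.
- `kde_overlay` is a Scott-bandwidth 2-D KDE on the log-log cloud for
  figures.

## 6. Synthetic generators (`kodep.synth`): what they emulate

`simulate_tfnseq` grows each mutant at `k0` until its arrest time
(`T = ln(o)/k0`), then at a small residual rate (default 5% of `k0`;
arrest is sharp but not perfectly degenerate), with lognormal initial
library abundances (sigma 0.5) and multinomial reads at fixed depth per
timepoint. `simulate_microcolony` implements the dilution model
literally: exponential area growth, division on area doubling with a
partitioning CV, conserved protein amount, sharp arrest at the
threshold. `simulate_rnaseq` draws multinomial reads proportional to
message numbers.

`simulate_genome` builds a genome in which essential genes follow the
optimal-overabundance curve at their own transcription level, with
lognormal scatter. Class assignment is coupled to expression: the
sufficiency fraction is taken from the genes whose predicted excess is
smallest — i.e. the highly expressed ones, whose optimum sits below the
assay's detection floor — and overabundance genes keep at least a
twofold excess (one doubling time of lag, the smallest excess the
trajectory assay resolves at the default schedule). This coupling is a
consequence of the trade-off model, not an independent choice: in an
optimal genome, "no measurable lag" and "high expression" are the same
genes. Four anchor genes (dnaA, dnaN, ftsN, murA) are pinned at fixed
transcription levels and classes.

**Not emulated:** read overdispersion beyond multinomial (the
`overdispersion` knob is reserved and must be 0), insertion-position
effects and polar effects on operons, protein degradation or
inheritance asymmetries beyond partitioning noise, time-varying `k0`
(media shifts), mapping/counting artifacts, and cross-replicate batch
effects (replicates differ only by seed).

## 7. Quantitative claims and how they are checked

The suite's acceptance tests pin down, among others: recovery of true
overabundances from simulated libraries to ~0.1 decade RMS; calibrated
(<= alpha-level) false-positive rates for the no-effect test against
its nominal threshold; single-colony `o_hat` recovery within 0.05
decades noise-free; exactness of the conservation/dilution/rate laws to
round-off; agreement of the likelihood and KS machinery with exhaustive
brute-force oracles; monotone decline of `o*` to within 30% of 1 at
`mu_m = 1000`; a floor above tenfold at the lowest admissible
expression; and the median-vs-weighted-mean signature at genome scale.

## 8. Parameter defaults

| Parameter | Default | Rationale |
|---|---|---|
| `k0` | 1 /h | fastest A. baylyi-like doubling (~40 min); always user-supplied for real data |
| `timepoints` | 0..12 h every 2 h | resolves lags up to ~4 doublings; `T` beyond the window is censored |
| `depth` | 1e6 reads/timepoint | pushes counting noise below the model-selection thresholds for a 200–4000 gene library |
| `min_count0` | 20 | below this, the arrest lag is unidentifiable; dropped genes are reported |
| `alpha1`, `alpha2` | 1e-4 | < 1 expected false call per stage on a ~4000-gene genome |
| `residual_rate` | 0.05 | sharp-but-finite arrest; exactly 0 makes `delta` degenerate |
| `partition_cv` | 0.05 | typical division asymmetry of rod-shaped bacteria |
| `epsilon` | 1e-4 | order of a low-expression essential protein's proteome share; predictions insensitive across 1e-6–1e-3 |
| `window` (single-cell) | 5 frames | smallest window giving exact rates on exponentials while smoothing frame noise; results stable to doubling it |
| `frac`, `persist` | 0.5, 3 | arrest = rate persistently below half the plateau rate; `persist` rejects single-frame dips |
| `M_total` | 4000 /cycle | calibration total for message numbers; scales `mu_m_hat` linearly |
| `n_boot` | 500 | percentile CIs stable to ~bin-median resolution; seeded |

## 9. Numerical choices

- Trajectory fits profile `T` on a 0.2 h coarse grid refined to 0.01 h,
  with bounded scalar minimization of `delta` at each `T`
  (`xatol = 1e-6`); the nested special cases (`delta = 0`, `T = 0`) are
  always included as candidates, guaranteeing the likelihood ordering
  `no_effect <= sufficiency <= overabundance` that the LR tests assume.
- The fitness maximization uses a 600-point log-grid on `[1, 1/epsilon]`
  followed by bounded golden-section refinement; unimodality is checked
  on the coarse grid and the global maximum taken (with a warning) if it
  fails. Verified against a dense-grid oracle to 2e-3 in `log10 o`.
- `P_a` uses `scipy.special.gammainc` directly (scale-free form); tests
  validate it against the integer-shape closed form and Monte-Carlo.
- All pipeline randomness is funnelled through per-stage seeds derived
  from one config seed; rerunning an identical config reproduces every
  output byte-for-byte, and the manifest records the config SHA-256 and
  all derived seeds.

## 10. Limitations

- The trade-off module is a structural reconstruction, not a fit to
  data: its claims are bounds and monotonicity properties, not exact
  values, and the cost term is linear in `o` by assumption.
- Overabundances above `exp(k0 * t_max)` are censored; the library assay
  cannot distinguish "very overabundant" from "nonessential" beyond the
  sampled window.
- `o` below ~2 is generally not resolvable by the trajectory assay at
  the default schedule; such genes are called sufficiency.
- The shape likelihood conditions away the initial fraction, so
  absolute fitness costs of insertions (constant offsets in abundance)
  are invisible by design.
- Library normalization assumes a detectable no-effect cohort; in
  libraries where every gene depletes, `Z = 1` is used with a warning
  and lags are biased toward larger values.
- The gamma noise model treats `mu_m` as the shape parameter exactly;
  for `mu_m < 1` the admissibility rule (CV <= 1) excludes the regime
  where that identification is least defensible.
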