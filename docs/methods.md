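# Methods

This note documents the statistical procedures `sleepbouts` implements, the
choices made where the design was genuinely open, and what the synthetic-data
generator does and does not establish.

## Data model

A **hypnogram** is a sequence of vigilance-state labels, one per fixed
scoring epoch (default 4 s), for one subject under one treatment. Raw labels
are AW, PW, S1, S2, IS, REMS; the non-REM superset is {S1, S2, IS}. Epochs
are 0-based and an epoch covers the half-open interval
`[i·epoch_seconds, (i+1)·epoch_seconds)`. Epoch indices must be contiguous
within a recording; gaps are an error, never imputed — silent gap-filling
would corrupt bout lengths.

A **bout** is a maximal run of identical state. Segmentation is run-length
encoding, so bout invariants (alternating states, lengths summing to the
recording length) hold by construction. REM bouts with ≤4 epochs (16 s) are
relabelled `REMS_S`, longer ones `REMS_L`; downstream analyses treat the two
as distinct states because their succession behaviour differs (long REM is
typically followed by IS; short REM is not).

## Time binning

The 3-h analysis window is split into three hourly bins (900 epochs each).
A bout belongs to the bin containing its **onset**; a bout spanning a bin
boundary is counted once, in its onset bin, and contributes its full
duration there. No splitting rule is imposed because counts must stay
integral for the count regression; the final, possibly truncated bout of a
recording is kept as-is (no censoring adjustment). Transitions are assigned
to the bin of the **successor** bout's onset, consistent with bout binning.

## NREM latency

Latency is the time from drug administration to the onset of the first
qualifying NREM episode. Scanning starts at the treatment epoch; a candidate
episode begins at the first NREM epoch. The episode *fails* the moment a
consecutive non-NREM run exceeds 14 epochs or cumulative non-NREM content
exceeds 60 epochs (240 s) — failure is strict (`>`), and the scan resumes
after the run that caused it. It *qualifies* the moment its NREM content
reaches 45 epochs (3 min). Two readings of the 3-min clause are possible:
NREM content only, or wall time including interruptions. The default counts
NREM content only, because the interruption budget (240 s) exceeds 3 min and
a wall-time reading would let an episode qualify while mostly awake; the
alternative is available via
`LatencyParams(episode_length_counts_interruptions=True)`. Returns `None`
("not reached") if no episode qualifies.

## Count model (bout-frequency ratios)

Counts per subject × treatment × state × bin are zero-filled (a state that
never occurs contributes structural zeros) and modelled per state with a
log-link negative binomial (NB2) regression: treatment and bin as unordered
categorical fixed effects, subject as a **fixed blocking effect**. The
exponentiated treatment coefficients are multiplicative frequency ratios
versus vehicle, reported with 95% Wald CIs.

Choices:

- **Subject as fixed, not random.** With six subjects a random intercept is
  numerically fragile in NB models and the estimand (within-subject dose
  ratio) is unchanged; this is a deliberate approximation of the mixed
  formulation.
- **Dispersion** is estimated by maximum likelihood. When the data are
  near-Poisson the NB dispersion estimate pins at ~0 and its likelihood
  surface degenerates; the fit then falls back to Poisson with a
  `RuntimeWarning`. Ratio estimates are essentially unaffected (the mean
  model is identical); CIs may be slightly narrower.
- **Boundary cases.** A dose whose counts are all zero (or a comparison
  against an all-zero vehicle) lies on the boundary of the parameter space
  where optimisation fails; such doses are flagged `not estimable` rather
  than fitted.
- Only Wald CIs are provided; no multiplicity adjustment is applied (the
  two-step test strategy — overall F, then per-dose contrasts — controls the
  overall type I error).

## Duration model

Durations are heavily right-skewed and modelled on the log scale:
`log(duration) ~ treatment * bin + subject` (all categorical). The
time × treatment interaction is tested by comparing the full model against
the additive one via the ratio of residual mean squares, which follows an
F distribution under the null. Cell-wise predicted mean log-durations
average the subject effect across subjects (so cells are comparable between
treatments) with 95% t-based CIs; back-transform with `exp` for seconds.
Empty cells are reported missing and the model is fitted on the remaining
data. Degenerate constant data (zero residual variance in both models) is
reported as F = 0, p = 1. The model is equivariant under duration rescaling:
multiplying all durations by *c* shifts every predicted log-mean by log *c*
and leaves the F statistic unchanged (verified by property test).

## Transition heatmaps

For each treatment × hour, consecutive bout pairs within each subject are
pooled into a K×K table `O` (pairs never cross subjects; at n = 6 subjects,
per-subject hourly tables would be almost entirely masked, so pooling is the
default and per-subject tables are a matter of calling `cross_tabulate` per
subject). The diagonal is structurally zero.

Expected counts use the naive independence product over the **full table
including the zero diagonal**: `E = outer(R, C) / N`. The default residual
is the Pearson form on counts, `z = (O − E)/√E`; an `adjusted` form divides
by `√((1 − R_i/N)(1 − C_j/N))`, and a probability-scale variant
(`on="probabilities"`) rescales z by `1/√N` for readers who think in
transition probabilities — the familiar ±2 rule presumes the count scale.
Cells are masked (rendered gray, z undefined) on the diagonal and wherever
the **observed** count is below 5; masking on expected counts is available
via `on_expected=True`.

**Known miscalibration under the null.** Because the diagonal is structural
rather than sampled, the independence product systematically misallocates
the diagonal's expected mass to off-diagonal cells: under a no-preference
generator each unmasked cell's z is shifted by roughly
`√E_ij · (q_i + p_j − d)` (p, q the source/destination frequencies, d their
overlap), which grows like √N. At N ≈ 2000 and K = 6–7 this inflates the
share of |z| > 2 cells to ~15–30% even with no real preference structure.
The heatmap is therefore an **explorative** tool: the ±2 shading is a
large-sample rule of thumb, not a calibrated test, and the proper null for
zero-diagonal tables (quasi-independence fitting) is intentionally out of
scope. Planted preferences of realistic size (≥2–3× a cell's baseline rate)
produce residuals far above this structural bias and are detected reliably.

Rendering: diverging colormap symmetric about 0 (shared limits across the
3×3 panel grid, set by the largest unmasked |z|), gray masked tiles, rows =
current state (Y), columns = next state (X). Exported CSVs serialize z with
`%.17g`, which round-trips float64 exactly (read with
`float_precision="round_trip"`).

## Synthetic studies

The simulator is a semi-Markov chain per recording: the next state is drawn
from the current hour's embedded transition matrix (zero diagonal, rows
summing to 1), the bout length from the state's dwell law, until 2700
epochs (3 h) are filled; the final bout is truncated. Regime changes at the
hour boundaries (epochs 900, 1800) take effect at the next transition; a
bout in progress keeps its drawn dwell.

- **Dwell law:** a two-component mixture of geometrics on {1, 2, ...}
  ("spike and slab"): with probability `p_short` a draw from a short-mean
  geometric, else from a long-mean one. Geometric components are the
  maximum-entropy memoryless choice and make the mixture mean analytic
  (`p·m_s + (1−p)·m_l`), which the tests exploit. Default mixtures (e.g. AW:
  60% short bouts of mean 8 s plus long bouts of mean 160 s; REM: 55% short
  of mean 8 s plus long of mean 88 s) give right-skewed, bimodal length
  histograms of the kind observed in rat vigilance data, with the REM split
  at 4 epochs well separated.
- **Treatment mechanism:** dwell mixtures are shared across treatments;
  doses act only on the transition matrices (column tilts toward AW,
  starving IS/S2/REM, applied by `tilt_matrix`). This encodes the
  hypothesis that the drug alters switching frequency, not state
  maintenance; `dwell_scale` simulates the alternative duration mechanism
  for power comparisons.
- **Determinism:** the whole study is a pure function of the config seed;
  per-recording seeds are `crc32("seed:subject:treatment")`, so adding
  subjects or treatments never perturbs existing recordings.
- The default matrices are qualitative mimics (vehicle: AW↔PW↔S1→S2 traffic
  with S2→IS→REM returns and a mild circadian drift; doses tilt toward
  wake). They are **not** estimates of any animal's physiology, so a green
  end-to-end test establishes that the pipeline recovers planted structure
  of realistic magnitude — not that it reproduces any particular animal
  study's effect sizes.
- Not emulated: continuous circadian modulation, EEG waveforms,
  concentration–effect coupling, inter-subject heterogeneity in transition
  structure (subjects differ only by seed).

## Pharmacokinetic decline utility

For a one-compartment model with first-order elimination, the relative
decline over t hours at half-life T is `100·(1 − 2^(−t/T))` percent. At
T = 22 h and t = 3 h this is ≈9.0%, small enough to treat plasma levels as
constant over a 3-h observation window. `duration = 0` returns 0 (no
elapsed time) rather than an error.

## Numerical notes

- State labels are case-insensitive on read, upper-case on write; every
  unrecognised label (including single-character corruptions) is rejected
  with its row number.
- Percent-time conservation (summing to 100) holds exactly up to float
  rounding because counts are integers divided by a common window length.
- `z_statistics` leaves cells with E = 0 as NaN (no information), distinct
  from masking, which is a reporting decision.
- CSV outputs of the pipeline are byte-deterministic for a fixed seed and
  configuration; the run log records parameters, seed and library versions
  but no timestamps.
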