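# Methods

## Scope and model

dielkit analyses bulk expression time courses sampled on an even ZT grid
(default: 48 h every 4 h, ZT0–ZT44). The working model is a per-gene
additive signal

    y_g(t) = baseline + amplitude · w_g(t) + ε,   ε ~ N(0, σ²) i.i.d.

where `w_g` is a periodic unit-amplitude waveform from one of five shape
families. Rhythm detection asks whether `y_g` is better explained by some
waveform than by exchangeable noise; phase estimation reports the
waveform's peak time.

## Waveform families

All shapes peak at `t ≡ phase (mod period)`:

- **cosine** — `cos(2π(t − phase)/period)`;
- **spike** — 1 at the grid position nearest the phase within each cycle
  (ties resolve to the earlier position), 0 elsewhere;
- **box** — indicator of the half-open half-period `[phase,
  phase + period/2)` on the circle (half-open so grid membership is
  unambiguous);
- **ramp_up / ramp_down** — sawtooths rising to, or decaying from, their
  maximum at the phase over one period.

## Pattern-matching detector

The model library is every (shape, integer phase 0–23) combination at
period 24 h — 120 patterns on the default grid; patterns that are
constant on a given grid are dropped with a warning. Each gene is
regressed on each pattern by OLS and scored by the signed Pearson
correlation with the best pattern (first maximum wins ties, i.e. shape
order then lower phase; constant genes score r = 0). Only r > 0 fits are
eligible.

The call criterion is conjunctive by default: `r ≥ max(c, r*)` with fixed
cutoff c = 0.81 and r\* the permutation threshold — the 95th percentile
(for the default top-q with q = 5) of the pooled null distribution of
best-pattern correlations obtained by independently shuffling each row's
time labels (default 200 rounds, seeded). Because "top 5%" can also be
read as the top 5% of genes ranked by correlation, that reading is
available as `criterion="top_fraction"`, alongside `cutoff_only` and
`permutation_only`; the conjunction is the default because it is the
stricter reading. An optional min-fold-change filter exists but is off
by default. Calls are affine-invariant per gene (correlation ignores
gene-wise scale and offset).

## Rank-concordance detector

Reference orderings are the average ranks of `cos(2π(t − lag)/period)`
on the grid, for periods {20, 24, 28} h — the grid-representable periods
within the conventional 20–28 h search window on a 4 h grid — and one lag
per timepoint within each period (5 + 6 + 7 = 18 combinations). The test
statistic is Kendall's S; pairs tied in either vector contribute 0.

The exact null pmf of S under uniformly random untied data is computed by
generating-function convolution: with the reference's tie-group sizes
(n₁, …, n_k), the concordant-pair count is distributed as the
Jonckheere–Terpstra statistic, whose generating polynomial is the
Gaussian (q-)multinomial coefficient built by exact integer polynomial
arithmetic (guarded at n ≤ 60). The pmf is symmetric about 0 and the
test is two-sided on |S|: a strong *anti*-concordance is a rhythm peaking
half a period from the lag, and such calls report phase
`lag + period/2 (mod 24)`; all other calls report `lag (mod 24)`.
Winning (period, lag) is the first maximum of |S| in (period asc, lag
asc) order. P-values are Bonferroni-multiplied by 18 and compared to
alpha = 0.05.

The null assumes untied data; observed ties (exactly periodic repeats,
integer-valued inputs) only shrink |S|, making the test conservative —
a documented limitation, not a correction.

## Circular phase arithmetic

Phases live on a 24 h circle. The circular mean is the direction of the
summed unit vectors; this automates the dawn-aware manual rule (ZT2 and
ZT22 average to ZT0). A perfectly antipodal set has no mean direction;
the smaller input phase is returned with an explicit tie flag (and a
warning) for determinism. The dawn adjustment for pair tables adds 24 h
to the smaller member of any pair differing by more than 12 h (strictly
greater), extending the scale past 24; R² between two phase columns is
ordinary Pearson on the adjusted values. Note the adjustment is not
correlation-neutral: for *independent* uniform phases it induces a
baseline adjusted R² of ≈ 0.39 (Monte-Carlo), so adjusted R² separates
concordant (≈ 1) from discordant tables but its floor is not 0.
Histogram and contour-grid bins are half-open `[lo, lo + bin)` labelled
by the lower edge.

## Identifier collapsing

Transcript-level calls merge into gene records via a many-to-many
transcript→gene table: phases merge by circular mean; a transcript with
k gene targets feeds k records; unmapped transcripts are dropped and
counted. When members disagree on period or shape the modal value wins,
ties preferring the pattern-matching entry then the lower period (a
package design choice made for determinism — the merge rule is not
externally prescribed). Ortholog joining takes the deduplicated union of
targets; reports reconcile input = mapped + unmapped exactly. Mapping
tables are user-supplied TSV; there are no live annotation-service
queries, keeping runs hermetic.

## Plex normalization

Bead-plex readings normalize in a fixed order: average technical
replicates → subtract background (a per-plate scalar, or per-gene if
supplied) → divide by the same-sample background-subtracted value of the
designated reference gene. A non-positive reference value is a hard
error naming the sample; negative post-subtraction values elsewhere are
floored at 0 and counted. Trough-vs-acrophase differences use Welch's
unequal-variance t-test (robust for duplicate-level group sizes; the
timepoint sets defining troughs and acrophases are explicit arguments,
not inferred). Degenerate identical groups return p = 1 by convention.

## Synthetic data

The generator emulates the study conditions the detectors assume: a
12-point 4 h grid, a configurable rhythmic fraction (default 0.11,
matching the ~11% union rate such liver surveys report), a
cosine-dominated shape mixture (0.6/0.1/0.1/0.1/0.1), period 24 h by
default (20/28 h available), phases uniform over the day or drawn from
wrapped-normal clusters, amplitude 1 on a log-intensity-like baseline of
8, and i.i.d. Gaussian noise with SD 0.25 (noise/amplitude well inside
the regime where phase recovery is reliable). `phase_grid` optionally
snaps true phases to a lattice for exact-recovery experiments.
Comparative scenarios place shared genes in two datasets with a
controlled circular phase shift and exclusive genes rhythmic in exactly
one dataset.

What it does **not** emulate: probe-level noise, array normalization
artefacts, batch effects, autocorrelated noise, amplitude heterogeneity
or missing values. Passing tests therefore demonstrate correctness of
the statistics under the stated model, not robustness to every failure
mode of real array data.

## Numerical and design choices

- Jaccard indexes round half-up to one decimal; genome fractions half-up
  to one decimal (printed as integers where they land on one).
- Detection and comparison are deterministic given a seed; the only
  stochastic component is the permutation threshold (seeded generator).
- Tie-breaks everywhere resolve to the earlier/lower candidate (pattern
  order, lag order, smaller phase) so repeated runs are byte-identical.
- Problem sizes in the test suite (≤ 1000 genes for error-control
  checks, 200 permutation rounds, 5000 genes for the p-value
  super-uniformity check) were chosen as the smallest sizes at which the
  binomial/Monte-Carlo error bands are meaningfully tight.
- Hard errors over silent repair: ragged tables, unparsable cells,
  duplicate ids, non-monotone grids and missing values all raise; the
  detectors assume complete, evenly sampled series.
- Two-day series may be supplied either as 12 distinct columns spanning
  48 h or as longer grids; the readers accept any evenly spaced strictly
  increasing ZT header (ZT/CT/LD dialects, LD offset configurable).

## Known limitations

- The pattern library is the five named shape families at period 24 h
  only; multi-period pattern libraries and 12 h harmonics are out of
  scope.
- Exact null computation assumes ≤ 60 timepoints (integer polynomial
  convolution cost grows quickly beyond).
- Four-or-more-set Venn partitions are handled as nested pairwise
  partitions, not as a joint decomposition.
- The adjusted-R² floor for unrelated phase tables (≈ 0.39, above)
  means absolute values of adjusted R² should be compared against that
  baseline, not against 0.
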