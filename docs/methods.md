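# Methods

## The classifier

A *grade signature* is a pair of disjoint probe sets: `g3_up` (expression
increased in high-grade tumours) and `g1_up` (increased in low-grade
tumours). For one expression profile with *n* probes, every probe is ranked
within the profile — 1 for the lowest value, *n* for the highest, with tied
values receiving mid-ranks — and the ranks of the two signature sets are
averaged separately. The set with the higher mean rank determines the
binary genomic grade (G3-like vs G1-like).

The estimator uses nothing outside the single profile. Consequences, all
verified by the test suite:

* **Monotone invariance** — any strictly increasing transform of the
  values (log, affine with positive slope, exponentiation) leaves the
  ranks, and hence the call, unchanged. The input matrix may be on any
  monotone expression scale.
* **Single-sample property** — adding, removing or rescaling other samples
  in a matrix cannot change a given sample's call.
* **Rank-sum conservation** — mid-ranks preserve `sum(ranks) =
  n(n+1)/2`; this is why mid-ranks were chosen for ties (the convention
  also preserves monotone invariance, which "first-occurrence" tie-breaking
  would not).

Numerical conventions:

* Ranking is over **all probes on the supplied matrix**, not only signature
  probes; *n* is the matrix's probe count, not a hard-coded chip size.
  When no signature probes are missing, the G3-vs-G1 comparison is the same
  either way; with missing probes the two choices can differ, and ranking
  over the whole platform is the definition used here.
* **Missing signature probes**: means are taken over the intersection of
  the signature with the platform, with the per-set counts reported in the
  call (`n_used_g3set`, `n_used_g1set`). Each set must retain at least
  `min_coverage` (default 0.5) of its probes or classification refuses to
  run.
* **Exact tie** of the two mean ranks (measure zero on continuous data):
  the call is G3, `tie_flag` is set, and a warning is emitted, so output is
  deterministic while callers can treat flagged calls as unclassifiable.
* `score = (mean_rank_g3set − mean_rank_g1set)/n ∈ (−1, 1)` is a
  **non-canonical** convenience margin; the method proper uses only its
  sign.

## Calibration (signature rebalancing)

The sign comparison implicitly assumes that, in grade-neutral tissue, the
two sets would sit at comparable average rank. If the `g1_up` probes are
systematically more expressed than the `g3_up` probes, every sample's G1
mean rank is inflated and calls are biased toward low grade. The imbalance
is diagnosed on a calibration cohort via the **grand mean rank** of each
set (mean over samples of the set's per-sample mean rank) and its
difference `delta`; the bias report also carries the fraction of samples
called G3.

Correction prunes probes from the **larger** set (pruning can only raise
the survivors' mean rank):

* `balance_by_count(matrix, sig, k)` removes the `k` probes with the lowest
  **cohort mean rank** (mean over samples of the probe's within-sample
  rank) in one batch.
* `balance_to_parity(matrix, sig, tol)` removes one lowest-ranked probe at
  a time, recomputing `delta` after each removal, until `|delta| ≤ tol`
  (default 1% of *n*), a floor of half the set's original size is reached
  (reported via `floor_reached`, not an error), or a removal would move the
  two sets further apart.

Design choices worth making explicit: "lowly expressed" is operationalised
as lowest cohort mean rank — scale-free and consistent with the method's
rank logic, since no expression-intensity threshold would survive the
monotone-invariance guarantee; ties in cohort mean rank break
lexicographically by probe identifier for reproducibility; and calibration
is a **training-time** activity — the rebalanced signature is frozen and
reused, classification never re-calibrates on new data. The parity stopping
rule is this package's formalisation; the published optimisation reports
only the removal count and rationale, so neither entry point claims to
regenerate a specific historical probe list (the bundled 91-probe fixture
stands in for that result).

## Evaluation

* **Agreement table**: genomic calls (2 rows) × histological grade
  (3 columns), with percentages computed within each histological column.
  Display rounding follows the published convention: nearest integer at
  ≥ 10%, one decimal below 10%, halves to even — the rule that reproduces
  every printed cell of the five-cohort agreement table bundled with the
  package, including its half-percent cases (62.5→62, 37.5→38, 87.5→88).
* **Pooled G1/G3 accuracy**: (histological G1 called G1 + histological G3
  called G3) / (all histological G1 + G3). Histological G2 is excluded
  because it has no binary ground truth; this pooling rule is inferred — it
  reproduces the published 88/97/88/78% accuracies from the printed counts
  (the arithmetic is re-run in the tests and the acceptance script).
* **Survival**: Kaplan–Meier product-limit curves and the standard
  unweighted two-group log-rank test (df = 1), both computed via
  `lifelines` behind the module surface; tied event times use the usual
  aggregated-increment convention. `stratify_g2` restricts to histological
  G2 samples, splits them by genomic grade, and returns both curves plus
  the log-rank comparison — the clinically motivating question of whether
  intermediate-grade tumours separate into distinct-prognosis groups. A
  stratum with fewer than two events triggers a low-power warning; an
  empty stratum is an error.

## The simulator

`simulate_cohort` emulates the data-generating structure the method
assumes, on an abstract log2-like scale:

* every probe gets a fixed per-probe **baseline** ~ N(0, `baseline_sd`²),
  shared by all samples. Default `baseline_sd = 2.0`, a typical spread of
  log2 expression levels. Baselines matter: without them "lowly expressed
  probes" would not exist and rebalancing would have nothing real to act
  on;
* per-sample noise is i.i.d. N(0, `noise_sd`²), default `noise_sd = 1`;
  the classifier is rank-based, so the distributional family is immaterial
  and Gaussian is chosen for simplicity;
* `g3_up` probes are shifted up by `effect_size · noise_sd` in samples with
  high-grade biology; `g1_up` probes likewise in low-grade-biology samples.
  Default `effect_size = 2`; acceptance runs use 3 (a strong, cleanly
  separable signature);
* `g1set_baseline_offset` (default 0) adds a constant to all `g1_up`
  probes in every sample, reproducing the expression imbalance that the
  calibration module corrects;
* histology: fractions 0.25 / 0.50 / 0.25 for G1/G2/G3. Histological G1
  and G3 have concordant biology by construction (they are treated as
  ground truth for accuracy); each histological G2 tumour carries
  high-grade biology with probability `g2_highlike_fraction` (default 1/3,
  the "about one-third" split reported for intermediate-grade tumours);
* survival: exponential event times with rate `hazard_low = 0.05`/year for
  low-grade biology and `hazard_high = 0.15`/year for high-grade
  (hazard ratio 3; 10-year event fractions ≈ 39% and 78%), administratively
  censored at `censor_time = 10` years. This is the simplest model that
  makes KM/log-rank analysis exercisable, not a claim about real
  breast-cancer hazards.

What the simulator deliberately omits: correlated gene modules, batch
effects, probe saturation, missing values, non-administrative censoring,
and any cross-platform identifier issues. Passing tests on simulated data
therefore demonstrate the *statistical logic* of the method — rank
arithmetic, bias correction, mixture recovery, survival separation — not
its accuracy on any real platform.

All randomness flows from one integer seed through
`numpy.random.default_rng`; identical seeds give bit-identical cohorts for
a fixed numpy version (generator-stability caveat: numpy guarantees stream
stability within, not necessarily across, major versions).

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` use cohorts of 200–300 samples
(≈ 1,000 background probes) for recovery and survival checks, 21,000
light-weight samples (8 background probes) for the G2 mixture fraction, an
exhaustive rank check over all value vectors of length ≤ 8 on a 3-letter
alphabet plus 10,000 random tied vectors, and 1,000 null replicates for
log-rank calibration — sizes chosen so the whole suite completes in well
under a minute of compute per component while keeping Monte-Carlo intervals
tight enough to be meaningful.

## Known limitations

* The bundled original/optimized signatures are synthetic stand-ins
  (structure, not identity, of the published lists); grading real arrays
  requires supplying the real probe lists.
* Sensitivity to systematic average-expression differences between the two
  sets is inherent to the sign rule; calibration mitigates but — when the
  pruning floor is reached — cannot always eliminate it.
* The binary call has no "intermediate" output by design; borderline
  samples (|score| near 0) are still assigned a side, and only `tie_flag`
  marks exact ties.
* Percentage display rounding (half-even, decimal below 10%) is an
  inferred convention; it reproduces all bundled printed cells but is not
  an authoritative specification.
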