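# Methods

## The measure

Let a dyad have sessions x = 1..n. Each session contributes two
*sub-transcripts*: the therapist's pooled language T_x and the client's
pooled language C_x. Each sub-transcript is represented by a 4-vector
of summary variables (analytic, clout, authentic, tone), each on a
0–100 scale. The 2n × 4 matrix is standardized per variable (z-scores
over the dyad's pooled rows) and partitioned with k-means. Session x is
*synchronized* iff T_x and C_x are assigned to the same cluster. The
dyad-level outcomes are the synchronized set, the percentage
100·|{x : sync}|/n (reported to one decimal), and the run-length
structure of the flags over time.

The measure is relative by construction: clusters delineate contrasts
*within* one dyad's treatment span, so percentages are comparable
across dyads only as summary descriptions, not as scores on a common
scale. All outcomes are invariant to cluster relabeling, row order, and
variable order.

## Scoring model

Word categories come from a user-supplied `.dic` dictionary: literal
words and `stem*` prefix patterns (case-insensitive; a token may count
toward several categories, at most once each). A text's category score
is the percentage of its tokens matching that category. Summary
variables are signed compositions

    value = clamp(offset + Σ_pos pct(c) − Σ_neg pct(c), 0, 100),  offset = 50

with the published sign structure per variable (analytic: +articles,
+prepositions, −pronouns, −auxiliary verbs, −conjunctions, −adverbs,
−negations; clout: +we, +you, −tentative; authentic: +i, +third-person
pronouns, +exclusive, −negative-emotion, −motion; tone:
+positive-emotion, −negative-emotion). The commercial tool that
popularized these variables additionally normalizes against proprietary
corpora; that step is unpublished and deliberately not imitated, so
absolute scores from this scorer are not comparable with that tool's
output. Pipelines that need published-tool scores feed them in as CSV —
the packaged demonstration fixtures are exactly such a table. Empty
sub-transcripts score the scale midpoint (50) on every variable and are
flagged degenerate.

Tokens are maximal runs of letters/digits with internal apostrophes,
lowercased; punctuation is discarded; bracketed transcription
annotations (`[...]`, `(...)`) are stripped before tokenization.

## Preprocessing

- **z-scoring** (default on) uses the sample SD (ddof 1) per variable
  over the dyad's pooled 2n rows. The choice of sample vs. population
  SD rescales every column by the same factor and cannot change any
  clustering outcome; it only changes the units of reported centers.
- **Per-speaker mean-centering** (default off) subtracts each speaker's
  own per-variable mean before z-scoring, for analyses that want to
  remove stable between-person style differences. It is off by default
  because the co-membership measure is precisely about whether those
  differences dominate; centering answers a different question.

Zero-variance variables abort with a degeneracy error rather than
silently producing NaNs.

## Clustering and the number of clusters

k-means uses k-means++ initialization, 50 restarts (best distortion
wins), Lloyd iterations to the assignment fixpoint or 300 iterations,
and a fixed seed (default 0); identical inputs and configuration give
bit-identical solutions. Distortion is the standard inertia (sum of
squared Euclidean distances to assigned centers). scikit-learn's KMeans
provides the optimizer; an exhaustive set-partition oracle
(`brute_force_kmeans`, capped at 10 rows and k ≤ 3) verifies in tests
that the restarted optimizer attains the global optimum on small
instances.

The elbow scan computes distortion for k = k_min..k_max (default 1..10,
capped at 2n−1). The elbow is operationalized as the k maximizing the
discrete second difference d(k−1) − 2d(k) + d(k+1), ties to the
smallest k. A scan whose maximal curvature is below 5% of the total
distortion drop is flagged "flat" (no clear elbow) with a warning. A
non-increasing distortion sequence is enforced by re-running offending
k values with 5× restarts.

Elbow reading is ultimately a judgment call: the demonstration analyses
chose their cluster counts (3, 2, 2 for dyads A, B, C) by visual
inspection, and for dyad A — whose distortion curve decays smoothly —
the second-difference rule prefers k = 2 instead of 3. The pipeline
therefore records the automatic choice but accepts an explicit `--k`
override (the route used when reproducing the published outcomes).
At k = 1 the measure is degenerately 100%; such solutions carry an
explicit degeneracy warning in the report.

Cluster validation follows the published practice: the k × 4 table of
per-cluster variable means ("cluster centers", in standardized units)
plus pairwise center distances as a separation diagnostic, and a 2-D
principal-component projection of the rows (top-2 right singular
vectors of the column-centered matrix; the largest-magnitude loading of
each component is made positive so projections are reproducible).

## Synthetic data

`simulate_token_stream` draws each token multinomially: with
probability rate(c) a uniformly chosen literal representative of
category c, otherwise a filler word constructed to match no dictionary
pattern. Scored percentages converge to the planted rates at the usual
binomial √(p(1−p)/N) speed, which the calibration tests rely on.

`simulate_profiles` plants per-session synchrony in a dyad profile
matrix. Each session is synchronized with probability `planted_rate`.
A synchronized session has **one shared profile**: a single draw from
N(sync_center, noise_sd²·I) used for both the therapist and client row
— planted synchrony literally means the pair shares a linguistic
profile that session. An asynchronized session draws its two rows
independently from role-specific centers. Default geometry: the sync
center sits at the scale midpoint (50,50,50,50) and the role centers at
sync ± separation·noise_sd·u along the unit direction
u = (½, ½, −½, ½) — therapists higher on analytic, clout and tone,
lower on authenticity, the pattern seen in real dyads. `separation`
(default 6) is the Euclidean sync↔role center distance in noise-SD
units, so role centers are 12 SDs apart and a session is mis-flagged
only when both of its rows cross a 3–6 SD decision boundary (a double
tail event, ~1e−6). Under these defaults the pipeline recovers the
realized truth flags exactly at rates 0, 0.25, 0.5 and 1 across seeds;
the recovered percentage estimates the *planted rate* itself only up to
binomial noise in the realized flags. An optional 4×4 noise covariance
replaces the isotropic default for correlated variables. Everything is
driven by a single integer seed through numpy's Generator; identical
seeds give identical outputs at both layers.

What the generator does **not** emulate: real summary-variable
distributions are bounded, skewed, and serially correlated across
sessions, speakers drift over treatment, and session lengths (hence
scorer measurement error) vary. Passing recovery tests show the
clustering/co-membership machinery is sound under clean separation,
not that the measure is robust on noisy clinical data.

## Fixtures

The demonstration scores (three dyads: 30, 28 and 40 sub-transcript
rows) are packaged as CSV, sha256-checksummed at load, alongside the
published outcomes (cluster counts 3/2/2, synchronized sets
{2,8,10,11,12}, ∅, {9,11,12,14,17}, percentages 33.3/0/25). Running the
default pipeline on these fixtures at the published cluster counts
reproduces the published synchronized sets and percentages exactly;
this is asserted in the test suite and recomputed by
`scripts/acceptance.py`.

## Numerical and design choices

- Distortion uses squared distances (what Lloyd's algorithm optimizes);
  the unsquared sum can be derived from reports for plotting parity
  with elbow plots drawn on other scales.
- Report floats are rounded to 10 decimals and serialized with sorted
  keys so identical runs are byte-identical.
- Percentages are reported to one decimal.
- Test and simulation problem sizes (50-session dyads, 50 seeds,
  10-restart elbow scans inside the recovery study, 200 oracle
  instances) were chosen to keep the full suite around half a minute
  while leaving the binomial/optimality margins comfortably wide.

## Limitations

- The elbow rule is one operationalization of a visual judgment; the
  synchrony percentage is systematically sensitive to the chosen k, and
  no automatic rule reproduced the visual k = 3 for the psychoanalysis
  dyad. Alternatives (gap statistic, silhouette) are deliberately out
  of scope for now.
- No significance/null model is attached to a dyad's percentage; a
  within-role permutation null is an obvious future addition.
- The measure makes no claim about treatment quality or outcomes, and
  absolute scores from the built-in scorer are not comparable with
  proprietary-tool output (see Scoring model).
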