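# Methods

`smartmcda` implements a two-stage decision analysis: weighted aggregation of
a healthcare-professional Likert survey into risk/opportunity criteria, then a
SMART (Simple Multi-Attribute Rating Technique) evaluation of candidate
resilience strategies by linear additive utility. This note documents the
model, its assumptions, the parameter conventions, what the synthetic-data
generator does and does not emulate, and the design choices made where the
design was genuinely open.

## Respondent weighting

Each respondent carries three credential coefficients:

| credential | categories | coefficients |
|---|---|---|
| education level | health assistant → PhD/academic (6 levels) | 1, 1.5, 2, 2.5, 3, 3.5 |
| years of specialty experience | 0–4, 5–9, 10–14, 15–19, 20+ | 1, 1.5, 2, 2.5, 3 |
| pandemic-response role | not involved/education → COVID support hospital/ER/ambulance (5 levels) | 1, 1.5, 2, 2.5, 3 |

The weight maps are validated *total* at construction (every category maps to
exactly one coefficient) and an unknown category is a hard load-time error —
defaulting to weight 1 would silently flatten the weighting scheme.

**Composite scheme.** How the three coefficients combine into one respondent
weight is not dictated by the elicitation itself, so it is a configurable
choice: arithmetic `mean` (default), `product`, or `sum`. The mean keeps the
composite on the 1–3.5 coefficient scale; the product would inflate the most
credentialed respondents to 31.5× the least, which we judged too aggressive a
default. All downstream stage-1 statistics are invariant to rescaling all
composite weights by a constant, so only the *relative* spread of the scheme
matters.

**Sample size.** `cochran_sample_size(z, p, e) = floor(z²·p(1−p)/e²)`.
Truncation (not ceiling) is used: at z = 1.96, p = 0.5, e = 0.05 the formula
gives 384.16 and the conventional benchmark quoted for large populations is
384. The more conservative "round up" convention would give 385; callers who
want it can add one.

## Stage 1 — weighted item summaries

For item *i* with responses *x* and composite weights *w* (missing answers
excluded listwise per item, from numerator and denominator alike):

* weighted mean: x̄_w = Σ w x / Σ w
* weighted SD: population convention, √(Σ w (x − x̄_w)² / Σ w). Dividing by
  Σ w (rather than Σ w − 1 or an effective sample size) is the only choice
  that is exactly invariant to weight rescaling and exactly reproduced by the
  integer-weight replication oracle.
* weighted index: x̄_w / scale_max × 100, a percentage in [0, 100] comparable
  across 1–5 and 1–6 items. The "weight index" values printed in the source
  tables of the motivating study (≈15–16 per item) follow an undisclosed
  construction and are **not** reproducible; this package defines its index
  explicitly and treats those printed values as observations, not targets.
* preferred response: the scale point with the greatest total weight; exact
  ties break toward the **lower** scale point and set a tie flag, so strong
  agreement is never overstated by default. The preferred share is that
  point's weight fraction × 100.
* quartiles: type-1 (left-continuous inverse CDF) weighted quantiles — the
  lowest scale point whose cumulative weight share reaches p. On discrete
  scales this is reproducible and agrees with the replication oracle.

Item ranking sorts descending by weighted index (or weighted mean), with
exact ties broken lexicographically by item id and flagged. Criterion
extraction maps configured attribute ids to source items; an attribute's
salience is the unweighted mean of its source items' weighted indices.

**Integer-weight oracle.** For integer weights, every summary equals the
unweighted summary of the expanded matrix in which respondent *i* is
replicated w_i times. This equivalence is enforced by test against an
independent brute-force implementation (exhaustively over all weight vectors
in {1,2,3}^n for n ≤ 4).

## Stage 2 — SMART

Dimensions K1…K4 carry normalized weights w_k; raw SMART importance scores in
[10, 100] are normalized by their sum (the score range is part of the
method's definition and is enforced). Each strategy assigns every attribute
an importance rank ≥ 1; rank totals per strategy are validated against a
configurable constant (14 in the packaged model) so strategies stay
comparable.

* attribute value: rank × w_k (of the attribute's dimension)
* dimension score: u_jk = Σ attribute values in dimension k
* performance total: Σ_k u_jk
* utility: U_j = Σ_k w_k · u_jk; the argmax is the recommendation, exact ties
  break to the lowest alternative id with a tie flag.

Note the additive model treats importance ranks as interval-scaled scores —
an assumption inherited from the method as practiced, not a theorem. All
internal float comparisons use an absolute tolerance of 1e-9; two-decimal
published values are matched at ±0.005.

**Packaged model.** The shipped configuration (`data/pandemic_resilience.yaml`)
has four dimensions (HR management 0.20, service planning 0.30 with four
attributes, budget 0.35, legal framework 0.15), three strategies each with
strategy weight 0.35 and importance ranks summing to 14. Its published source
tables contain two kinds of internal inconsistency, reconciled as follows:

1. *Per-cell typos*: where a printed per-attribute value conflicts with
   rank × w_k or with a printed column total, the formula wins; this choice
   uniquely reproduces all printed dimension totals (3.70, 3.80, 3.90) and
   utilities (1.04, 1.09, 1.14).
2. *Dimension-label swap*: one table names K1 = HR management (0.20) and
   K3 = budget (0.35), another names K1 = budget (0.35). The numeric pipeline
   is keyed by the attribute-to-weight assignment, which is consistent
   everywhere; both label variants are carried (`label` / `alt_label`), and
   because the two strategies affected rank the swapped attributes equally,
   both keyings give identical numbers.
3. A published per-alternative coefficient column (0.35, 0.70, 1.50 — the
   last conflicting with rank × strategy weight = 1.05) is metadata only and
   never enters U_j.

**Sensitivity.** One-at-a-time: w_k ← w_k ± δ, remaining weights rescaled
proportionally to restore Σ = 1; the *entire* evaluation (attribute values,
dimension scores, utilities) is recomputed under the perturbed weights, since
in this SMART variant the performance scores themselves depend on w_k. A
perturbation driving any weight out of (0, 1) is skipped with a note. The
report gives, per dimension, the smallest δ on the grid that reverses the
recommendation (default grid 0.01…0.99 step 0.01), validated against
brute-force grid enumeration.

## Synthetic survey generator

The generator emulates the stated world of a 412-respondent healthcare-
professional survey:

* **Demographics** are drawn independently per field from categorical
  marginals. The packaged spec uses the published category counts,
  renormalized where the printed column is internally inconsistent (the
  profession counts sum to 416, not 412). Two fields required choices the
  publication does not determine, made once: the three published education
  bands are split across the six weight-map categories (pre-university →
  health/medical assistant evenly; university → resident; post-university →
  specialist/primary/PhD evenly), and the experience-band marginal — absent
  from the publication — is a fixed mid-career default (62/82/103/82/83 of
  412) consistent with the published mean age of ~41.
* **Responses** per item follow a discretized Laplace kernel,
  P(x) ∝ exp(−|x − mode|·concentration) on the item's scale points: one
  concentration parameter spans near-degenerate patterns (everyone at the
  mode, matching published IQR 6.0–6.0 items) through uniform (concentration
  → 0). Default concentration 2.0 puts 76–87% of mass on the planted mode
  (interior vs endpoint mode) — strong but not degenerate consensus, in the
  upper range of the published preferred-response shares. Planted modes are the 22 published
  preferred responses (8 workload items on 1–6 scales; 9 access and 5
  resilience items on 1–5 scales).
* **Missingness** is independent per cell with a per-item probability
  (packaged: 0.02 workload block, 0.10 access/telemedicine block, 0.05
  resilience block, reflecting the relative non-response the publication
  reports). Missing cells are inserted after response sampling.
* **Determinism**: one integer seed drives two independent child streams
  (respondents, responses) via `numpy` `SeedSequence.spawn`, so each half is
  reproducible on its own and two runs with the same seed are identical.

What the generator does **not** emulate: joint demographic structure (only
marginals are published), correlation between demographics and response
behaviour, item-item correlation, and informative missingness. A green
recovery test therefore establishes that the aggregation pipeline recovers
planted marginal structure at survey scale — not that it would be robust to
confounded real-world response patterns.

**Recovery check.** Per item, the stage-1 preferred response is compared to
the planted mode; the observed weighted-index ranking is compared with the
analytic kernel ranking pairwise, skipping pairs whose analytic indices
differ by ≤ 1 percentage point (such pairs are not ordered by the stated
world). With n = 412 and concentration 2.0, all 22 modes are recovered in
≥ 99 of 100 seeds (enforced by test).

## Pipeline and numerical conventions

Configuration is pydantic-validated all-or-nothing (`extra="forbid"`; any
dangling criteria→item or criteria→attribute reference aborts before
computation), and output bundles are rendered fully in memory before anything
touches disk, so partial bundles cannot occur. The run manifest records a
canonical config hash, the seed and the package version — no timestamps — so
reruns are byte-identical. Stage 2 can run standalone from a decision-model
config; the stage-1 → stage-2 linkage (which items evidence which attribute)
is an explicit, auditable mapping rather than a hard-coded narrative.

## Limitations

* The stage-1 index of the motivating study is not recoverable; numerical
  agreement with its per-item table values is out of reach by construction
  (no raw data, no formula) and is not claimed.
* SMART with rank-derived scores is ordinal input forced through an interval
  model; conclusions are only as strong as that assumption, which is why the
  sensitivity sweep ships as a first-class operation.
* The sensitivity analysis perturbs one weight at a time; joint perturbations
  and Monte-Carlo uncertainty on scores are out of scope.
* No pairwise-comparison (AHP), outranking (ELECTRE/PROMETHEE) or fuzzy
  extensions.
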