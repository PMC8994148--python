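# Methods

## Model

The package models a cleaned AE report cohort as i.i.d. draws from a
discrete Bayesian network B(G, Θ): a DAG G over the outcome (GBS), age
(4 levels), gender (2 levels) and K binary AE indicators, with one
conditional probability table (CPT) per node. The joint factorises as
P(x) = ∏ᵢ P(xᵢ | pa(xᵢ)). Two assumptions matter in practice:

- **Markov property.** Conditioning on a node's Markov blanket (parents,
  children, spouses) separates it from the rest of the graph; the final
  predictive model is therefore the induced subnetwork on GBS and its
  blanket, and reports' AE columns outside the blanket are ignored at
  prediction time by construction.
- **Complete data.** Exclusions run before modelling, so the case matrix
  has no missing cells and maximum likelihood reduces to closed-form
  frequency ratios per parent configuration.

## Cleaning and discretisation

Reports with missing age, age < 0.5 years, or unknown gender are
excluded. Age rules are evaluated before the gender rule, so a report
failing both is logged once, under age — this affects only the exclusion
log, never the retained set, and makes log counts sum exactly to the
number removed. Age bins are half-open — [0.5, 18), [18, 50), [50, 65),
[65, ∞) — so every admissible age lies in exactly one bin; fractional
ages between printed labels (e.g. 17.6) fall in the lower bin. AE term
matching is exact string comparison after trimming, case-folding and
whitespace squeezing; no MedDRA hierarchy logic is attempted. Top-K
prevalence ties are broken lexicographically for reproducibility.

## Screening

Association tests are uncorrected Pearson chi-squares on 2×2 tables
(1 df); no Yates correction, because the uncorrected statistic is what
reproduces the borderline published p-values (.001 for tenderness, .003
for vomiting). Significance is strict p < α with α = .001 (0.05/50
Bonferroni), so a p-value that *rounds* to .001 is non-significant.
Terms with zero cases in all groups are reported as untestable rather
than counted on either side. Published prevalences printed per mille at
two decimals are inverted to integer counts by nearest-integer
reconstruction, exact whenever 0.005·N/1000 < 0.5 (true for all four
cohort group sizes); the below-printable entry "<0.01" can only mean
zero cases at these group sizes and is mapped to 0.

## Structure learning

BIC here is the natural-log likelihood minus (ln N / 2)·(r−1)·q per
family (higher is better), with 0·ln 0 := 0; parent configurations with
zero support contribute zero likelihood and full penalty. Tabu search
starts from the whitelist-only graph and repeatedly applies the best
add/delete/reverse move, forbidding moves that recreate one of the last
10 visited structures (canonical arc-set hash) and allowing up to 10
consecutive non-improving moves past a local optimum before stopping;
the best structure visited is returned. Ties between equal-score moves
are broken by lexicographic arc order, then move type (delete < add <
reverse), so runs are exactly reproducible; the search itself contains
no randomness and the recorded seed only governs downstream stages.
Whitelist arcs are never deletion/reversal candidates; blacklist arcs
are never added. The structure is learned **once**, on the full
development cohort, and held fixed during cross-validation; only CPTs
are refit per fold. Arc strengths are raw BIC deltas for removing the
arc (negative = supported), computed by rescoring only the child family
(decomposability).

## Parameters and inference

CPTs are pure MLE. Parent configurations unseen in training are filled
uniformly and flagged (`unsupported_rows`) rather than smoothed, keeping
supported rows exactly at their empirical frequencies; an add-k
smoothing mode exists but is off by default. Inference is exact
enumeration over unobserved variables, in log space; in the prediction
setting every non-target variable is observed, so scoring costs two CPT
gathers per family of the target and its children. When a validation
row has probability zero under both target states (a child CPT cell
estimated at exactly zero for a supported-but-sparse configuration),
the evaluation paths fall back to the target's CPT row given the
observed parents — dropping the offending child likelihoods — and the
library's direct `predict_scores` raises unless that policy is chosen
explicitly. The posttest-probability table is read directly from the
outcome's CPT: parents d-separate the outcome from its other
non-descendants, so no other evidence changes those rows.

## Validation protocol

Folds are stratified on the outcome: with ~1.26% prevalence,
unstratified 5-fold splits would risk single-class validation folds.
The Youden-maximising threshold is chosen **on the validation fold
itself**, reproducing the development protocol; this is mildly
optimistic, and an honest train-fold-threshold mode is available
(`threshold_on="training"`). Classification is strict
(score > threshold). Only finite thresholds (observed score values) are
Youden candidates — the all-positive sentinel's Youden value of 0 is
always matched by the all-negative endpoint, so it is never a strict
optimum. AUC is trapezoidal with tied scores grouped at one threshold,
which makes it exactly equal to Mann–Whitney concordance with half
credit for ties. Summary CIs are mean ± 1.96·sd/√K over the K retained
folds (sample sd, ddof = 1). External validation applies the trained
structure and CPTs unchanged; its threshold defaults to Youden on the
external cohort's own ROC, with a transferred fixed threshold available
as an option, since the development protocol does not pin this choice
down.

## Synthetic cohort generator

The generator exists because the raw surveillance cohorts cannot be
redistributed. Its bundled ground-truth network has 13 nodes — GBS;
parents age, gender, erythema; children asthenia, hypesthesia, muscular
weakness, paresthesia; spouses chills, dizziness, myalgia, nausea, pain
in extremity — with the published qualitative sign structure: GBS risk
rises then falls with age (peak 50–64), is three-fold higher in men,
and is reduced 50-fold by erythema. The outcome CPT's overall scale is
solved exactly (the marginal is linear in it) so that P(GBS) = 0.0126;
exogenous marginals match the US totals (age 16.7/32.1/22.1/29.1%, male
30.1%, root-AE prevalences at the published per-mille totals), and the
GBS-conditional risk ratios of the child AEs echo the published GBS vs
non-GBS prevalence contrasts (7–15×). All CPT magnitudes are artifact
constants, calibrated by direct enumeration at build time.

Two generator design choices deserve emphasis:

- **Outcome-by-spouse interaction.** Child-AE CPTs multiply a baseline
  by per-parent risk factors, but spouse effects (3.5–6×) apply only in
  non-GBS reports and reverse (×0.3) in GBS reports — narrated as
  symptom-list competition in spontaneous reporting, where the syndrome
  dominates what gets listed. Without an interaction of this kind the
  collider orientations at the children are nearly unidentifiable from
  data (purely multiplicative CPTs carry almost no explaining-away
  information at realistic effect sizes), and no search algorithm could
  recover the spouse arcs reliably.
- **Spouse wiring.** The published description fixes the spouse *roles*
  but not which spouse feeds which child; the default map wires chills,
  nausea and pain in extremity into asthenia, dizziness into
  paresthesia, and myalgia into muscular weakness. Spouses are
  deliberately attached to low-arity child families: a v-structure at a
  child whose co-parents include the 4-level age variable costs ~16
  extra BIC parameters versus 1 for the reversed arc, which makes that
  orientation statistically undecidable at cohort sizes near 10⁵. The
  map is a constructor argument for experiments with other wirings.

Decoy AEs are independent of everything with prevalences drawn uniformly
from 15–120‰ (the published top-50 range), so correct pruning is
testable. The raw-report emulator renders age groups as uniform draws
within each bin (the open-ended top group within [65, 90)), injects
configured fractions of missing ages, ages below 0.5 years and unknown
genders, and adds the outcome term to the report's AE set for GBS rows.

What the generator does **not** emulate: reporting biases and stimulated
reporting, MedDRA term overlap, year-to-year formulation changes, and
any AE–AE dependence beyond the blanket (decoys are independent by
design). Passing end-to-end tests therefore demonstrates correctness of
the pipeline's statistics and search on data satisfying the model's
assumptions, not robustness to real-world reporting artifacts.

## Problem sizes and numerical choices

The test suite and the acceptance script run end-to-end recovery on 20
cohorts of 80,000 reports with 50 candidate AEs and 2 CV repeats — sizes
chosen so the whole pipeline (including constrained tabu search over ~53
variables) exercises every stage in a few seconds per seed while leaving
the blanket-recovery signal comfortably identifiable; the published
protocol's 100 CV repeats remain the library default. CPT probability
vectors must sum to 1 within 1e-9; joint and posterior computations are
carried in log space; BIC decomposability and arc-strength shortcuts are
tested against full rescoring at 1e-9; exact-inference agreement with
full-joint enumeration is tested at 1e-10. Families whose CPT would
exceed 10⁷ cells score −∞, a guard against pathological parent sets
during search. Seeds propagate through `numpy.random.default_rng`
everywhere; equal seeds give bitwise-equal cohorts, searches and CV
results.

## Known limitations

- Arc orientations that depend on weak v-structures (notably
  erythema → GBS, whose collider information lives in the handful of
  GBS cases with erythema) are frequently reversed in learned
  structures. Blanket *membership* — what the pipeline promises — is
  unaffected; the posttest table is therefore reported from the model
  fitted under the generating structure when orientation matters.
- The validation-fold threshold choice inflates sensitivity/specificity
  slightly; use `threshold_on="training"` for honest thresholds.
- Exact enumeration limits inference to networks of a few dozen nodes;
  the intended use (Markov-blanket subnetworks, all evidence observed)
  costs only two joint evaluations per report regardless of size.
- MLE CPTs can overfit sparse parent configurations; the uniform
  fallback applies only to configurations with *zero* support.
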