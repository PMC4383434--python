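# Methods

This note records the models implemented in `dentalcbr`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not demonstrate.

## Case schema and encodings

A case is one restored posterior tooth: 41 problem attributes (patient
number, sex, smoking, drinking, date of birth; eight dental sicknesses
scored 0 = absent or 1–10 severity; seventeen yes/no systemic conditions;
tooth number 1–32; the tooth's previous restoration date, longevity and
material; restoration level 1–10; four prior-failure flags; aesthetic
importance; the current restoration date) and a 2-attribute solution
(material ∈ {amalgam, composite}, longevity in years).  Longevity of a
restoration that has not failed is the time from placement to the
reference ("present") date and is flagged right-censored; censored
durations are used as-is in averages and training.  Dates are ISO-8601 in
files; internally every duration uses a 365.25-day year, and raw calendar
dates never enter a model — the current restoration date contributes only
through derived durations (age at restoration, years since the prior
restoration).

Three encodings feed the three model families:

* **EM** — booleans and nominals as category codes; the 1–10 ordinals
  (severities, restoration level) also as category codes; age, years
  since prior restoration and prior longevity as reals.  Ordinals are
  deliberately *not* treated as Gaussians: severity variables are
  zero-inflated (a point mass at 0 plus a 1–10 scale), and a Gaussian
  family there is misspecified in a way that systematically inflates the
  cross-validated cluster count, because extra mixture components get
  spent on fixing the marginal fit rather than on real structure.
* **BN** — fully discrete: reals equal-frequency binned into 4 bins
  (edges fitted on the training case-base); tooth number grouped into 8
  anatomical classes (upper/lower × molar/premolar/canine/incisor),
  since with 32 raw levels every G² test that conditions on the tooth
  falls below the 5·df small-sample floor and would silently delete true
  edges; the longevity target binned into 2-year intervals 0–20 plus an
  open 20+ bin (midpoint taken as 21).
* **MLP** — a real vector (0/1 binaries, raw ordinals and durations,
  one-hot tooth number, 71 components; 72 with the candidate material
  appended) min–max scaled into [0.2, 0.8].  Constant dimensions map to
  0.5; out-of-range queries are clamped.

The solution attributes are excluded from the EM encoding: retrieval must
assign a probe that has no solution yet, so the case-memory organization
can only depend on the problem descriptor.

## EM clustering and cluster-count selection

The mixture uses a naive per-cluster factorization: category tables for
discrete attributes, univariate Gaussians for continuous ones.  The
M-step uses Laplace smoothing α = 1 on category counts and a variance
floor of 10⁻⁶ (both configurable).  With the smoothing read as a
Dirichlet prior this is MAP-EM, and `loglik_trace` records the penalized
objective (data log-likelihood + log-prior), which provably never
decreases; the raw likelihood alone can dip by tiny amounts under
smoothing.  Initialization seeds each cluster from a distinct random
case (category tables leaning toward the seed's codes, Gaussians centred
on its values with the global variance); a random hard assignment was
found to leave the components symmetric and prone to collapse at small
n.  Five restarts keep the best objective; all randomness flows from one
seed.

K is selected by cross-validated held-out log-likelihood (default 10
folds): K increases from 1 until the relative improvement
(L_K − L_{K−1})/|L_{K−1}| falls to the threshold (default 10⁻⁶), and the
previous K is returned.  The threshold is read as *relative* improvement;
an absolute criterion can be had by scaling.  Fold assignments are shared
across K (common random numbers), and the CV fits use 3 restarts and a
looser tolerance than the final fit — selection needs ranking, not
polish.

## Bayesian networks

Structure learning is PC-style: start complete, remove edge (a, b) when
some S ⊆ adj(a) ∪ adj(b) with |S| ≤ max_cond yields conditional
independence, orient v-structures (a → c ← b when c separates nothing),
close under Meek's rules, and orient whatever remains from the lower to
the higher column index so runs are reproducible; the result is checked
acyclic.  The G² likelihood-ratio statistic decides independence with
df = (|a|−1)(|b|−1) × (nonempty strata of S); tests with fewer than 5·df
records return "independent" without testing (the standard PC
small-sample rule).  α defaults to 0.05 and max_cond to 3; the
cluster-classifier network is learned with max_cond = 1 — it is a wide,
shallow star around the cluster node, and deeper conditioning only costs
time there.  Conditioning subsets are tried in column order, and the
cluster label is placed first, so the single most plausible separator is
tested first.  CPTs are Laplace-smoothed conditional frequencies; unseen
parent configurations get a uniform row.  Inference is exact enumeration
(adequate because engine queries supply evidence on every non-target
variable; a guard refuses more than 12 free variables).

Two separately trained networks are used: the cluster classifier
(descriptor → hard EM label) and the per-cluster longevity expert
(descriptor + material → binned longevity).

## MLP and mixture of experts

The perceptron is one hidden layer of 2n+1 sigmoid units with biases.
Training is online backpropagation with momentum, per-pattern updates

    Δw_kj = η (d_k − y_k) y_k (1 − y_k) y_j + μ (w_kj(t) − w_kj(t−1)),

with the hidden layer receiving the error backpropagated through the
*pre-update* output weights — with μ = 0 one update is then exactly a
gradient-descent step on ½Σ(d − y)², which the test suite verifies
against central finite differences at 10⁻⁶.  Defaults: η = 0.1, μ = 0.9,
weight init Uniform(−0.5, 0.5), per-epoch shuffling, early stopping on a
20% validation split with patience (epoch budgets are configurable; the
engine defaults to 200 epochs / patience 15, which is where validation
error plateaus on case-bases of a few thousand records).  η = 0 is a
legal null update; negative η is an error.

The mixture trains the BN expert and the MLP expert on a cluster's
cases, collects *out-of-fold* predictions from an internal 5-fold split
(the combiner must not see resubstitution outputs, which would understate
expert error), and trains a 2-input, 5-hidden, 1-output combiner MLP on
those predictions against the true longevity.  One scaler (fitted on the
training longevities) carries expert outputs and targets into the
working range.  The BN expert's structure is learned once per training
split and only the CPTs are refitted per fold — structure search is the
expensive part and is stable across 80% subsamples.  Final predictions
are inverse-scaled to years and clamped at 0.

## The reasoning cycle

* **Retrieve** — cluster by BN posterior (ties broken by EM
  responsibility, then lower index), then the top-m cases (default
  m = 20) by mean per-attribute match score: equality for categoricals,
  1 − |Δ|/range for reals.  The similarity is the one genuinely open
  design point (no nearest-neighbour metric survives in the system this
  package models); the equal-weight match score is the simplest defensible
  choice and is isolated behind one function.
* **Reuse** — the cluster's mixture, trained lazily on first use and
  cached; clusters under 20 cases fall back to per-type averaging,
  flagged.
* **Revise** — clamp into mean ± z·sd (z = 2) of the cluster's same-type
  longevities; clusters without same-type cases borrow the global type
  limits, flagged.
* **Retain** — append (duplicate keys rejected), invalidate that
  cluster's mixture, recompute limits; EM and the classifier are
  retrained after 50 retains (configurable).

Two longevity estimates are reported per material and kept side by side:
the mean of the retrieved same-type cases (headline by default) and the
revised mixture output.  The recommendation maximizes the configured
headline estimate.

## Evaluation machinery

The exact Mann-Whitney test uses U = #{x_i > y_j} and
p = P(U_null ≤ U_obs) with the null distribution enumerated by dynamic
programming over rank arrangements (validated in the tests against
explicit enumeration of all C(n₁+n₂, n₁) arrangements and against an
independent library implementation).  Ties *between* the samples raise an
error directing callers to the mid-rank + Monte-Carlo permutation
fallback; ties within one sample are harmless to U and are allowed.
5×2 CV draws five year-stratified half/half splits, trains each method on
each half and tests on the other, pooling both directions into one mean
absolute error per repetition; years with fewer than two cases are merged
into a neighbour with a warning.  Leave-one-out by default amortizes:
clustering and classifier are built once and only the retrieval pool
excludes the probe (full retraining per fold is available but quadratic).
Failure-rate tables use a strict "<" at the 50%-of-type-mean boundary;
report values keep full precision internally and are rounded only for
display.

## Synthetic data

The generator draws a latent profile per case (default: three profiles —
young low-risk, middle-aged, older heavy-wear — separated in age,
smoking, drinking, several severity profiles, systemic conditions,
restoration level, caries history and aesthetic preference), then every
attribute independently from that profile's tables, ages and
restoration-history durations from per-profile Gaussians, and longevity
from a Normal truncated at 0 with per-(profile, material) means
(amalgam 14.5–15.5 y, composite 8.5–10.5 y, sd 1.2) — so the
amalgam/composite ordering and magnitudes match the reported yearly
duration bands, and composite prevalence is 93%.  Default censoring
fraction is 0.6 ("most restorations do not fail").  Failed cases get a
placement date uniform in 1993–2003 and a failure date placement +
longevity; censored cases are placed at reference − longevity so the
duration-to-present *is* the drawn value.  Dates of birth are
synthesized backward from the drawn age.

What this emulates: latent patient structure, mixed attribute types,
heavy class imbalance between materials, right-censoring, a 1993–2003
collection window.  What it does not: correlated attributes within a
profile (real comorbidities co-occur), informative censoring, secular
drift in materials, operator effects, or multiple correlated restorations
per patient.  Passing tests therefore demonstrate that the machinery
recovers known structure under the stated assumptions — not that the
clinical error rates of any particular practice would be matched.

## Problem sizes and numerical choices

Test and acceptance runs use case-bases of 2 000–3 000 cases, 500
held-out probes and ten generator seeds for the cluster-count check —
sizes at which every estimate of interest (CV log-likelihood differences,
held-out MAE, expert MSEs) is stable across seeds.  Variance floor 10⁻⁶;
Laplace α = 1 throughout; EM tolerance 10⁻⁶ relative on the objective;
similarity ties broken by case order; undirected-edge orientation by
attribute index; all seeds fanned out from one master seed via
SeedSequence (derived seeds kept below 2³¹).

## Known limitations

* The naive within-cluster factorization ignores attribute correlations;
  with strongly correlated real attributes the CV-selected K will exceed
  the true profile count (extra components repair the joint fit).
* The BN expert's 2-year longevity bins put a ≈0.5-year quantization
  floor on its accuracy; the combiner compensates only partially.
* Exact BN inference restricts queries to nearly-full evidence; there is
  no message passing.
* Censored durations are treated as observed values, matching the
  averaging conventions of the reports; no survival-analysis correction
  is attempted.
* With ≈7% amalgam prevalence, per-cluster amalgam statistics rest on few
  cases at small n; amalgam estimates are correspondingly noisier.
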