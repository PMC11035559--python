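# Methods

## The statistical model

The package analyses co-occurrence of ICD-10 diagnosis codes in a patient
registry.  Within one age–gender cohort, codes and patients form a
bipartite network: code *i* is linked to patient *p* when *p* was
diagnosed with *i* at or before the cohort's upper age bound.  The
one-mode projection onto codes links every pair of codes sharing at least
one patient — but in a registry whose code prevalences span several orders
of magnitude, most of those links arise by chance from the margins alone.

The null model randomly rewires the bipartite network while preserving
every degree: each patient keeps their number of codes, each code its
prevalence.  Under that null the number of patients shared by codes *i*
and *j* is hypergeometric,

    H(X | N, N_i, N_j) = C(N_i, X) C(N − N_i, N_j − X) / C(N, N_j),

with N the cohort size and N_i, N_j the code prevalences.  The one-sided
p-value for an observed co-occurrence N_ij is the upper tail
P(X ≥ N_ij) = 1 − Σ_{X<N_ij} H(X | N, N_i, N_j); only over-representation
is tested.  Across the T tested pairs of a cohort the p-values are ranked
increasingly and links of rank k are retained when p_(k) ≤ k·α/T — the
Benjamini–Hochberg step-up rule at level α = 0.01 by default, with
Bonferroni (p ≤ α/T) as an alternative.  The surviving edges form the
statistically validated network (SVN); the ego network of a focal code
(default I67.1, unruptured intracranial aneurysm) is the focal node plus
its validated neighbours.

T defaults to the number of pairs actually tested, i.e. pairs of retained
codes with co-occurrence ≥ `min_cooccurrence`.  Pairs that never co-occur
have p = 1 and can never be rejected, but counting them changes every
threshold; `count_zero_pairs=True` switches to T = all pairs of retained
codes for sensitivity analysis.

## Cohort construction

Events are reduced to one record per (patient, code) at the minimum
observed age ("first diagnosis").  A patient belongs to the 10-year cohort
[lo, lo+9] of their gender exactly when some code of theirs was first
diagnosed at an age in that bracket, and carries there their *cumulative*
history: all codes first diagnosed at or before lo+9.  First diagnoses at
56 and 63 therefore place the patient in 50–59 with one code and in 60–69
with both.  The top bracket is open-ended (80+, labelled `80-XX`).
A decade in which the patient has no new first diagnosis confers no
membership by default; `carry_forward=True` instead fills every decade
between the patient's first and last first-diagnosis decades with the
cumulative set, since registry semantics could be read either way.  Ages
derived from dates use completed years, ⌊(event − birth)/365.25 d⌋.

ICD codes are normalised to the XX.X level: upper-cased, dotless subcodes
re-punctuated (`I671` → `I67.1`), and anything beyond one post-decimal
digit truncated, not rounded (`I67.12` → `I67.1`) — truncation is the
deterministic reading of "one decimal digit of specificity".  Chapter
mapping is total over all syntactically valid codes; official chapter
gaps (e.g. E91–E99) are absorbed into the neighbouring block so that every
code maps to exactly one category.  Eye (H00–H59) and ear (H60–H95)
blocks are distinguished for labelling but merged into H00–H99 in the
tabular summaries.

## Numerics

The tail P(X ≥ N_ij) is computed from one anchored log-pmf term plus an
exact term-ratio recurrence

    pmf(X+1)/pmf(X) = (N_i − X)(N_j − X) / ((X+1)(N − N_i − N_j + X + 1)),

accumulated in scaled linear space (renormalising whenever the running
sum exceeds 1e280) and exponentiated at the end, so results stay accurate
for p down to ~1e-300; tails below the smallest double subnormal clamp to
5e-324 to keep p in (0, 1].  Log-binomials use an extended-precision
Stirling-series log-gamma: standard double log-gamma carries ~1 ulp of its
value, which at arguments near 10^6 is an absolute log-error around 1e-9 —
enough to show up when pmf terms are summed over a wide support.  The
long-double series keeps the pmf normalised to ~1e-12 at N = 10^6.

Ties in p-values share eligibility under the step-up rule; ranks use the
deterministic sort key (p, lexicographic pair), so all outputs are
order-invariant and re-runs are byte-identical.  Degenerate inputs:
N_ij = 0 (or any value at/below the support minimum) returns p = 1
exactly; empty cohorts and empty networks raise; a focal code absent from
a network yields a singleton ego network rather than an error.

Percentages in summary tables are rounded half-up to one decimal (so
14/19 → 73.7), matching the convention of printed clinical tables rather
than banker's rounding.

## The synthetic registry generator

Real hospital registries of this kind are proprietary, so
`synthetic_data` generates populations with known ground truth.  Each of
`n_patients` patients per gender draws each code independently at a
code-specific prevalence, log-uniform on [0.001, 0.3] by default — two to
three orders of magnitude of heterogeneity, with per-patient code counts a
sum of independent Bernoullis and therefore themselves heterogeneous.
The focal code defaults to I67.1 at 3%, the estimated population
prevalence of unruptured intracranial aneurysms.  Each carried code gets a
first-diagnosis age uniform in its bracket (default 30–79, configurable
per code).  A planted pair (a, b, ρ) redraws b for carriers of a at
probability min(1, ρ·p_b) — a one-directional conditional that induces
*symmetric* excess co-occurrence with relative risk ρ; no directionality
should be read into which code is listed first.  Gender restrictions
limit the boost to one gender; a decade restriction additionally pins the
boosted patients' ages for both codes inside that bracket so the signal
lands in a known cohort.

Under the baseline (no planted pairs) the generator matches the null's
exchangeability assumption exactly, so every validated link is a false
discovery by construction — which is what makes the calibration studies
meaningful.  What the generator does **not** model: disease progression
and longitudinal correlation between codes, coding-practice artifacts,
censoring and mortality, or realistic chapter composition.  Passing tests
therefore demonstrate the statistical machinery is correct under its own
assumptions, not that the pipeline's output on a particular real registry
is clinically valid.

## Calibration studies and problem sizes

`null_fdp_study` runs replicate null registries through the full pipeline
and records, per cohort family, the realized false-discovery proportion
(1 when the family validated anything, since every discovery is false
under the null).  The test suite uses 200 replicates of 1,000 patients
per gender with 150 codes at prevalences 0.005–0.30; discreteness of the
hypergeometric p-values makes the step-up rule conservative, so the mean
realized FDP sits well below the nominal α = 0.01.

`planted_recovery_study` measures how often a planted focal link is
validated.  The headline configuration plants (I67.1 at 3%, partner at
20%, ρ = 5) in 100 replicates of 2,500 patients per gender; ρ·p_b = 1, so
every focal carrier also carries the partner.  All code ages are drawn in
a single decade (50–59) for this study so that each gender contributes
exactly one cohort with fully defined margins — separating the power
question from cohort-dilution effects.  `analytic_recovery_power`
cross-checks the Monte-Carlo rate with no pipeline code: it sums the
binomial law of the focal count N_a, takes the partner margin at its
conditional expectation, and asks when the hypergeometric tail clears the
rank-one step-up threshold α/T — a slight lower bound on the procedure's
power, adequate because the planted effect is overwhelming (power
≈ 1 − 10^-8).

The acceptance script re-runs both studies at reduced replicate counts
(100 null, 60 recovery) — the estimates it reports are binomial
proportions whose standard errors at those sizes are already far below
the margins of interest.

## Known limitations

- The hypergeometric null conditions on margins within one cohort; links
  are validated per cohort with no pooling or meta-analysis across
  cohorts, and no correction across the cohort families.
- Only excess co-occurrence is tested; protective (under-representation)
  relationships are invisible.
- Cumulative cohort histories make late-decade networks nearly nested
  supersets of early ones; cross-cohort presence tables should be read
  with that dependence in mind.
- The p-value recurrence is exact in structure but accumulates ~1e-13
  relative error over very long supports; beyond-double tails clamp at
  5e-324.
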