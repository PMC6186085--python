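# Methods

This note documents the models implemented in `p53netval`, the choices
made where the underlying procedures admit more than one reading, and
what the synthetic-data generators do and do not emulate.

## Network model

An interaction network is a signed directed graph. Nodes are genes,
stimuli or output phenotypes; edges carry +1 (activation) or −1
(inhibition). Two nodes are designated: the stimulus input (`DNA_damage`
by default) and the p53 node (`TP53`). Exact duplicate edges collapse
with a warning; opposite-sign parallel edges are kept, since curated
networks contain genuinely dual regulation. Node identity is
case-sensitive exact string match — gene-symbol normalization is left to
explicit mapping steps so that no silent aliasing occurs.

The SIF dialect is `source relation target`, whitespace- or
tab-separated, relations `activates`/`inhibits`, `#` comments, bare node
names for isolated nodes. A JSON sidecar (`<file>.sif.json`) carries the
designated node names and any non-gene node kinds, making
read∘write an identity up to ordering.

`toy_p53_network()` is a 20-node fixture around the DNA-damage → ATM →
TP53 axis: the TP53–MDM2 negative feedback (the fixture's only cycle),
ATM's inhibition of MDM2 (which lets damage resolve the feedback), a
TP53-only apoptosis arm (BAX/APAF1/CASP9), and an E2F1/FOXM1
proliferation arm carrying survival-relevant genes (FEN1, MMP2, SIAH1,
AURKA, …). Signs encode textbook regulatory logic; the fixture is a
plausible stand-in for a p53 interactome model, not a reconstruction of
any published edge list. `random_network()` generates reproducible test
surfaces: the input node has out-edges only, every node is reachable
from it (orphans are re-wired), and `acyclic=True` restricts edges to a
fixed topological order for solver-vs-oracle comparisons.

## Logical steady states

The update rule is inhibitor-dominant three-valued (Kleene) logic,
evaluated *cautiously*: a node is assigned a determined value only when
no refinement of still-undetermined regulators could change it.

* 1 when at least one activator is 1 **and every inhibitor has resolved
  to 0** (vacuous without inhibitors);
* 0 when some inhibitor is 1, or all regulators have resolved to 0;
* NaN otherwise.

The cautious reading (requiring inhibitors to be determined 0, not
merely "not 1") is what makes the update monotone in the information
order NaN ⊑ {0, 1}: determined states never flip, so iteration from
all-NaN reaches the least fixpoint in at most |V| sweeps and cycles
resolve to NaN unless forced from outside. The naive reading ("no
inhibitor is currently 1") oscillates on the TP53–MDM2 negative
feedback and admits no well-defined fixpoint semantics; it was rejected
for that reason. On acyclic networks the fixpoint coincides with direct
recursive evaluation, which the tests exploit as an independent oracle.

Scenario handling: the input node is clamped to 1 (damage ON) or 0
(OFF). A p53-null scenario clamps the p53 node to 0 before iteration —
a loss-of-function knockout that keeps the graph intact while all
downstream logic sees an inactive node; for signed-graph logic this is
behaviorally identical to node deletion. Source nodes other than the
input are uncontrolled and stay NaN rather than defaulting to 0 —
absence of evidence is "undetermined", not "inactive". Phenotype nodes
are treated exactly like gene nodes.

`E_mod` between two steady states is the nine-case state-change table;
it is total on {0, NaN, 1}² and antisymmetric (swapping scenarios negates
every call).

## Differential expression and E_exp

The package does not re-implement array/count model fits (limma, edgeR);
externally fitted DE tables (gene, log2fc, pvalue) are first-class
inputs. For synthetic data a Welch two-sample t-test on log₂ values
stands in: log2fc = mean(B) − mean(A), unequal-variance p-value. Counts
are log₂(x+1)-transformed; linear intensities log₂-transformed;
log-intensity matrices used as-is. Degenerate cases are made total:
zero variance in both groups gives p = 1 for equal means (no evidence of
change) and p = 0 otherwise; single-sample groups give p = NaN and the
gene is excluded from calling.

Calls use |log₂FC| ≥ log₂(1.5) (inclusive) and raw p < 0.05 (strict),
with no multiple-testing correction — the boundary conventions follow
the literal "fold change of 1.5 and p-value < 0.05" filter, and both
boundaries are pinned by tests. Probe-level matrices collapse to genes
by the median across probes. Mapping DE genes to the model is exact-id
intersection with logged mapped/unmapped counts; DE tables are filtered
to model genes *before* any summary statistics are formed.

## Score flow

The score-flow heuristic is reconstructed from its observable contract,
with its three open choices exposed in `StsfaConfig`:

* **normalization** — a regulator's contribution is `final(u)/outdeg(u)`
  (a hub distributes rather than replicates its score); switchable off;
* **clamping** — final scores are clamped at 0 (activities, not signed
  quantities); switchable off;
* **damping** — fixed point of `final = clamp₀(init + W·final)` solved
  by damped iteration `x ← (1−d)·x + d·F(x)`. The default d = 1
  (undamped) is exact on acyclic networks within |V| sweeps; d < 1 is
  available for oscillatory cycles. Convergence is declared when the
  maximum relative change drops below 1e−9 (default), with a
  residual-reporting error otherwise — divergent positive feedback loops
  (loop gain ≥ 1) are reported, not silently iterated.

Out-degree normalization bounds every column sum of |W| by 1, so damped
iteration converges whenever the flow system has a finite solution.

Score initialization: mapped gene scores are log₂ expression × 100 (the
scale factor turns log intensities into integer-ish inputs). The
DNA-damage node gets the arithmetic mean of mapped gene scores when the
scenario has damage ON and their minimum when OFF; all unmapped model
nodes get the minimum. The p53 node counts as an ordinary mapped gene in
that mean — only the input node itself is excluded.

Fold-change classification uses log₁₀((final₂+1)/(final₁+1)) — the
pseudocount of 1 keeps clamped zero scores finite and is negligible at
the ×100 score scale — with sample SD (ddof = 1, pinned by a
hand-computed test: values {1, 0, −1, 0.2, −0.2} give sd ≈ 0.7211).
Calls are strict inequalities against mean ± SD, so an all-equal
fold-change vector calls nothing. Under approximately Gaussian fold
changes each tail captures ≈ 16% of genes; tests assert ≤ 30% loosely.

## Validation statistic

Per gene |E_mod − E_exp| ∈ {0, 1, 2}. The summary's significance is the
exact binomial **point** probability C(n,k)(1/3)ᵏ(2/3)ⁿ⁻ᵏ of the
observed number of correct predictions under a null of three
equiprobable outcomes, computed in log space; cross-checked against a
brute-force enumeration oracle at small n. The point mass (rather than
an upper tail) is the reconstruction that matches published
validation-table values of this statistic; an `upper_tail` mode is
provided behind a flag. Percentages are reported to two decimals.

## Survival analysis

Pearson correlation of per-patient gene score with survival time is a
ranking heuristic that ignores censoring — the event indicator is
required in metadata (defaulting to all-events with a loud warning when
absent), and the Cox model honors it. The univariate Cox fit maximizes
the Breslow partial likelihood by Newton–Raphson (Breslow rather than
Efron tie handling: simpler, and ties are rare at day resolution);
standard errors come from the observed information, CIs are
exp(β ± 1.96·se), p-values from the Wald chi-square. Monotone
likelihoods (complete separation) are detected (|β| > 50) and reported
as errors naming the cause. The implementation is cross-checked in tests
against a fine-grid brute-force maximizer of the same likelihood and
against an independent general-purpose fitter. Sign conventions: a
survival-decreasing covariate gets β > 0 (HR > 1, "bad prognostic
factor"), pairing with a negative Pearson correlation against time.

Stratification partitions patients by TP53 status × chemotherapy; empty
or tiny groups are allowed (real surgical series have near-empty
mutant+chemo cells) and skipped with warnings in per-group reports
(minimum 3 patients). The Cox table is fitted pooled across groups on
per-gene standardized scores so coefficients are comparable between
genes; a per-group fit is available by passing the group's records.

## Staging

Per gene, one-way ANOVA across stages 1–4 on per-patient scores; stages
with fewer than 2 patients are excluded, and genes with fewer than 2
eligible stage groups are skipped. Zero-variance degenerate inputs
return p = 1 ("no evidence of difference") to keep pipelines total.
Direction is the stage-4 vs stage-3 median comparison, independent of
significance (the significance filter is the caller's); it is invariant
to positive affine transforms of the scores.

## Synthetic data

The experiment generator emulates a small two-condition cell-line
experiment over network genes: per gene a baseline log₂ mean ~ U(6, 12),
i.i.d. Gaussian noise (default sd 0.25), a treated-group shift of
±effect size (default 1.0 log₂ units, i.e. 2-fold) or 0 according to the
*intended call*, and a triplicate default per condition. The intended
call equals the logical model's E_mod with probability = concordance
(default 0.75, the regime reported for cell-line validations of such
models); discordant genes draw uniformly between the two wrong classes,
which makes the expected small/large error mix analytic. The generator
emulates magnitude and noise of a normalized array experiment, not
probe-level structure, normalization artifacts, or correlated noise — so
passing end-to-end tests demonstrate pipeline correctness under clean
conditions, not robustness to real-data pathologies.

The cohort generator defaults to the emulated surgical series: 71
patients split 27/26/1/17 over (wt, chemo)/(wt, no)/(mut, chemo)/(mut,
no) by largest-remainder apportionment, stage mix 10/20/40/30%,
~30% censoring, median survival ≈ 500 days. Per-patient counts are drawn
per gene from a log-normal (patient sd 1.0 log₂ units), scored through
the actual score-flow machinery under the patient's own scenario (damage
ON iff chemotherapy, p53 null iff mutant), and survival times are
exponential with hazard λ₀·exp(Σ β_g·z_g) over *standardized* driver
scores — standardization makes β units (log hazard per SD of score)
comparable across genes and recovery tolerances scale-free. Censoring is
an independent exponential whose rate is solved numerically so the
expected censored fraction matches the request; censoring at a uniform
fraction of the event time was rejected as informative. Stage-effect
genes get a fixed log₂ shift in stage-4 patients before scoring.

## Problem sizes and calibration checks

The solver-vs-oracle and calibration checks run at sizes chosen to give
stable statistics at interactive runtimes: 100 random DAGs for the
logical fixpoint oracle, 20 for the score-flow oracle, Cox recovery at
n = 500 (β = 0.5 ± 0.15), and ~1000 gene-level null tests each for the
Cox Wald and staging ANOVA type-I error (expected ≈ 5%). Because score
flow makes gene scores correlated *within* a cohort, the 1000 null Cox
tests are split over 20 independently generated cohorts of 50 genes, so
the rejection-rate estimate averages over independent survival draws.

## Known limitations

* The logical semantics is a documented reconstruction; other
  steady-state engines may handle cycles differently (e.g. resolving
  some feedbacks that remain NaN here).
* The score-flow contract (normalization, clamping, damping) is likewise
  a reconstruction; it is not claimed to be bit-identical to any
  particular plugin implementation.
* Pearson-vs-survival treats censored times as observed; use the Cox
  output where censoring matters.
* The Welch-test DE path is a stand-in for proper count/array models and
  should not be used on real RNA-seq counts when an edgeR/DESeq-style
  table can be ingested instead.
* The packaged drug–target table is a small static snapshot for report
  joining, not a live database query.
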