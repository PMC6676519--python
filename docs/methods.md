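# Methods

`sigbench` benchmarks a *directional gene signature* — a fixed list of genes,
each tagged with the direction (+1/−1) it is expected to move in the condition
of interest — against empirical null distributions built from randomly sampled
gene-sets of the same size. The package exists because the two obvious ways of
running such a benchmark give very different answers: repeated train/test
splits **within** one cohort reward any structure that lives in that cohort
(including laboratory batch effects), while **cross-cohort** external
validation only rewards signal that replicates in independent data. Every
component here is designed to make that contrast measurable.

## Per-sample scoring

For a cohort with G genes on its platform, expression values are ranked
ascending *within each sample* (ties averaged). A signature with up-set U and
down-set D scores sample s as

    score(s) = [ mean_{g in U} rank_g(s) − mean_{g in D} rank_g(s) ] / G.

One-sided signatures (U or D empty) are scored with the single mean rank,
centred by 0.5 so a direction-free expectation sits at zero. Because ranking is
within-sample, the score is invariant to any monotone per-sample transform and
needs no cross-cohort normalisation — the property that makes external
validation coherent. By default genes are ranked against the full platform;
`rank_within_signature=True` ranks only the signature genes (provided for
comparison, not default: full-platform ranking keeps the score's scale stable
when signatures of different sizes are compared).

Signature genes absent from a platform are dropped with a warning (platforms
genuinely differ in gene content); an overlap below 50% of the signature warns
loudly, zero overlap is an error.

## Validation schemes

*Within-cohort*: `n_repeats` stratified random splits at training share
`split_fraction` (0.5 and 0.75 are the named presets). Per repeat, gene
directions are fitted on the training share as the sign of the case-minus-
control mean difference (an exactly zero difference is deterministically +1,
logged), and the held-out share is scored and summarised as a Mann–Whitney
AUC. Splits preserve the class ratio; a draw that leaves either side without a
class is re-drawn (capped at 100 attempts).

*Cross-cohort*: directions are fitted once on the **entire** training cohort
and the fitted signature travels unchanged to each test cohort, where ranks
are computed within that cohort. Refitting per test cohort would leak exactly
the information external validation is supposed to withhold.

The candidate signature is passed through the same machinery as the null sets
(directions fitted on training data), so candidate-versus-null comparisons are
like-for-like.

A statistical caveat worth knowing: for a *fixed* dataset, the repeat splits
of within-cohort validation are strongly correlated, so a single gene-set's
repeat-mean AUC is data-conditional — on pure noise it can sit far from 0.5
for one dataset while being unbiased across datasets. Calibration claims in
the tests therefore always average over many gene-sets or label permutations,
never over repeats of one set. Relatedly, because a null distribution
evaluates every set under the *same* split sequence (so that evaluation is a
deterministic function of the set and the scheme), the split draw is a shared
component of all null AUCs: at 10 repeats the null mean itself carries a
data-conditional standard deviation of roughly 0.03. More repeats shrink this;
10 is the default used in the shipped experiments.

## Null distributions

`sample_gene_sets` draws sets uniformly without replacement within a set;
sets are mutually independent (a gene may recur across sets). Pools:

- **all** — the whole platform universe;
- **background** — probes at the detection floor: expression at or below the
  `floor_quantile` (default 0.25) of the cohort's pooled intensity in at least
  `sample_fraction` (default 0.8) of samples. "Below detection" has no single
  numeric definition on arrays; this quantile/fraction operationalisation is
  ours and both knobs are exposed.
- **filtered** — the universe minus an exclusion list (e.g. previously
  published age/disease genes), with the removed ids recorded.

When several platforms are in play, each platform has its own pool (different
arrays carry different genes); `intersect_pools` builds the shared pool needed
when a single sampled set must be evaluable on all platforms — the mode that
enables cross-cohort significance testing of nulls. Per-set failures are
recorded and counted, never silently dropped.

## Significance

Empirical p uses the add-one convention p = (1 + #{null ≥ candidate})/(1 + n);
ties count against the candidate and finite resampling never reports p = 0.
The rank is 1 + #{null > candidate}. Score-versus-label significance uses the
two-sided Mann–Whitney test: exact enumeration for tie-free instances with
n₁·n₀ ≤ 400, otherwise the normal approximation with tie and continuity
correction. Benjamini–Hochberg (via statsmodels) is applied across families of
candidates — a single prespecified signature is instead judged by replication:
unadjusted p < α in *every* independent cohort.

## Case definitions and matching

`AD_vs_CTL` drops MCI samples entirely; `ADMCI_vs_CTL` merges the
heterogeneous MCI group into the case class (only a fraction of MCI carry the
disease process, so merging dilutes a true signature and can flatter a
batch-driven one). Matching is greedy 1:1 within sex strata: cases in
descending age, each paired with the unused same-sex control minimising
|Δage|, accepted within `age_tolerance` (default 5 years); exact-distance ties
are broken by a seed-shuffled control order, making the output deterministic.
Greedy rather than optimal matching: deterministic, O(n log n), and adequate
at the cohort sizes this package targets.

## Synthetic data generator

Gaussian log₂-intensity model (microarray-like — the motivating data are
bead-array cohorts, not counts):

    y[g,s] = μ_g + d·dir_g·signal(s)·1[g ∈ S]
           + β_g·(age_s − mean age)/10 + γ_g·1[male]
           + b[batch(s), g] + ε[g,s]

with signal(s) = 1 for cases, Bernoulli(π) for MCI, 0 for controls. Key
structural choices:

- **Batch effects hit every gene, background probes included**
  (b[k,g] ~ N(0, τ²) per cohort/batch/gene). This is what lets background-only
  sampling "perform" within a confounded cohort.
- **Batch-class confounding** is parameterised as concentration: a fraction ρ
  of cases is forced into the first batch (interpretable and directly
  testable). ρ can be set per cohort; the optimism experiments confound the
  training cohort only, since confounding in the test cohort turns the
  cross-cohort null mean into a seed-dependent coin flip (batch offsets
  dominate floor-level probes and same-pool sets share most genes) rather
  than a clean 0.5 reference.
- **Gene-level parameters are shared across cohorts** (baselines, directions,
  age/sex slopes), while samples, batch effects and noise are per-cohort: a
  planted signal replicates externally, batch noise does not.
- **Platform universes** consist of a shared core (holding all signal,
  background, age- and sex-effect genes — validated at construction) plus
  cohort-specific tail genes, emulating differing array content.
- **Cases can be drawn older** (age_shift_cases) so that skipping matching
  measurably inflates an age-tracking candidate.

Defaults (G = 2000 genes, 150 signal genes at d = 0.8 log₂ units against
σ = 1 noise, 400 background probes at floor 4.0 with sd 0.25, 60 cases/60
controls per cohort, universe 1800 at 85% core overlap) were chosen once to
give clearly detectable but not trivial signal at desk scale; the true
effect and batch variance scales of any real cohort are unknown here and the
data are synthetic by construction. What the generator does **not** emulate:
probe-level bead chemistry, normalisation artefacts, correlated gene modules
(genes are independent given the design), dropout, or RNA-seq counts.
Passing tests therefore demonstrate that the *pipeline logic* behaves as the
statistics predict, not that any particular real signature is valid.

## Pipeline and reproducibility

`run_benchmark` executes load/generate → group selection → optional matching →
candidate evaluation → null sampling/evaluation → significance → report, cell
by cell (one cell per configured arm). One master seed is fanned out to named
per-stage seeds via `numpy.random.SeedSequence`, so a single integer
reproduces a run byte-for-byte; report files contain no timestamps (wall
clock goes to `run.log` only). The rigor checklist (external validation done,
significant in all test cohorts, matched design used, MCI excluded, multiple
testing corrected) is recomputed purely from the report's cells.

Problem sizes in the shipped experiments (1,000-set nulls for calibration and
planted-signature recovery, 500-set nulls for the confounding and filtering
contrasts, two 120-sample cohorts) are the package's chosen desk-scale study
conditions; they complete in a couple of minutes on one core.

## Known limitations

- Gene identifiers are opaque strings; no probe/symbol mapping layer.
- No normalisation or batch *correction* — the pipeline measures batch
  effects, it does not remove them.
- Covariate-matched gene sampling (matching random genes to signature genes
  by mean expression) is a worthy extension, not implemented.
- Within-cohort repeats are correlated (see above); the reported per-repeat
  AUCs should not be treated as independent replicates.
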