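# Methods

## The movement-flux model

`magflux` quantifies net microbial population movement between metagenome
samples from a species-level MAG abundance table (RPKM units in the
intended use).  The model rests on an origin proxy: a species-level MAG is
assumed to originate from the sample in which its representative genome
was recovered, because genomes assemble most readily where read coverage
is highest.  When the dereplication record is unavailable, the origin is
approximated by the sample of maximum abundance (`assign_origins`); an
explicit taxon-to-sample map always overrides the proxy.

Given origins, for every ordered sample pair (A, B):

    f_AB = mean over taxa with origin A of their abundance in B
    F_AB = f_AB − f_BA                (net flux)
    M_AB = (f_AB + f_BA) / 2          (mixture index)

The mean defining `f` runs over *all* of A's taxa, zeros included;
excluding absent taxa would inflate the flux between weakly connected
samples.  F is antisymmetric and its sign names the direction of net
movement; M is symmetric and measures bidirectional exchange; both
inherit the abundance unit and `|F| ≤ 2M` holds identically because
`f ≥ 0`.  Self-flux `f_AA` is computed for diagnostics but excluded from
pair outputs.

## Permutation null and pair labels

Significance is judged against a null that permutes the origin labels
across taxa — a uniform multiset permutation, so per-sample origin counts
are preserved while taxa are reassigned.  One shared stream of `n_perm`
permutations (default 9999) serves all pairs of a run; F and M are
recomputed under each permuted origin map.  Labels follow a fixed
precedence:

1. **Isolated** — observed M strictly below at least `⌈level·n_perm⌉`
   null M values (less exchange than random origin placement);
2. **Transmitted** — observed |F| strictly above at least
   `⌈level·n_perm⌉` null values and the pair is not Isolated; the sign of
   the observed F names the net source;
3. **Mixed** — observed M strictly above the same count of null M values
   and the pair is not Transmitted;
4. **Others** — indistinguishable from the permutation null.

`level` defaults to 0.95.  Ties count against significance (strict
inequalities), which is conservative and deterministic.  The Transmitted
statistic uses |F| by default so the criterion is orientation-invariant;
`use_signed_f=True` switches to the signed statistic.  Permutation is
global across all taxa by default; `stratify_by="medium" | "zone" |
"group"` restricts shuffling to within-stratum taxa for sensitivity
analyses, without any claim that a stratified null is the canonical one.

For small instances, `classify_pairs_exhaustive` enumerates every
distinct arrangement of the origin-label multiset exactly once (all are
equally likely under a uniform permutation) and serves as the exact
oracle for the Monte-Carlo path; it refuses instances above 10⁶
arrangements.

A habitat-level condensation (`summarize_habitat_pair`) reduces the
sample-pair labels between two habitat groups to one regime call:
Transmitted when at least one cross pair is Transmitted and all such
pairs agree on the source habitat; Mixed when no pair is Transmitted but
at least one is Mixed; Isolated when every cross pair is Isolated;
Others otherwise.  This detection-style rule mirrors how group-level
movement statements ("significant movement from X to Y, average net flux
…") are read off per-pair results, and it is the rule the recovery
benchmarks score.

## Supporting statistics

* **GPM** (genes per million): `GPM_k = (r_k/l_k) / Σᵢ(rᵢ/lᵢ) × 10⁶` with
  `r` mapped reads and `l` gene length in bp — arithmetically TPM applied
  to metagenomic gene counts.  Non-empty columns sum to 10⁶ exactly
  (checked at 1e-9 relative tolerance); a sample with zero mapped reads
  becomes an all-zero column with a warning.  Functional-group rows
  (KO/module style) are sums of member-gene GPM; tables aggregated over a
  partial grouping are marked incomplete and exempt from the million-sum
  invariant.
* **Group comparisons**: two-sided Wilcoxon rank-sum per gene row.  The
  exact distribution is used when both groups have ≤ 8 samples and no
  ties; otherwise the tie-corrected normal approximation.  Identical
  constant rows carry no ordering information and report p = 1.  Both
  Benjamini–Hochberg and Bonferroni adjustments are reported, applied
  across gene rows within each group pair; significance codes
  (`.`, `*`, `**`, `***`) key to the FDR-adjusted p at 0.1 / 0.05 /
  0.01 / 0.001.  Rows all-zero in both groups are skipped.
* **Co-occurrence network**: nodes are genes; the co-occurrence level of
  two genes is the binary Jaccard similarity of the MAG sets carrying
  them, and an edge requires level strictly greater than the threshold
  (default 0.3).  The similarity scale is used because a 0.3 cutoff is
  only coherent there; genes carried by no MAG stay as isolated nodes.
* **Distances**: Bray–Curtis (`Σ|x−y| / Σ(x+y)`) and binary Jaccard
  sample-by-sample matrices, exported as square TSV for external
  ordination/PERMANOVA.  A pair of all-zero samples is defined as
  distance 0 (warned for Bray–Curtis, where the formula is 0/0).
* **Shared fraction**: within each zone, a taxon is detected in a medium
  when its abundance exceeds the detection threshold in ≥ 1 sample of
  that medium-zone; a sample's shared fraction is the summed abundance of
  taxa detected in *both* media of its zone divided by its total
  abundance.  This is the weakest defensible reading of "shared member";
  the threshold is exposed because the fraction depends on it.  Zones
  with a single medium are skipped; empty samples report 0.

## Synthetic metacommunity generator

Each sample seeds `taxa_per_sample` taxa whose base abundance is
log-normal (`base_log_mean` 2.0, `base_log_sd` 1.0 on the natural-log
scale — heavy-tailed, like real MAG abundance tables).  A habitat-level
transmission matrix τ copies `τ[A][B] ×` (origin abundance) into every
sample of habitat B, multiplied by log-normal noise with coefficient of
variation `noise_cv` (default 0.2, mean 1).  Samples of the same habitat
exchange nothing, so within-habitat support stays concentrated in the
origin sample.  Abundances below `detection_threshold` are zeroed after
noise (emulating coverage-fraction dropout of rare transmitted taxa), and
origin violations — swapping a taxon's maximum into a random non-origin
sample — are applied last.  The default shape mirrors a 33-sample
four-group trench survey (3 slope-seawater, 9 slope-sediment,
7 bottom-seawater, 14 bottom-sediment samples; 11 taxa per sample,
≈ 360 taxa).

Ground truth includes the origin map and per-pair regimes derived from τ:
Isolated when neither direction exceeds the regime margin, Transmitted
(with source) when exactly one does, Mixed when both do; within-habitat
pairs are Isolated by construction.

Gene counts are negative-binomial (shape `dispersion` = 10) around a
log-normal per-kilobase rate times gene length (uniform 300–3000 bp),
scaled by per-group fold-changes.

What the generator does *not* emulate: phylogenetic structure among taxa,
compositional closure of relative abundances, sample-specific sequencing
depth, binning/dereplication artefacts, and correlated (current-driven)
transport among neighbouring samples.  Passing tests therefore certify
the statistical machinery under the stated abundance model, not the
upstream assembly/binning stack.

## Numerical and design choices

* Origin ties break to the lexicographically smallest sample id; a taxon
  that is zero everywhere with no explicit origin is a hard error.
* A sample contributing zero origin taxa yields a zero flux row with an
  explicit flag rather than an error; a pair with no origin taxa on
  either side is labelled Others with a warning.
* Pair outputs are lexicographically oriented and sorted; identical seed
  and inputs reproduce byte-identical outputs (a single named seedable
  generator drives every stochastic step).
* Benchmarks of exact origin recovery use transmitted fractions
  (τ = 0.3 / 0.1) small enough that τ × noise < 1 holds essentially
  surely — with unbounded multiplicative noise, exact recovery is only
  guaranteed under that precondition (at τ = 0.5, cv = 0.2 a transmitted
  copy overtakes its origin with probability ≈ 1.6e-4 per
  taxon-destination, which is visible at benchmark scale).
* The null-calibration benchmark of rank-sum p-value uniformity uses
  survey-sized groups (9 vs 14), where the large-sample p-values are
  near-continuous; with small groups the exact test's discrete,
  conservative p-values make any uniformity test reject by construction.

## Known limitations

* Detection power of the permutation labels depends on table size: the
  null F and M scale with the whole-table mean abundance, so a pair's
  exchange is only detectable when enough background samples dilute the
  null.  In the desk-scale two-habitat benchmark (6 samples, 50
  taxa/sample) one-way transmission and full isolation are recovered
  essentially always, while symmetric mixing — whose cross-flux itself
  dominates the table mean — is detected in only roughly three quarters
  of replicates (the exact rates are recomputed by
  `scripts/acceptance.py`).  Real surveys with tens of samples sit in the
  favourable regime.
* The origin proxy conflates "sample of the representative genome" with
  "sample of maximum abundance"; when the two disagree the proxy is
  wrong, which the `origin_violation_rate` stress knob simulates.
* No multiple-testing correction is applied across sample pairs in the
  classification, matching the procedure it implements; analytical
  p-values are out of scope.
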