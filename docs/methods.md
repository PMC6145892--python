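# Methods

This note documents the models, the statistical procedures, the parameter
defaults and their rationale, what the synthetic-data generator does and does
not emulate, and the design choices made where the design was genuinely open.
It states no empirical result that the test suite or the acceptance script
does not itself compute.

## Coordinate frame and data model

All analysis happens in transcript space: 0-based, half-open intervals on the
sense strand of annotated transcripts (`utr5_end` = CDS start, `cds_end` =
3'UTR start, CDS length divisible by 3). There is no genome and no read
mapper; aligned reads are records of (transcript, start, length) plus a
mismatch list used only for T>C accounting. Sequences are held in the DNA
alphabet internally; the motif layer accepts RNA or DNA and answers in the
caller's alphabet.

## CLIP site calling

**Window test.** For each 40-nt window (step 1 nt) the number of overlapping
CLIP reads `r_i` is compared to a binomial null with `r` trials (total CLIP
reads in the replicate after QC) and per-trial probability derived from the
mRNA-seq abundance `p_i` of the host transcript. The upper tail
`P(X ≥ r_i)` is computed as the regularized incomplete beta function
`I_p(r_i, r − r_i + 1)`; a window is significant when the tail is below
`1 − prob_cutoff` (default cutoff 0.999). No multiple-testing correction is
applied beyond this cutoff, mirroring the reference procedure; users should
treat per-window significance as a screening call that the downstream
replicate-support and read-count filters consolidate.

**The `p_i` convention.** Two nulls are implemented:

* *transcript-level* (`window_scaled=False`, the literal definition):
  `p_i` is the relative mRNA abundance of the whole transcript. This makes
  the null depend on transcript length and only fires when CLIP coverage is
  concentrated at sites far beyond the per-position enrichment the simulator
  produces — a 15-nt site at 20× on a ~1-kb transcript contributes only a
  third of the whole-transcript expectation, so nothing is ever called.
* *window-level* (`window_scaled=True`, the pipeline default): the null
  probability is scaled to the window. Because a read overlaps a window iff
  its start falls in a span of `width + readlen − 1` positions, the correct
  scale factor is `(width + L̄ − 1)/L` with `L̄` the mean read length —
  scaling by `width/L` alone makes every expressed window ~1.7× "enriched"
  and floods the output with false clusters. `effective_read_length=1`
  recovers the plain `width/L` variant for comparison.

**Clustering and retention.** Significant windows from all replicates are
merged into maximal intervals. A cluster's `replicate_support` is the set of
replicates contributing ≥ 1 significant window to the interval; retained
clusters need support from every replicate and strictly more than 50 CLIP
reads pooled across replicates (the filter is applied to the pooled cluster,
after cross-replicate merging). Cluster regions (5'UTR/CDS/3'UTR) are
assigned by midpoint, with a `(spanning)` suffix kept for audit when the
cluster crosses a boundary.

**T>C profile.** Around motif anchors, the per-offset conversion density is
(T>C mismatches)/(coverage), evaluated only at T/U positions, averaged over
anchors (mean ± SEM). Offsets with no covered T are reported missing rather
than zero.

## Motif discovery and structural elements

The external discovery stack of the reference analysis (MEME/PhyloGibbs,
Patser, RNAclust/LocARNA, Infernal covariance models) is replaced by
self-contained equivalents:

* **PWM learning** — ZOOPS (zero-or-one occurrence per sequence) EM, width 15,
  background = 0-order composition of the training set, pseudocount 0.1.
  Starting points are the three most frequent exact 15-mers plus
  `n_restarts` random windows (MEME-style); the best log-likelihood wins
  after a ±3-column shift refinement that guards against phase-locked
  solutions. Cluster sequences are split into equal training/test halves
  (train = ⌈n/2⌉, seeded shuffle) before learning. On uniform random input
  the learner's self-selection of best-matching windows still sharpens
  columns to ~0.8 bits — a property shared with MEME — so "no motif" should
  be judged against that empirical null ceiling, not against zero.
* **Scanning** — sense-strand log-odds scan; hits at or above the cutoff are
  de-overlapped greedily by score. The default cutoff is the score at which
  5% of shuffled sequences would carry a hit (the 95th percentile of
  per-sequence maximal scores on a shuffle set), a stand-in for an unstated
  threshold in the reference analysis.
* **Stem-loops** — an exhaustive enumeration of (arm, loop) decompositions:
  4–5 nt arms that are exact (optionally wobble-permitting) reverse
  complements enclosing a 3–12 nt loop with U-fraction ≥ 0.5; score = stem
  length + loop U-fraction. CDE-like hairpins use the same rule restricted
  to a tri-loop matching the pyrimidine–purine–pyrimidine pattern, with no
  U-fraction requirement. This rule-based surrogate deliberately trades the
  sensitivity of covariance models for exactness and testability (it equals
  brute force by construction, and the test suite checks that against an
  independently written enumeration).
* **Backgrounds** — three per-sequence mononucleotide shuffles (length and
  composition preserved exactly); a dinucleotide-preserving shuffle is
  available since the composition model is not pinned down. The enrichment
  fold is observed/shuffled hit fractions; the empirical p is the fraction
  of shuffle sets reaching the observed fraction, so with three sets it can
  only take the values {0, 1/3, 2/3, 1}.

**Site counting.** Per transcript, hits of all kinds are unioned and
overlapping hits collapse into single sites; the histogram strata are
1/2/3/4+. Counting motif occurrences (rather than clusters) is one of two
defensible readings of "binding sites per mRNA"; the cluster-level count is
available from the site-calling output directly.

## Ribosome profiling

**A-site offsets.** For each read length, candidate offsets 10–14 nt are
scored by the number of reads whose A-site (5' start + offset) lands on
frame 0 of the CDS; ties break toward the canonical 12 nt. Because this
argmax guarantees frame 0 is nominally maximal even for frame-random reads,
the periodicity verdict additionally requires the frame-0 fraction to reach
0.4 (comfortably above the uniform 1/3 and far below genuine periodicity).
Lengths with fewer than 100 reads are excluded; an experiment in which no
length passes raises rather than silently proceeding.

**Counting and normalization.** RPFs are counted into a gene iff their
A-site lies in the CDS (retained lengths only); mRNA reads count wherever
they align. Size factors are median-of-ratios (genes with any zero excluded
from factor estimation), computed within assay. Fold-changes are
`log2((mean_perturbed + 0.5)/(mean_ctrl + 0.5))` on normalized counts; the
0.5 pseudocount stabilizes low-count genes at the cost of shrinking their
fold-changes toward zero.

**TE test.** `te_log2fc = rpf_log2fc − mrna_log2fc` holds as an exact
identity per gene. Significance comes from permuting condition labels over
(condition, replicate) units, applying the same relabeling to the mRNA and
RPF samples of a unit (so the test is valid even when mRNA levels change).
The distinct relabelings are enumerated (capped at 5000) and `n_perm` of
them are sampled per gene independently, which decorrelates p-values across
genes; the estimator is `(1 + #extreme)/(1 + n_perm)`, two-sided on |TE|.
This is a transparent stand-in for negative-binomial TE machinery (DESeq2 /
babel); its p-values are calibrated but less powerful, and are not
numerically comparable to the reference analysis. A hard design constraint:
with `n` replicates per condition only `C(2n, n)` distinct relabelings
exist, so p-values are grid-valued at 3 + 3 (20 levels) and only become
usefully fine-grained at 5 + 5 (252 levels); calibration experiments in the
test suite therefore use 5 replicates per condition.

**Metagene profiles.** 100-nt bins over the first and last 1000 nt of the
ORF (bin 1 starts at the start codon; bin 10 of the "last" end abuts the
stop codon); only ORFs ≥ 1000 nt contribute, and genes between 1000 and
2000 nt contribute to both ends with overlap. RPFs are binned by A-site,
mRNA reads by midpoint (a convention choice; the reference does not state
one). Per-bin log2 fold-changes are averaged across genes (mean ± SEM).
Size factors should come from the full gene-level count table: normalizing
within a uniformly-repressed gene subset cancels the very signal being
profiled (the workflow does this automatically).

## Stratified comparisons

Mann–Whitney U is computed exactly (full enumeration over group
assignments, correct under ties, two-sided p = `min(1, 2·min(P(U≤u),
P(U≥u)))`) when `n1·n2 ≤ 64`, and by the tie-corrected normal approximation
otherwise. Target/nontarget matching is greedy nearest-neighbor on
log10(3'UTR length) without replacement, reporting the residual KS distance.
The translational-repression set is the `floor(0.10 · n_targets)` targets
with the most negative TE change, ties broken by permutation p then gene id
— a deterministic, transparent rule (on 974 targets it selects 97; the
reference analysis reports 96, suggesting an unstated extra filter that is
deliberately not guessed here). The multiple-element association is a
Pearson chi-square without continuity correction (Yates optional) on
repressed × multiple-elements, where "multiple" means ≥ 2 distinct element
kinds by default (≥ 2 sites of any kind via `multiple_by="sites"`); expected
cells below 5 attach a warning. No multiple-testing correction is applied
across strata pairs by default.

## The synthetic world

The generator emulates: transcript models with realistic length mixes
(5'UTR 50–200 nt, CDS 300–1500 nt, 3'UTR 200–1000 nt, uniform composition,
ATG…TAA ORFs); log-normal abundances (σ = 1 on the log scale); CLIP read
starts proportional to abundance per position, boosted 20× inside planted
sites, read lengths 20–40 nt (an explicit modeling choice — the reference
does not state the post-RNase length distribution); T>C conversions at
planted crosslink uridines with probability 0.55, matching the reported
~0.55–0.57 conversion fraction; mRNA reads uniform along transcripts; RPFs
of 28–30 nt with per-length A-site offsets {11, 12, 13}, frame-0 probability
0.8, and optional 5'-biased pile-up (`rpf_stall_bias`) to emulate elongation
stalls; condition effects as per-stratum log2 fold-changes, by default mRNA
repression deepening with site count (−0.25 to −1) and TE repression
confined to the 4+ stratum (−1), echoing the observed pattern that only
multi-site targets are translationally repressed. Planted sites sit in
3'UTRs, non-overlapping with ≥ 60-nt gaps so that merged clusters resolve
individual sites; the site-count mix (66/15/15/4% for 1/2/3/4+) follows the
observed strata proportions, capped by what physically fits in each 3'UTR.
Read totals per replicate equal the configured depth exactly, and every
site, crosslink and effect size is emitted to ground-truth tables consumed
only by tests.

Not emulated: base-call qualities and sequencing-error structure (a uniform
mismatch rate is available but defaults to 0), PCR duplicates, mapping
ambiguity, isoforms, rRNA contamination, overdispersion beyond multinomial
sampling, and any dependence of binding on RNA structure context. A green
recovery test therefore establishes that the statistics behave correctly
under the stated generative model — not that they are robust to the
technical noise of real libraries.

## Determinism

One top-level seed drives everything; each stage/assay/condition/replicate
derives an independent child stream, so a fixed config reproduces
byte-identical outputs (the workflow report records SHA-256 digests of every
output file, and the test suite checks digest equality across reruns).

## Known limitations

* The literal transcript-level `p_i` null is faithful to its verbal
  definition but essentially inert at realistic per-position enrichments;
  all pipeline defaults use the calibrated window-level null.
* The permutation TE test needs ≥ 4–5 replicates per condition before its
  p-values are fine-grained; at 2–3 replicates they are honest but coarse.
* The rule-based stem-loop detector requires perfect (or wobble) arm
  complementarity and will miss bulged or mismatched stems that covariance
  models would accept.
* The EM motif learner assumes one dominant ungapped motif of fixed width;
  co-occurring secondary motifs are left to repeated runs on residual
  sequences.
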