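# Methods

This note documents the models, parameter choices and numerical conventions
behind `crypticsplice`, and what the synthetic-data tests do and do not
establish about behaviour on real data.

## Cryptic 3′ splice-site calling

Input is the 9-column `SJ.out.tab` junction dialect: chromosome, first and
last intronic base (1-based inclusive), strand code 0/1/2, motif code
(ignored), annotated flag, unique-read count, multi-read count (ignored) and
overhang (ignored). Internally all coordinates are 0-based half-open; the
intron `(first, last)` becomes `[first−1, last)`. On the `+` strand the donor
boundary base is the interval start and the acceptor (the G of the 3′ AG) is
`end − 1`; on `−` the roles flip.

The caller proceeds in fixed order:

1. **Coverage filter.** Junctions whose unique-read total summed across all
   samples is below 50 are dropped. Only uniquely-mapped counts are used —
   a conservative choice, since multi-mapped reads at near-identical
   junctions are ambiguous by construction. The threshold is configurable
   (`min_total_reads`).
2. **Classification.** Each stranded junction's two boundary bases are
   looked up in the strand-matched annotated donor and acceptor site sets
   derived from the GTF (consecutive exons per transcript). Exactly one
   annotated end ⇒ novel splice site; both ⇒ canonical; neither, or
   undefined strand ⇒ excluded from pairing (kept in the table, flagged).
3. **Canonical pairing.** Candidates for a novel junction are the fully
   annotated junctions in the same filtered table sharing its annotated end.
   The partner minimising |novel end − canonical end| is selected. Ties are
   broken toward the partner with the larger read total, then the smaller
   genomic coordinate — determinism was the requirement; the data almost
   never exercises the tie.
4. **Side and direction.** A novel acceptor is a 3′ss event, a novel donor a
   5′ss event; an event is *upstream* when the novel site precedes the
   canonical one in transcript orientation (for 3′ss this is intron-ward:
   on `+`, cryptic < canonical). Downstream and 5′ss events are computed
   and reported but excluded from the default 3′ss analyses.
5. **PSI.** Per sample, PSI = cryptic/(cryptic + canonical) using only the
   single paired canonical junction, undefined (NaN) when the denominator
   is zero. Pooling all junctions sharing the 5′ end into the denominator
   is a defensible alternative; the single-partner definition matches the
   per-pair framing of the statistic and is what the tests pin down.

## Differential usage statistics

Per event, a two-sided Welch (unequal-variance) t-test compares PSI between
groups; the pooled-variance Student test is available via `welch=False` and
is the default in the expression stage. Events with fewer than two defined
PSI values in either group are reported untested rather than raising.
Degenerate inputs: when both groups have zero variance, p = 1 if the means
agree and the smallest positive double otherwise. This convention makes
"no cryptic reads anywhere" literally p = 1, which the control-intron
selection uses: controls are annotated, covered introns that are not the
canonical partner of any detected event, sampled uniformly with a fixed
seed.

Benjamini–Hochberg adjustment is the standard step-up with monotone
enforcement (delegated to statsmodels; tested against a brute-force
implementation of the definition). Significant events require p < 0.05
(strict), side 3′ss, direction upstream, and distance < 50 nt (strict).
Ranking is by descending |ΔPSI| with ties by ascending p then event id.
Row z-scores for heatmap-style matrices use the sample (n−1) standard
deviation; constant rows map to zeros.

## Sequence-context statistics

Windows span positions −100..−1 (intron, with −2,−1 the AG) and +1..+10
(exon) around an acceptor boundary base, in transcript orientation; minus
strand windows are reverse-complemented slices. Windows running off a
chromosome or containing N are dropped with a logged count.

- **Composition/Fisher.** Per-position base counts over the window set; at
  each position and base, a two-sided Fisher exact test on
  [[target base, target not-base], [control base, control not-base]].
  Per-position p-values are reported raw (a −log₁₀ track against 0.05), not
  multiplicity-corrected — the display convention of this analysis; a BH
  option exists in the API via `bh_adjust`.
- **A-run features.** Within −50..−1 (configurable), maximal runs of A are
  classified as A/AA/AAA (exact lengths 1–3) or AAAA (length ≥ 4). Each
  maximal run counts once. An overlapping-k-mer counting mode is available
  behind a flag. Runs are clipped at the region boundary, making features
  invariant to sequence outside the stated region. The AG itself (−2,−1) is
  inside the region, taken literally; a genuine acceptor contributes at most
  one single-A from its A.
- **Group comparison.** The two classes' run-start frequency tracks (fraction
  of windows with a run of the class starting at each offset) are paired by
  position and compared with the Wilcoxon signed-rank test: zero differences
  dropped, midranks for ties, exact two-sided null (2ⁿ sign assignments,
  computed by convolution over doubled midranks) for ≤ 25 informative pairs,
  normal approximation with continuity correction beyond. Pairing by
  position is the only pairing that makes a signed-rank test well-defined
  between two event sets of different sizes, and matches a paired test over
  a shared positional axis. A rank-sum on the per-window counts
  (`RunFeatureMatrix.counts`) is the unpaired alternative.
- **k-mers.** Overlapping 6-mers in −30..−1, frequency = count/total k-mers,
  two-sided Fisher per k-mer against controls, unique ranks by descending
  target frequency with lexicographic tie-break.

## Expression stage

Counts → RPKM (count / (length/10³) / (library/10⁶), library = column sum by
default) → log2 with pseudocount 1 (configurable) → sample-level quantile
normalisation. Quantile normalisation supports two tie policies: averaging
(ties receive the mean of the reference values they would occupy — the
textbook description) and order-stable (`ties="first"`, every column an
exact permutation of the reference vector). With integer counts, ties are
common, and averaging then slightly perturbs the shared distribution; the
pipeline chain uses the order-stable policy so the defining property —
identical sorted columns, exact idempotence — holds exactly. Genes with mean
count below 1 are removed first (the depth cutoff is exposed; no canonical
value exists for it).

Differential expression is a per-gene two-sided Student t-test on the
normalised matrix with BH correction (q < 0.05), Welch switchable. PCA
treats samples as observations of centred, unscaled features and uses full
SVD; scores, loadings and variance fractions are returned. Hierarchical
clustering is agglomerative with Euclidean distance and complete linkage by
default (average and Ward available); the dendrogram is exported in Newick
form and the 3-cut partition is compared against genotype labels where
truth is known.

## Synthetic cohorts

The generator is the package's study design: its defaults are the
conditions under which all recovery and power properties are stated.

**Geometry.** 2000 genes (three exons of 100–250 nt, introns of 280–360 nt,
both strands, 200 genes per chromosome). 300 genes carry one differential
cryptic event each (80 R625H-preferred, 80 K700E-preferred, 40 shared) and
100 carry a null event; the remaining ~3600 introns are event-free and
serve as controls. The affected fraction (~15% of genes) matters: quantile
normalisation assumes most genes are unchanged, and an early draft with
half the genes affected visibly absorbed the planted expression signal into
the normalisation.

**Acceptor context.** Every intron ends in AG preceded by a 23-nt T/C-biased
tract (85% pyrimidine) and a branch-point-like A 26–40 nt upstream. Event
introns get a cryptic AG planted 10–24 nt (uniform) upstream of the
canonical AG, with planted maximal A-runs in the 50 nt upstream of the
cryptic AG: Poisson-distributed counts at 3.5 runs/50 nt background
intensity, multiplied by 3 for R-preferred and 1.5 for K-preferred events
(shared events use 1.5, lacking the R-specific branch-point A excess; null
events use 1). Run lengths 1–4 are drawn with probabilities (0.25, 0.35,
0.22, 0.18) and placed in non-overlapping slots with non-A flanks so each
planted run stays maximal at its drawn length. The base intensity and
length mix were calibrated once — so that the planted R-vs-K contrast is
clearly significant for AA/AAA/AAAA at the motif-analysis set sizes
(350/348 windows), reproducing the qualitative finding the analysis is
built around — and then frozen. Construction guarantees no competing AG
within 8 nt upstream of a planted cryptic AG and none between the cryptic
and canonical AGs.

**Counts.** Per intron and sample, junction depth ~ NegBin(mean 100,
dispersion 10); cryptic reads ~ Binomial(depth, PSI) with class-and-group
PSI (R-preferred: WT 0.02 / K700E 0.15 / R625H 0.40; K-preferred mirrored;
shared 0.02/0.30/0.30; null 0.02 throughout). Gene expression baselines are
log-normal (log-mean 6, log-sd 1); a gene carrying an event has its group
mean scaled by 1 − 0.8 × PSI_group (NMD efficiency 0.8), and counts are
NegBin(dispersion 10) around the mean. Cohort: WT/K700E/R625H × 5 samples.

**What the simulation does not capture.** No read-level alignment artefacts
(the junction table is the contract), no mapping bias, no isoform structure
beyond one cryptic acceptor per gene, no batch effects or covariates, no
sequencing-error model, and i.i.d. negative-binomial noise rather than the
correlated biological variation of real cohorts. Passing recovery tests
therefore demonstrate the correctness of the computational chain under its
own assumptions, not performance on clinical data.

## Problem sizes and study conditions used by the checks

The test suite and `scripts/acceptance.py` run at: 1000 random instances
for caller/enumerator agreement; the default cohort above for recovery,
expression and determinism checks; 2000 equal-PSI events (PSI 0.2 in every
group — high enough that every null junction clears the 50-read coverage
filter, which PSI 0.02 events would not) for type-I error; 200 replicates
at 350/348 windows for poly-A discrimination power; all 2×2 tables with row
margins ≤ 30 for Fisher exactness; n ≤ 12 for exhaustive signed-rank
enumeration; 1000 random vectors for BH.

## Known limitations

- PSI uses the single paired canonical junction; genes with several active
  canonical acceptors sharing one donor are summarised per pair, not per
  donor.
- The one-end-annotated definition cannot see cryptic junctions whose both
  ends are novel, nor annotation errors; it inherits the GTF's notion of
  "known".
- Per-position Fisher tracks are unadjusted by design; with 440
  position×base tests, ~22 nominal false positives are expected at 0.05 and
  should be read as a track, not as individual calls.
- The position-paired signed-rank comparison has at most 50 informative
  pairs and correspondingly bounded power; large per-window effects are
  needed for significance, as the power study documents.
- `select_control_introns` reads "no cryptic usage detected" as "not the
  canonical partner of any detected event", which under the degenerate-case
  convention is exactly p = 1; an intron with a single cryptic read anywhere
  is ineligible.
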