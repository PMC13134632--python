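# crypticsplice

Detection and sequence-context analysis of cryptic 3′ splice-site usage from
RNA-seq splice-junction tables.

Hotspot mutations in the spliceosome factor SF3B1 (most prominently K700E in
hematologic malignancies and R625H in melanomas) redirect branch-point
recognition and activate *cryptic* 3′ splice acceptors, typically 10–24 nt
upstream of the canonical AG. The two hotspots prefer different targets, and
the discriminating feature sits in the intron: R625H-preferred cryptic sites
carry an excess of consecutive adenines (poly-A runs) around the cryptic
branch point, on top of the weakened polypyrimidine tract shared by all
cryptic acceptors. Because the misspliced isoform often gains a premature
termination codon, cryptic usage is coupled to reduced mRNA levels through
nonsense-mediated decay (NMD).

`crypticsplice` implements that analysis end to end for anyone working from
STAR-style junction count files (`SJ.out.tab`), a GTF and a genome FASTA:

- **Cryptic 3′ss calling** — junctions with < 50 uniquely-mapped reads summed
  across samples are removed; a junction with exactly one end matching an
  annotated donor/acceptor is a novel splice site; its canonical partner is a
  fully annotated junction sharing the annotated end, chosen at minimum
  distance; the novel end's role gives side (3′/5′) and direction
  (upstream/downstream) in transcript orientation.
- **Differential usage** — per sample, PSI = c/(c + k) where c and k are the
  cryptic and canonical junction read counts; two-sided Welch t-tests on PSI
  between groups; Benjamini–Hochberg q-values; significant events have
  p < 0.05 and lie < 50 nt upstream of the canonical acceptor; events split
  into R625H- and K700E-preferred sets by the sign of ΔPSI(R − K).
- **Sequence context** — −100..+10 windows around cryptic, canonical and
  control acceptors; per-position A/C/G/T composition with two-sided Fisher
  exact enrichment against controls; maximal consecutive-A runs (A, AA, AAA,
  AAAA with AAAA meaning length ≥ 4) in the −50..−1 region; position-paired
  Wilcoxon signed-rank comparison of run-start frequency tracks between
  mutation classes (exact null up to 25 informative pairs, normal
  approximation with continuity correction beyond); overlapping 6-mer
  enrichment in −30..−1.
- **Expression** — RPKM → log2 → sample-level quantile normalisation;
  per-gene t-tests with BH correction; PCA (samples as observations, centred
  features) and Euclidean-distance hierarchical clustering of both the
  expression and PSI matrices.
- **Synthetic cohorts with ground truth** — a simulator that plants cryptic
  acceptors, class-dependent poly-A context, group PSI differences and
  NMD-coupled expression, so every stage is testable without any external
  data.

## Worked example

`examples/03_sequence_context.py` simulates acceptor windows for the two
mutation classes plus canonical controls and compares their branch-point
context:

```
mean consecutive-A occurrences per window (-50..-1):
  feature    R625H   K700E  control
  A          5.303   6.115    6.238
  AA         3.426   2.879    1.338
  AAA        1.834   1.319    0.354
  AAAA       1.423   0.945    0.106
position-paired Wilcoxon signed-rank, R625H vs K700E:
  AA    W+=  889.0  p=5.95e-04
  AAA   W+=  889.0  p=1.43e-04
  AAAA  W+=  939.0  p=1.37e-05
positions with significant A enrichment vs control: 51 (all at negative offsets: True)
```

Reading this: both mutant classes are A-enriched relative to canonical
acceptors for runs of length ≥ 2, the R625H class significantly more so than
K700E (all three signed-rank p-values < 10⁻³), and every significantly
A-enriched position sits upstream (intron-ward) of the acceptor AG — the
branch-point neighbourhood — not in the exon. The other example scripts walk
through calling (`01`), differential PSI (`02`) and the NMD-coupled
expression stage (`04`).

A complete run over files on disk, from the shell:

```sh
crypticsplice simulate --seed 1 --out sim/
crypticsplice run --sj-dir sim/sj --gtf sim/annotation.gtf \
    --fasta sim/genome.fa --counts sim/counts.tsv --groups sim/groups.tsv \
    --out-dir results/ --seed 1
```

which writes differential-splicing tables, the event BED, composition and
run-feature tables, expression results, a `report.json` summary and a run
manifest.

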