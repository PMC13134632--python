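"""I/O for splice-junction tables, annotation, genome sequence and event exports.

Coordinate conventions
----------------------
All *internal* coordinates are 0-based half-open; every external format is
converted at the boundary:

- SJ.out.tab dialect: 1-based inclusive first/last intronic base; the intron
  ``(first, last)`` maps to the internal interval ``[first - 1, last)``.
- GTF: 1-based inclusive exon intervals.
- BED6 output: 0-based half-open (native).

For an intron stored as ``[start, end)``:

- on the ``+`` strand the donor boundary base is ``start`` and the acceptor
  boundary base (the G of the 3' AG) is ``end - 1``;
- on the ``-`` strand the donor is ``end - 1`` and the acceptor is ``start``.

Strand codes in the SJ dialect are decoded ``0 -> '.'`` (undefined),
``1 -> '+'``, ``2 -> '-'``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import reverse_complement
from pyfaidx import Fasta

SJ_COLUMNS = [
    "chrom",
    "intron_first",
    "intron_last",
    "strand_code",
    "motif_code",
    "annotated_flag",
    "unique_reads",
    "multi_reads",
    "max_overhang",
]

STRAND_DECODE = {0: ".", 1: "+", 2: "-"}
STRAND_ENCODE = {v: k for k, v in STRAND_DECODE.items()}

#: columns identifying one junction across samples (internal coordinates)
JUNCTION_KEY = ["chrom", "start", "end", "strand"]


class ParseError(ValueError):
    """Malformed external input (names the file and line where possible)."""


@dataclass
class JunctionTable:
    """Merged per-sample splice-junction read counts.

    ``df`` has one row per unique junction key with columns
    ``chrom, start, end, strand, annotated_flag`` followed by one unique-read
    count column per sample and a ``total`` column (sum across samples).
    Classification columns (``donor_annotated``, ``acceptor_annotated``,
    ``category``) are added by the cryptic caller.
    """

    df: pd.DataFrame
    samples: list[str] = field(default_factory=list)

    def totals(self) -> pd.Series:
        return self.df["total"]

    def __len__(self) -> int:
        return len(self.df)

    def copy(self) -> "JunctionTable":
        return JunctionTable(self.df.copy(), list(self.samples))


def read_junction_table(paths_by_sample: Mapping[str, str | os.PathLike]) -> JunctionTable:
    """Read and merge per-sample SJ.out.tab files.

    Junctions are merged on ``(chrom, start, end, strand)``; a sample with no
    row for a junction gets count 0. Only the uniquely-mapped read count
    (column 7) is used; the multi-mapped column is ignored. Undefined-strand
    junctions are retained (strand ``'.'``) but excluded from cryptic calling
    downstream.

    Raises
    ------
    ParseError
        On a row with the wrong column count or a non-integer field, or on a
        duplicate junction key within one file.
    """
    frames = []
    samples = list(paths_by_sample)
    for sample, path in paths_by_sample.items():
        rows = []
        seen: set[tuple] = set()
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 9:
                    raise ParseError(
                        f"{path}:{lineno}: expected 9 tab-separated columns, got {len(parts)}"
                    )
                chrom = parts[0]
                try:
                    first, last, strand_code, _motif, ann, uniq = (
                        int(parts[1]),
                        int(parts[2]),
                        int(parts[3]),
                        int(parts[4]),
                        int(parts[5]),
                        int(parts[6]),
                    )
                    int(parts[7]), int(parts[8])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-integer field: {exc}") from exc
                if first < 1 or last < first:
                    raise ParseError(
                        f"{path}:{lineno}: invalid intron coordinates ({first}, {last})"
                    )
                if uniq < 0:
                    raise ParseError(f"{path}:{lineno}: negative read count {uniq}")
                if strand_code not in STRAND_DECODE:
                    raise ParseError(f"{path}:{lineno}: unknown strand code {strand_code}")
                strand = STRAND_DECODE[strand_code]
                key = (chrom, first - 1, last, strand)
                if key in seen:
                    raise ParseError(
                        f"{path}:{lineno}: duplicate junction {chrom}:{first}-{last}({strand})"
                    )
                seen.add(key)
                rows.append(key + (bool(ann), uniq))
        frames.append(
            pd.DataFrame(
                rows,
                columns=JUNCTION_KEY + ["annotated_flag", sample],
            )
        )

    if not frames or all(len(f) == 0 for f in frames):
        df = pd.DataFrame(columns=JUNCTION_KEY + ["annotated_flag"] + samples + ["total"])
        return JunctionTable(df, samples)

    merged: pd.DataFrame | None = None
    for frame in frames:
        if merged is None:
            merged = frame
        else:
            merged = merged.merge(
                frame, on=JUNCTION_KEY, how="outer", suffixes=("", "_r")
            )
            if "annotated_flag_r" in merged.columns:
                merged["annotated_flag"] = (
                    merged["annotated_flag"].astype("boolean").fillna(False)
                    | merged["annotated_flag_r"].astype("boolean").fillna(False)
                ).astype(bool)
                merged = merged.drop(columns=["annotated_flag_r"])
    assert merged is not None
    for sample in samples:
        if sample not in merged.columns:
            merged[sample] = 0
        merged[sample] = merged[sample].fillna(0).astype(int)
    merged["annotated_flag"] = merged["annotated_flag"].astype(bool)
    merged["total"] = merged[samples].sum(axis=1)
    merged = merged.sort_values(JUNCTION_KEY, kind="mergesort").reset_index(drop=True)
    return JunctionTable(merged, samples)


def write_junction_table(table: JunctionTable, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write one 9-column SJ-dialect file per sample (rows with count > 0).

    Inverse of :func:`read_junction_table` up to rows a sample does not
    support; returns ``{sample: path}``.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for sample in table.samples:
        path = os.path.join(out_dir, f"{sample}.SJ.out.tab")
        with open(path, "w") as fh:
            for row in table.df.itertuples(index=False):
                count = getattr(row, sample)
                if count <= 0:
                    continue
                fh.write(
                    "\t".join(
                        str(v)
                        for v in (
                            row.chrom,
                            row.start + 1,
                            row.end,
                            STRAND_ENCODE[row.strand],
                            0,
                            int(row.annotated_flag),
                            count,
                            0,
                            0,
                        )
                    )
                    + "\n"
                )
        paths[sample] = path
    return paths


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # 0-based half-open, sorted


@dataclass
class GenomeAnnotation:
    """Derived annotation sets used by the cryptic caller.

    ``donor_sites`` / ``acceptor_sites`` hold ``(chrom, strand, pos)`` where
    ``pos`` is the 0-based intronic boundary base adjacent to the exon.
    ``introns`` maps ``(chrom, strand, start, end)`` (0-based half-open) to the
    gene id. ``gene_lengths`` is the union-of-exons length in bp.
    """

    transcripts: dict[str, Transcript]
    donor_sites: set[tuple[str, str, int]]
    acceptor_sites: set[tuple[str, str, int]]
    introns: dict[tuple[str, str, int, int], str]
    gene_lengths: dict[str, int]


def intron_sites(chrom: str, strand: str, start: int, end: int) -> tuple[tuple, tuple]:
    """Return ``(donor_site, acceptor_site)`` for an intron ``[start, end)``."""
    if strand == "+":
        return (chrom, strand, start), (chrom, strand, end - 1)
    if strand == "-":
        return (chrom, strand, end - 1), (chrom, strand, start)
    raise ValueError(f"stranded intron required, got {strand!r}")


def read_annotation(gtf_path: str | os.PathLike) -> GenomeAnnotation:
    """Parse exon features from a GTF and derive splice-site sets.

    Donor/acceptor sites and introns come from consecutive exons within each
    transcript; single-exon transcripts contribute no introns. Gene length is
    the length of the union of the gene's exon intervals.

    Raises
    ------
    ParseError
        On malformed GTF rows, missing transcript_id, or overlapping exons
        within one transcript.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            str(gtf_path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:
        raise ParseError(f"{gtf_path}: failed to parse GTF: {exc}") from exc

    exons_by_tx: dict[str, list[tuple[int, int]]] = {}
    tx_meta: dict[str, tuple[str, str, str]] = {}  # tx -> (gene, chrom, strand)
    for feat in db.features_of_type("exon"):
        tx_ids = feat.attributes.get("transcript_id")
        if not tx_ids:
            raise ParseError(f"{gtf_path}: exon without transcript_id at {feat.seqid}:{feat.start}")
        tx = tx_ids[0]
        gene = feat.attributes.get("gene_id", [tx])[0]
        if tx in tx_meta and tx_meta[tx][1:] != (feat.seqid, feat.strand):
            raise ParseError(f"{gtf_path}: transcript {tx} spans chrom/strand")
        tx_meta.setdefault(tx, (gene, feat.seqid, feat.strand))
        exons_by_tx.setdefault(tx, []).append((feat.start - 1, feat.end))  # to 0-based

    transcripts: dict[str, Transcript] = {}
    donor_sites: set[tuple[str, str, int]] = set()
    acceptor_sites: set[tuple[str, str, int]] = set()
    introns: dict[tuple[str, str, int, int], str] = {}
    gene_exons: dict[str, list[tuple[int, int]]] = {}

    for tx, exons in exons_by_tx.items():
        gene, chrom, strand = tx_meta[tx]
        exons = sorted(exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ParseError(f"overlapping exons in transcript {tx}")
        transcripts[tx] = Transcript(tx, gene, chrom, strand, tuple(exons))
        gene_exons.setdefault(gene, []).extend(exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            intron = (chrom, strand, e1, s2)  # [end of left exon, start of right exon)
            if intron[3] <= intron[2]:
                raise ParseError(f"zero-length intron in transcript {tx}")
            introns[intron] = gene
            donor, acceptor = intron_sites(*intron)
            donor_sites.add(donor)
            acceptor_sites.add(acceptor)

    gene_lengths = {gene: _union_length(iv) for gene, iv in gene_exons.items()}
    return GenomeAnnotation(transcripts, donor_sites, acceptor_sites, introns, gene_lengths)


def _union_length(intervals: Iterable[tuple[int, int]]) -> int:
    total = 0
    cur_s = cur_e = None
    for s, e in sorted(intervals):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


class GenomeSequence:
    """Chromosome name -> uppercase nucleotide string over {A,C,G,T,N}."""

    def __init__(self, seqs: Mapping[str, str]):
        self.seqs = {name: seq.upper() for name, seq in seqs.items()}

    @classmethod
    def from_fasta(cls, path: str | os.PathLike) -> "GenomeSequence":
        fasta = Fasta(str(path), rebuild=True, build_index=True)
        return cls({name: str(fasta[name][:]) for name in fasta.keys()})

    def chrom_length(self, chrom: str) -> int:
        return len(self.seqs[chrom])

    def write_fasta(self, path: str | os.PathLike, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.seqs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def extract_sequence(
    genome: GenomeSequence, chrom: str, start: int, end: int, strand: str
) -> str:
    """1-based inclusive slice; ``-`` strand returns the reverse complement.

    Out-of-bounds coordinates raise (no silent clipping).
    """
    if chrom not in genome.seqs:
        raise KeyError(f"unknown chromosome {chrom!r}")
    n = genome.chrom_length(chrom)
    if not (1 <= start <= end <= n):
        raise ValueError(
            f"interval {chrom}:{start}-{end} outside chromosome bounds [1, {n}]"
        )
    seq = genome.seqs[chrom][start - 1 : end]
    if strand == "-":
        return reverse_complement(seq)
    return seq


def write_events(
    events: Sequence,
    psi,
    results,
    out_prefix: str | os.PathLike,
) -> tuple[str, str]:
    """Export cryptic events as a TSV and a BED6 of cryptic acceptor bases.

    The TSV carries coordinates, side, direction, distance, per-group mean
    PSI, dPSI, p and q per event. The BED names the event id and scores it
    ``round(1000 * |dPSI|)``; minus-strand events stay on forward coordinates
    with strand ``-``.
    """
    out_prefix = str(out_prefix)
    tsv_path = out_prefix + ".events.tsv"
    bed_path = out_prefix + ".events.bed"

    res_by_id = {r.event_id: r for r in results} if results is not None else {}
    rows = []
    for ev in events:
        r = res_by_id.get(ev.event_id)
        row = {
            "event_id": ev.event_id,
            "chrom": ev.chrom,
            "strand": ev.strand,
            "side": ev.side,
            "direction": ev.direction,
            "cryptic_pos": ev.cryptic_pos + 1,  # export as 1-based
            "canonical_pos": ev.canonical_pos + 1,
            "shared_pos": ev.shared_pos + 1,
            "distance": ev.distance,
        }
        if r is not None:
            for group, mean in r.group_means.items():
                row[f"mean_psi_{group}"] = mean
            row["delta_psi"] = r.delta_psi
            row["p_value"] = r.p_value
            row["q_value"] = r.q_value
        rows.append(row)
    pd.DataFrame(
        rows,
        columns=[
            "event_id",
            "chrom",
            "strand",
            "side",
            "direction",
            "cryptic_pos",
            "canonical_pos",
            "shared_pos",
            "distance",
        ]
        + sorted({k for row in rows for k in row} - {
            "event_id", "chrom", "strand", "side", "direction",
            "cryptic_pos", "canonical_pos", "shared_pos", "distance",
        }),
    ).to_csv(tsv_path, sep="\t", index=False)

    with open(bed_path, "w") as fh:
        for ev in events:
            r = res_by_id.get(ev.event_id)
            score = 0
            if r is not None and r.delta_psi == r.delta_psi:  # not NaN
                score = int(round(1000 * abs(r.delta_psi)))
            fh.write(
                f"{ev.chrom}\t{ev.cryptic_pos}\t{ev.cryptic_pos + 1}\t"
                f"{ev.event_id}\t{score}\t{ev.strand}\n"
            )
    return tsv_path, bed_path
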