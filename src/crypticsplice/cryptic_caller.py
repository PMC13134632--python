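"""Cryptic splice-site identification from merged junction tables.

The algorithm, applied to a coverage-filtered junction table:

1. classify every stranded junction by whether its donor and acceptor
   boundary bases match annotated splice sites (both / one end / neither);
2. a junction with exactly one annotated end is a candidate novel splice
   site; its canonical partner is a fully annotated junction sharing the
   annotated end, chosen at minimum distance between the two novel/canonical
   ends when several exist;
3. the novel end's role gives the side (novel acceptor -> 3'ss, novel donor
   -> 5'ss) and its position relative to the canonical site in transcript
   orientation gives the direction (upstream / downstream);
4. per-sample PSI = cryptic / (cryptic + canonical) unique junction reads,
   undefined when both counts are zero.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .junction_io import GenomeAnnotation, JunctionTable, intron_sites

logger = logging.getLogger(__name__)

JunctionKey = tuple[str, int, int, str]  # (chrom, start, end, strand), 0-based half-open


@dataclass(frozen=True)
class CrypticEvent:
    """A novel splice site paired with its canonical partner junction."""

    event_id: str
    chrom: str
    strand: str
    side: str  # "3ss" | "5ss"
    direction: str  # "upstream" | "downstream"
    cryptic_pos: int  # 0-based boundary base of the novel end
    canonical_pos: int  # 0-based boundary base of the paired canonical end
    shared_pos: int  # 0-based annotated end shared by both junctions
    distance: int  # |cryptic_pos - canonical_pos|, minimum over candidates
    cryptic_junction_key: JunctionKey
    canonical_junction_key: JunctionKey
    gene_id: str | None = None


@dataclass
class PsiMatrix:
    """Event x sample PSI with companion cryptic/canonical count matrices.

    ``psi`` holds NaN exactly where cryptic + canonical counts are zero.
    """

    psi: pd.DataFrame
    cryptic_counts: pd.DataFrame
    canonical_counts: pd.DataFrame


def filter_low_coverage(table: JunctionTable, min_total: int = 50) -> JunctionTable:
    """Drop junctions whose unique-read total across all samples is < ``min_total``."""
    if min_total < 0:
        raise ValueError(f"min_total must be non-negative, got {min_total}")
    df = table.df[table.df["total"] >= min_total].reset_index(drop=True)
    return JunctionTable(df, list(table.samples))


def classify_junctions(table: JunctionTable, ann: GenomeAnnotation) -> JunctionTable:
    """Label each junction's ends against the annotated donor/acceptor sets.

    Adds ``donor_annotated``, ``acceptor_annotated`` and ``category`` columns;
    categories are ``both`` / ``novel_acceptor`` / ``novel_donor`` /
    ``neither`` / ``unstranded``.
    """
    df = table.df.copy()
    donor_ann = np.zeros(len(df), dtype=bool)
    acceptor_ann = np.zeros(len(df), dtype=bool)
    category = []
    for i, row in enumerate(df.itertuples(index=False)):
        if row.strand not in ("+", "-"):
            category.append("unstranded")
            continue
        donor, acceptor = intron_sites(row.chrom, row.strand, row.start, row.end)
        d = donor in ann.donor_sites
        a = acceptor in ann.acceptor_sites
        donor_ann[i], acceptor_ann[i] = d, a
        if d and a:
            category.append("both")
        elif d:
            category.append("novel_acceptor")
        elif a:
            category.append("novel_donor")
        else:
            category.append("neither")
    df["donor_annotated"] = donor_ann
    df["acceptor_annotated"] = acceptor_ann
    df["category"] = category
    return JunctionTable(df, list(table.samples))


def _junction_key(row) -> JunctionKey:
    return (row.chrom, row.start, row.end, row.strand)


def pair_with_canonical(
    table: JunctionTable, ann: GenomeAnnotation
) -> list[CrypticEvent]:
    """Pair each one-end-annotated junction with its nearest canonical partner.

    Candidates for a novel junction are the fully annotated (``both``)
    junctions in the same table sharing its annotated end; the partner at
    minimum |novel end - canonical end| distance is chosen. Distance ties are
    broken toward the partner with the larger read total, then the smaller
    genomic coordinate. Novel junctions with no candidate are dropped (a
    count is logged).
    """
    df = table.df
    if "category" not in df.columns:
        raise ValueError("run classify_junctions first")

    # index fully annotated junctions by each of their boundary sites
    by_donor: dict[tuple, list] = {}
    by_acceptor: dict[tuple, list] = {}
    for row in df[df["category"] == "both"].itertuples(index=False):
        donor, acceptor = intron_sites(row.chrom, row.strand, row.start, row.end)
        by_donor.setdefault(donor, []).append(row)
        by_acceptor.setdefault(acceptor, []).append(row)

    events: list[CrypticEvent] = []
    n_unpaired = 0
    novel = df[df["category"].isin(["novel_acceptor", "novel_donor"])]
    for row in novel.itertuples(index=False):
        donor, acceptor = intron_sites(row.chrom, row.strand, row.start, row.end)
        if row.category == "novel_acceptor":
            side, shared_site, novel_pos = "3ss", donor, acceptor[2]
            candidates = by_donor.get(shared_site, [])
        else:
            side, shared_site, novel_pos = "5ss", acceptor, donor[2]
            candidates = by_acceptor.get(shared_site, [])
        if not candidates:
            n_unpaired += 1
            continue

        def canonical_end(cand) -> int:
            cd, ca = intron_sites(cand.chrom, cand.strand, cand.start, cand.end)
            return ca[2] if side == "3ss" else cd[2]

        best = min(
            candidates,
            key=lambda c: (abs(novel_pos - canonical_end(c)), -c.total, canonical_end(c)),
        )
        canon_pos = canonical_end(best)
        distance = abs(novel_pos - canon_pos)
        if row.strand == "+":
            upstream = novel_pos < canon_pos
        else:
            upstream = novel_pos > canon_pos
        direction = "upstream" if upstream else "downstream"
        canonical_key = _junction_key(best)
        gene = ann.introns.get((best.chrom, best.strand, best.start, best.end))
        events.append(
            CrypticEvent(
                event_id=f"{row.chrom}:{row.start + 1}-{row.end}:{row.strand}",
                chrom=row.chrom,
                strand=row.strand,
                side=side,
                direction=direction,
                cryptic_pos=novel_pos,
                canonical_pos=canon_pos,
                shared_pos=shared_site[2],
                distance=distance,
                cryptic_junction_key=_junction_key(row),
                canonical_junction_key=canonical_key,
                gene_id=gene,
            )
        )
    if n_unpaired:
        logger.info("dropped %d novel junctions with no canonical partner", n_unpaired)
    events.sort(key=lambda e: (e.chrom, e.cryptic_pos, e.strand, e.side))
    return events


def compute_psi(events: Sequence[CrypticEvent], table: JunctionTable) -> PsiMatrix:
    """Per-sample PSI for each event from raw unique-read junction counts."""
    samples = list(table.samples)
    lookup = {}
    for row in table.df.itertuples(index=False):
        lookup[_junction_key(row)] = np.array(
            [getattr(row, s) for s in samples], dtype=float
        )
    zero = np.zeros(len(samples))
    cryp_rows, canon_rows, ids = [], [], []
    for ev in events:
        cryp = lookup.get(ev.cryptic_junction_key)
        canon = lookup.get(ev.canonical_junction_key)
        if cryp is None or canon is None:
            raise KeyError(f"event {ev.event_id} junctions missing from table")
        cryp_rows.append(cryp if cryp is not None else zero)
        canon_rows.append(canon if canon is not None else zero)
        ids.append(ev.event_id)
    cryptic = pd.DataFrame(cryp_rows, index=ids, columns=samples)
    canonical = pd.DataFrame(canon_rows, index=ids, columns=samples)
    denom = cryptic + canonical
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = cryptic / denom
    psi = psi.where(denom > 0)  # NaN where denominator is zero
    return PsiMatrix(psi=psi, cryptic_counts=cryptic, canonical_counts=canonical)


def distance_histogram(events: Sequence[CrypticEvent]) -> dict[int, int]:
    """Counts of upstream 3'ss events per cryptic-to-canonical distance."""
    return dict(
        Counter(
            ev.distance
            for ev in events
            if ev.side == "3ss" and ev.direction == "upstream"
        )
    )
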