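"""Sequence-context statistics around 3' splice acceptors.

Windows span ``up`` nt of intron (positions -up..-1, with -2,-1 being the AG
for a genuine acceptor) and ``down`` nt of exon (+1..+down) in transcript
orientation; the default is -100..+10. On these windows the module computes
per-position base composition with two-sided Fisher exact enrichment against
control windows, maximal consecutive-A run features (A / AA / AAA / AAAA,
where AAAA means run length >= 4) in a stated upstream region, a paired
Wilcoxon signed-rank comparison of per-position run-start frequency tracks
between groups, and overlapping k-mer enrichment.

These are the statistics that expose the acceptor's recognition context: a
canonical acceptor shows a long T/C-rich polypyrimidine tract, whereas
cryptic acceptors show a weakened tract and adenine-run enrichment in the
branch-point neighbourhood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .junction_io import GenomeSequence, extract_sequence

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
RUN_FEATURES = ("A", "AA", "AAA", "AAAA")


@dataclass(frozen=True)
class SeqWindow:
    """A transcript-oriented acceptor window (positions -up..-1, +1..+down)."""

    site_id: str
    site_class: str  # "cryptic" | "canonical" | "control"
    seq: str
    up: int = 100
    down: int = 10

    def __post_init__(self):
        if len(self.seq) != self.up + self.down:
            raise ValueError(
                f"window {self.site_id}: length {len(self.seq)} != up+down "
                f"{self.up + self.down}"
            )

    def index_of(self, label: int) -> int:
        """Map a position label (-up..-1, +1..+down; no 0) to a string index."""
        if label < 0:
            if label < -self.up:
                raise IndexError(label)
            return label + self.up
        if label == 0 or label > self.down:
            raise IndexError(label)
        return self.up + label - 1

    def region(self, start_label: int, end_label: int) -> str:
        """Inclusive slice between two position labels."""
        return self.seq[self.index_of(start_label) : self.index_of(end_label) + 1]


def position_labels(up: int, down: int) -> list[int]:
    return list(range(-up, 0)) + list(range(1, down + 1))


def extract_windows(
    sites: Iterable[tuple[str, str, str, str, int]],
    genome: GenomeSequence,
    up: int = 100,
    down: int = 10,
) -> list[SeqWindow]:
    """Extract acceptor windows for ``(site_id, site_class, chrom, strand, pos)``.

    ``pos`` is the 0-based acceptor boundary base (the G of the AG). On ``+``
    the forward slice covers that base and ``up - 1`` bases before plus
    ``down`` after; on ``-`` the mirrored slice is reverse-complemented so the
    returned string always reads -up..+down in transcript orientation.
    Windows that would run off the chromosome, and windows containing N, are
    dropped with a logged count.
    """
    windows: list[SeqWindow] = []
    n_off = n_with_n = 0
    for site_id, site_class, chrom, strand, pos in sites:
        e = pos + 1  # 1-based boundary base
        if strand == "+":
            start, end = e - up + 1, e + down
        elif strand == "-":
            start, end = e - down, e + up - 1
        else:
            raise ValueError(f"site {site_id}: stranded position required")
        if start < 1 or end > genome.chrom_length(chrom):
            n_off += 1
            continue
        seq = extract_sequence(genome, chrom, start, end, strand)
        if "N" in seq:
            n_with_n += 1
            continue
        windows.append(SeqWindow(site_id, site_class, seq, up, down))
    if n_off:
        logger.info("dropped %d windows running off a chromosome end", n_off)
    if n_with_n:
        logger.info("dropped %d windows containing N", n_with_n)
    return windows


@dataclass
class CompositionProfile:
    """Per-position base counts/frequencies over a window set."""

    counts: pd.DataFrame  # 4 x L, index BASES, columns position labels
    n_windows: int

    @property
    def frequencies(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = self.counts / totals
        return freq.fillna(0.0)


def composition_profile(windows: Sequence[SeqWindow]) -> CompositionProfile:
    """Count A/C/G/T at each window position."""
    if not windows:
        raise ValueError("at least one window required")
    up, down = windows[0].up, windows[0].down
    labels = position_labels(up, down)
    arr = np.frombuffer(
        "".join(w.seq for w in windows).encode(), dtype="S1"
    ).reshape(len(windows), up + down)
    counts = pd.DataFrame(
        {lab: 0 for lab in labels}, index=list(BASES), dtype=int
    )
    for base in BASES:
        counts.loc[base] = (arr == base.encode()).sum(axis=0)
    return CompositionProfile(counts=counts, n_windows=len(windows))


def fisher_position_enrichment(
    target: CompositionProfile, control: CompositionProfile
) -> pd.DataFrame:
    """Two-sided Fisher exact p per position and base, target vs control.

    The 2x2 table at each (position, base) is
    ``[[target base, target not-base], [control base, control not-base]]``.
    Positions with zero counts in either profile get NaN.
    """
    if list(target.counts.columns) != list(control.counts.columns):
        raise ValueError("profiles must share the same position layout")
    pvals = pd.DataFrame(
        np.nan, index=list(BASES), columns=target.counts.columns, dtype=float
    )
    t_tot = target.counts.sum(axis=0)
    c_tot = control.counts.sum(axis=0)
    for pos in target.counts.columns:
        if t_tot[pos] == 0 or c_tot[pos] == 0:
            continue
        for base in BASES:
            tb = int(target.counts.at[base, pos])
            cb = int(control.counts.at[base, pos])
            _, p = stats.fisher_exact(
                [[tb, int(t_tot[pos]) - tb], [cb, int(c_tot[pos]) - cb]],
                alternative="two-sided",
            )
            pvals.at[base, pos] = p
    return pvals


def maximal_a_runs(seq: str) -> list[tuple[int, int]]:
    """``(start_index, length)`` of every maximal run of A in ``seq``."""
    runs = []
    i, n = 0, len(seq)
    while i < n:
        if seq[i] == "A":
            j = i
            while j < n and seq[j] == "A":
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def _run_feature(length: int) -> str:
    return RUN_FEATURES[min(length, 4) - 1]


@dataclass
class RunFeatureMatrix:
    """Per-window consecutive-A run features over an upstream region.

    ``counts``: window x feature occurrence counts. ``tracks``: per feature,
    a window x position 0/1 matrix marking where a maximal run of that class
    starts (used for position-paired group comparison). ``region`` is the
    inclusive label range scanned, e.g. ``(-50, -1)``.
    """

    counts: pd.DataFrame
    tracks: dict[str, pd.DataFrame]
    region: tuple[int, int]

    def feature_means(self) -> pd.Series:
        """Averaged occurrence of each run feature per window."""
        return self.counts.mean(axis=0)

    def mean_track(self, feature: str) -> pd.Series:
        """Across-window frequency of a run-start at each region position."""
        return self.tracks[feature].mean(axis=0)


def polyA_run_features(
    windows: Sequence[SeqWindow],
    region: tuple[int, int] = (-50, -1),
    overlapping: bool = False,
) -> RunFeatureMatrix:
    """Count consecutive-A features per window within ``region``.

    With the default maximal-run counting, a maximal run of length L counts
    once toward A (L=1), AA (L=2), AAA (L=3) or AAAA (L>=4). With
    ``overlapping=True`` every occurrence of the literal k-mer A/AA/AAA/AAAA
    is counted instead (sliding by one).
    """
    if not windows:
        raise ValueError("at least one window required")
    lo, hi = region
    if not (-windows[0].up <= lo <= hi <= -1):
        raise ValueError(f"region {region} must lie within -{windows[0].up}..-1")
    labels = list(range(lo, hi + 1))
    ids = [w.site_id for w in windows]
    n_pos = hi - lo + 1
    count_arr = np.zeros((len(windows), len(RUN_FEATURES)), dtype=int)
    track_arr = {f: np.zeros((len(windows), n_pos), dtype=int) for f in RUN_FEATURES}
    feat_idx = {f: i for i, f in enumerate(RUN_FEATURES)}
    for wi, w in enumerate(windows):
        sub = w.region(lo, hi)
        if overlapping:
            for f in RUN_FEATURES:
                k = len(f)
                for i in range(len(sub) - k + 1):
                    if sub[i : i + k] == "A" * k:
                        count_arr[wi, feat_idx[f]] += 1
                        track_arr[f][wi, i] = 1
        else:
            for start, length in maximal_a_runs(sub):
                f = _run_feature(length)
                count_arr[wi, feat_idx[f]] += 1
                track_arr[f][wi, start] = 1
    counts = pd.DataFrame(count_arr, index=ids, columns=list(RUN_FEATURES))
    tracks = {
        f: pd.DataFrame(track_arr[f], index=ids, columns=labels)
        for f in RUN_FEATURES
    }
    return RunFeatureMatrix(counts=counts, tracks=tracks, region=region)


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact signed-rank p over all sign assignments (midranks ok)."""
    r2 = np.rint(2 * ranks).astype(int)  # doubled midranks are integers
    total = int(r2.sum())
    # distribution of doubled W+ by convolution over rank inclusion
    dist = np.zeros(total + 1, dtype=float)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= 2.0 ** len(r2)
    w2 = int(np.rint(2 * w_plus))
    p_ge = dist[w2:].sum()
    p_le = dist[: w2 + 1].sum()
    return float(min(1.0, 2.0 * min(p_ge, p_le)))


def compare_run_frequencies(
    group_a: RunFeatureMatrix | pd.Series,
    group_b: RunFeatureMatrix | pd.Series,
    feature: str = "AAAA",
    exact_threshold: int = 25,
) -> tuple[float, float]:
    """Wilcoxon signed-rank on position-paired run-start frequency tracks.

    The two groups' mean frequency tracks are paired by upstream position
    offset; zero differences are dropped (Wilcoxon convention). With at most
    ``exact_threshold`` informative pairs the exact two-sided null over all
    sign assignments is used; beyond that, the normal approximation with
    continuity correction. Returns ``(W_plus, p)``; all-zero differences give
    ``(0.0, 1.0)``.
    """
    ta = group_a.mean_track(feature) if isinstance(group_a, RunFeatureMatrix) else group_a
    tb = group_b.mean_track(feature) if isinstance(group_b, RunFeatureMatrix) else group_b
    if list(ta.index) != list(tb.index):
        raise ValueError("tracks must cover the same positions")
    d = (ta.to_numpy(dtype=float) - tb.to_numpy(dtype=float))
    d = d[d != 0.0]
    if d.size == 0:
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if d.size <= exact_threshold:
        return w_plus, _exact_signed_rank_p(ranks, w_plus)
    res = stats.wilcoxon(d, zero_method="wilcox", correction=True, method="approx")
    return w_plus, float(res.pvalue)


def kmer_enrichment(
    target_windows: Sequence[SeqWindow],
    control_windows: Sequence[SeqWindow],
    k: int = 6,
    region: tuple[int, int] = (-30, -1),
) -> pd.DataFrame:
    """Overlapping k-mer frequencies in ``region`` with Fisher p vs control.

    Returns a DataFrame indexed by k-mer with target/control counts and
    frequencies, a two-sided Fisher p per k-mer, and a unique rank by
    descending target frequency (ties broken lexicographically).
    """
    lo, hi = region
    if hi - lo + 1 < k:
        raise ValueError(f"region {region} shorter than k={k}")

    def count(windows):
        c: dict[str, int] = {}
        total = 0
        for w in windows:
            sub = w.region(lo, hi)
            for i in range(len(sub) - k + 1):
                kmer = sub[i : i + k]
                c[kmer] = c.get(kmer, 0) + 1
                total += 1
        return c, total

    tc, tn = count(target_windows)
    cc, cn = count(control_windows)
    kmers = sorted(set(tc) | set(cc))
    rows = []
    for kmer in kmers:
        a, b = tc.get(kmer, 0), cc.get(kmer, 0)
        _, p = stats.fisher_exact([[a, tn - a], [b, cn - b]], alternative="two-sided")
        rows.append(
            {
                "kmer": kmer,
                "target_count": a,
                "target_freq": a / tn if tn else 0.0,
                "control_count": b,
                "control_freq": b / cn if cn else 0.0,
                "fisher_p": p,
            }
        )
    df = pd.DataFrame(rows).set_index("kmer")
    df = df.sort_values(["target_freq", "kmer"], ascending=[False, True],
                        kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def logo_matrix(profile: CompositionProfile) -> pd.DataFrame:
    """Position x base frequency table, ready for any logo plotter."""
    return profile.frequencies.T


def windows_to_fasta(windows: Sequence[SeqWindow], path) -> None:
    """Write a window set as FASTA (id and site class in the header)."""
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f">{w.site_id} {w.site_class} -{w.up}..+{w.down}\n{w.seq}\n")
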