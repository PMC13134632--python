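"""Independent oracles used across the test suite.

Each oracle implements its statistic or algorithm by direct enumeration or
textbook formula, sharing no code path with the package implementation it
checks.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np
from scipy import stats


# ---------------------------------------------------------------------------
# brute-force cryptic caller: literal pairwise enumeration of the rules
# ---------------------------------------------------------------------------

def oracle_call(junctions, donor_sites, acceptor_sites):
    """Enumerate all junction pairs and apply the calling rules verbatim.

    ``junctions``: list of dicts with keys chrom, start, end (0-based
    half-open), strand, total. Returns a set of event tuples
    ``(cryptic_key, canonical_key, side, distance, direction)``.
    """

    def ends(j):
        if j["strand"] == "+":
            donor = (j["chrom"], j["strand"], j["start"])
            acceptor = (j["chrom"], j["strand"], j["end"] - 1)
        else:
            donor = (j["chrom"], j["strand"], j["end"] - 1)
            acceptor = (j["chrom"], j["strand"], j["start"])
        return donor, acceptor

    def key(j):
        return (j["chrom"], j["start"], j["end"], j["strand"])

    events = set()
    for j in junctions:
        if j["strand"] not in "+-":
            continue
        donor, acceptor = ends(j)
        d_ann = donor in donor_sites
        a_ann = acceptor in acceptor_sites
        if d_ann == a_ann:  # both or neither annotated: not a novel site
            continue
        side = "3ss" if d_ann else "5ss"
        best = None
        for c in junctions:
            if c is j or c["strand"] not in "+-":
                continue
            cd, ca = ends(c)
            if not (cd in donor_sites and ca in acceptor_sites):
                continue
            if side == "3ss":
                if cd != donor:
                    continue
                novel_pos, canon_pos = acceptor[2], ca[2]
            else:
                if ca != acceptor:
                    continue
                novel_pos, canon_pos = donor[2], cd[2]
            dist = abs(novel_pos - canon_pos)
            rank = (dist, -c["total"], canon_pos)
            if best is None or rank < best[0]:
                best = (rank, c, canon_pos, novel_pos)
        if best is None:
            continue
        _, c, canon_pos, novel_pos = best
        dist = abs(novel_pos - canon_pos)
        if j["strand"] == "+":
            direction = "upstream" if novel_pos < canon_pos else "downstream"
        else:
            direction = "upstream" if novel_pos > canon_pos else "downstream"
        events.add((key(j), key(c), side, dist, direction))
    return events


def random_caller_instance(rng: np.random.Generator):
    """A random small annotation + junction set exercising the calling rules.

    Builds a handful of annotated introns per strand, then emits canonical
    junctions, novel-end perturbations (including deliberate equidistant
    ties), double-novel and unstranded junctions.
    """
    donor_sites, acceptor_sites = set(), set()
    junctions = []
    introns = []
    chrom = "chrT"
    pos = 100
    for _ in range(int(rng.integers(2, 8))):
        strand = "+" if rng.random() < 0.5 else "-"
        length = int(rng.integers(80, 200))
        start, end = pos, pos + length
        pos = end + int(rng.integers(50, 150))
        if strand == "+":
            donor_sites.add((chrom, strand, start))
            acceptor_sites.add((chrom, strand, end - 1))
        else:
            donor_sites.add((chrom, strand, end - 1))
            acceptor_sites.add((chrom, strand, start))
        introns.append((chrom, start, end, strand))

    seen = set()

    def add(start, end, strand, total):
        k = (chrom, start, end, strand)
        if k in seen or end - start < 2:
            return
        seen.add(k)
        junctions.append(
            {"chrom": chrom, "start": start, "end": end, "strand": strand,
             "total": int(total)}
        )

    for chrom_, start, end, strand in introns:
        if rng.random() < 0.9:  # canonical junction usually present
            add(start, end, strand, rng.integers(50, 500))
        n_novel = int(rng.integers(0, 3))
        for _ in range(n_novel):
            shift = int(rng.integers(1, 40)) * (1 if rng.random() < 0.7 else -1)
            if rng.random() < 0.7:  # perturb the acceptor-side end
                if strand == "+":
                    add(start, end - shift, strand, rng.integers(50, 200))
                else:
                    add(start + shift, end, strand, rng.integers(50, 200))
            else:  # perturb the donor-side end
                if strand == "+":
                    add(start + shift, end, strand, rng.integers(50, 200))
                else:
                    add(start, end - shift, strand, rng.integers(50, 200))
        if rng.random() < 0.2:  # double-novel junction: must be ignored
            add(start + 3, end - 3, strand, rng.integers(50, 200))
        if rng.random() < 0.1:  # unstranded junction: must be ignored
            add(start, end, ".", rng.integers(50, 200))
    # equidistant canonical partners: two annotated introns sharing a donor
    if rng.random() < 0.5 and introns:
        chrom_, start, end, strand = introns[0]
        d = int(rng.integers(5, 20))
        if strand == "+":
            acceptor_sites.add((chrom, strand, end - 1 + d))
            add(start, end + d, strand, rng.integers(50, 500))
            add(start, end + d // 2, strand, rng.integers(50, 200))
        else:
            acceptor_sites.add((chrom, strand, start - d))
            add(start - d, end, strand, rng.integers(50, 500))
            add(start + d // 2, end, strand, rng.integers(50, 200))
    return junctions, donor_sites, acceptor_sites


# ---------------------------------------------------------------------------
# statistical kernels
# ---------------------------------------------------------------------------

def fisher_two_sided_enum(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by exhaustive hypergeometric enumeration."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(k):
        if k < 0 or k > r1 or c1 - k < 0 or c1 - k > r2:
            return 0.0
        return math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for k in range(0, min(r1, c1) + 1):
        pk = prob(k)
        if pk <= p_obs * (1 + 1e-9):
            total += pk
    return min(1.0, total)


def signed_rank_two_sided_enum(diffs: np.ndarray) -> float:
    """Two-sided signed-rank p by enumerating every sign assignment."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0.0]
    if d.size == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    w_all = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in product([False, True], repeat=len(ranks))
    ]
    w_all = np.array(w_all)
    n = len(w_all)
    p_ge = np.sum(w_all >= w_obs - 1e-12) / n
    p_le = np.sum(w_all <= w_obs + 1e-12) / n
    return min(1.0, 2.0 * min(p_ge, p_le))


def bh_step_up(p: np.ndarray) -> np.ndarray:
    """Textbook BH: q_i = min_{j: p_j >= p_i} (m * p_j / rank_j), capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running_min = np.inf
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, m * p[idx] / rank_from_top)
        q[idx] = min(1.0, running_min)
    return q


def welch_p(a: np.ndarray, b: np.ndarray) -> float:
    """Textbook Welch two-sided p via the Welch-Satterthwaite formula."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return 2.0 * stats.t.sf(abs(t), df)
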