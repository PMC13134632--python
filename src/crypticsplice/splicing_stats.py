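"""Differential cryptic-3'ss usage statistics and event selection.

Per event, group PSI means are compared with a two-sided t-test (Welch by
default; pooled-variance Student available), p-values are adjusted with the
Benjamini-Hochberg step-up procedure, and significant events are those with
p below threshold that lie a short distance upstream of their canonical
acceptor. Degenerate events where both groups have zero variance get p = 1
when the means agree (no usage difference anywhere) and the smallest
representable positive p when they differ; this makes "no cryptic reads in
any sample" literally p = 1, which the control-intron selection relies on.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cryptic_caller import CrypticEvent, PsiMatrix
from .junction_io import GenomeAnnotation

logger = logging.getLogger(__name__)

_TINY_P = np.nextafter(0.0, 1.0)


@dataclass
class SplicingTestResult:
    event_id: str
    group_means: dict[str, float]
    delta_psi: float
    p_value: float  # NaN when the event could not be tested
    q_value: float
    n_per_group: dict[str, int]
    tested: bool = True


def _two_sided_t(a: np.ndarray, b: np.ndarray, welch: bool) -> float:
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        return 1.0 if a.mean() == b.mean() else _TINY_P
    with warnings.catch_warnings():
        # near-constant PSI vectors are routine for null events; the large p
        # scipy returns there is exactly what we want
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.pvalue)


def test_differential_psi(
    psi: PsiMatrix | pd.DataFrame,
    groups: Mapping[str, str],
    group_a: str,
    group_b: str,
    welch: bool = True,
    min_per_group: int = 2,
) -> list[SplicingTestResult]:
    """Two-sided t-test of PSI between two sample groups, per event.

    ``delta_psi`` is mean(group_a) - mean(group_b). Events with fewer than
    ``min_per_group`` non-missing PSI values in either group are reported
    with ``tested=False`` and missing p/q rather than raising. q-values are
    BH-adjusted across the tested events.
    """
    mat = psi.psi if isinstance(psi, PsiMatrix) else psi
    samples_a = [s for s in mat.columns if groups.get(s) == group_a]
    samples_b = [s for s in mat.columns if groups.get(s) == group_b]
    if not samples_a or not samples_b:
        raise ValueError(f"groups {group_a!r}/{group_b!r} not found among samples")

    results: list[SplicingTestResult] = []
    for event_id, row in mat.iterrows():
        a = row[samples_a].dropna().to_numpy(dtype=float)
        b = row[samples_b].dropna().to_numpy(dtype=float)
        means = {group_a: float(a.mean()) if a.size else np.nan,
                 group_b: float(b.mean()) if b.size else np.nan}
        n = {group_a: int(a.size), group_b: int(b.size)}
        if a.size < min_per_group or b.size < min_per_group:
            results.append(
                SplicingTestResult(event_id, means, np.nan, np.nan, np.nan, n, tested=False)
            )
            continue
        p = _two_sided_t(a, b, welch)
        results.append(
            SplicingTestResult(
                event_id, means, means[group_a] - means[group_b], p, np.nan, n
            )
        )
    tested = [r for r in results if r.tested]
    if tested:
        q = bh_adjust(np.array([r.p_value for r in tested]))
        for r, qv in zip(tested, q):
            r.q_value = float(qv)
    n_skipped = len(results) - len(tested)
    if n_skipped:
        logger.info("skipped %d events with <%d usable PSI values per group",
                    n_skipped, min_per_group)
    return results


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone-enforced)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def select_significant_events(
    results: Sequence[SplicingTestResult],
    events: Sequence[CrypticEvent],
    p_max: float = 0.05,
    max_upstream: int = 50,
) -> list[CrypticEvent]:
    """Events with p < ``p_max`` that are upstream 3'ss closer than ``max_upstream`` nt.

    Both inequalities are strict. Output order is deterministic (by event id)
    and independent of input order.
    """
    p_by_id = {r.event_id: r.p_value for r in results if r.tested}
    kept = [
        ev
        for ev in events
        if ev.side == "3ss"
        and ev.direction == "upstream"
        and ev.distance < max_upstream
        and p_by_id.get(ev.event_id, np.nan) < p_max
    ]
    return sorted(kept, key=lambda e: e.event_id)


def rank_top_events(
    results: Sequence[SplicingTestResult], n: int = 30
) -> list[SplicingTestResult]:
    """Top ``n`` results by descending |dPSI|; ties by ascending p, then id."""
    tested = [r for r in results if r.tested]
    ranked = sorted(
        tested, key=lambda r: (-abs(r.delta_psi), r.p_value, r.event_id)
    )
    return ranked[:n]


@dataclass
class EventSelection:
    """Mutation-preferred event sets plus no-cryptic control introns."""

    r_preferred: list[str]
    k_preferred: list[str]
    control_introns: list[tuple] = field(default_factory=list)
    params: dict = field(default_factory=dict)


def split_preferred_sets(
    results_r_vs_k: Sequence[SplicingTestResult],
    events: Sequence[CrypticEvent],
    n_r: int = 350,
    n_k: int = 348,
    p_max: float = 0.05,
    max_upstream: int = 50,
) -> EventSelection:
    """Split significant events into R-preferred / K-preferred sets.

    ``results_r_vs_k`` must carry dPSI = mean(R625H) - mean(K700E); positive
    dPSI events rank into the R-preferred set (top ``n_r`` by dPSI) and
    negative into the K-preferred set (top ``n_k`` by -dPSI).
    """
    significant = select_significant_events(results_r_vs_k, events, p_max, max_upstream)
    sig_ids = {e.event_id for e in significant}
    tested = [r for r in results_r_vs_k if r.tested and r.event_id in sig_ids]
    pos = sorted(
        (r for r in tested if r.delta_psi > 0),
        key=lambda r: (-r.delta_psi, r.p_value, r.event_id),
    )
    neg = sorted(
        (r for r in tested if r.delta_psi < 0),
        key=lambda r: (r.delta_psi, r.p_value, r.event_id),
    )
    return EventSelection(
        r_preferred=[r.event_id for r in pos[:n_r]],
        k_preferred=[r.event_id for r in neg[:n_k]],
        params={"n_r": n_r, "n_k": n_k, "p_max": p_max, "max_upstream": max_upstream},
    )


def select_control_introns(
    ann: GenomeAnnotation,
    events: Sequence[CrypticEvent],
    table,
    n: int = 500,
    seed: int = 0,
) -> list[tuple]:
    """Seeded uniform sample of annotated introns with no cryptic usage.

    Eligible introns are annotated introns present in the (filtered) junction
    table with nonzero canonical coverage that are not the canonical partner
    of any detected cryptic event — i.e. no cryptic read supports an
    alternative end anywhere, which under the degenerate-case convention is
    exactly p = 1. Returns fewer than ``n`` (with a warning) if eligibility
    runs out.
    """
    excluded = {ev.canonical_junction_key for ev in events}
    covered = {
        (row.chrom, row.start, row.end, row.strand)
        for row in table.df.itertuples(index=False)
        if row.total > 0
    }
    eligible = sorted(
        (chrom, strand, start, end)
        for chrom, strand, start, end in ann.introns
        if (chrom, start, end, strand) in covered
        and (chrom, start, end, strand) not in excluded
    )
    rng = np.random.default_rng(seed)
    if len(eligible) <= n:
        if len(eligible) < n:
            logger.warning(
                "only %d eligible control introns (requested %d)", len(eligible), n
            )
        return eligible
    idx = rng.choice(len(eligible), size=n, replace=False)
    return [eligible[i] for i in sorted(idx)]


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-score (sample sd, ddof=1); constant rows map to zeros."""
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # ddof with one column
        sd = values.std(axis=1, ddof=1, keepdims=True)
        z = (values - mean) / sd
    z[~np.isfinite(z)] = 0.0
    if values.shape[1] < 2:
        z[:] = 0.0
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)


def complete_psi_matrix(psi: PsiMatrix | pd.DataFrame) -> pd.DataFrame:
    """Events with PSI defined in every sample (for heatmaps/PCA)."""
    mat = psi.psi if isinstance(psi, PsiMatrix) else psi
    return mat.dropna(axis=0)
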