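"""End-to-end orchestration: call -> test -> select -> motif -> expression -> report.

The pipeline consumes per-sample SJ-dialect junction files, a GTF, a genome
FASTA, a gene count matrix and a sample-group table, and writes result TSVs,
a JSON report and a run manifest into an output directory. All thresholds
default to the analysis' standard values (coverage >= 50 summed reads,
p < 0.05, cryptic acceptor < 50 nt upstream, -100..+10 windows, -50..-1
A-run region, 6-mers over -30..-1). A fixed seed makes a rerun byte-identical.
"""

from __future__ import annotations

import dataclasses
import glob
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__, cryptic_caller, expression_stats, junction_io
from . import sequence_features as seqf
from . import splicing_stats

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Paths, thresholds and toggles for one pipeline run."""

    # inputs
    sj_dir: str = ""
    gtf: str = ""
    fasta: str = ""
    counts: str = ""
    groups: str = ""
    out_dir: str = "crypticsplice_out"
    # group labels
    wt_group: str = "WT"
    k_group: str = "K700E"
    r_group: str = "R625H"
    # thresholds (defaults are the analysis' standard values)
    min_total_reads: int = 50
    p_threshold: float = 0.05
    max_upstream: int = 50
    window_up: int = 100
    window_down: int = 10
    run_region: int = 50
    kmer_k: int = 6
    kmer_region: int = 30
    top_n: int = 30
    n_r_set: int = 350
    n_k_set: int = 348
    n_controls: int = 500
    min_gene_mean: float = 1.0
    welch: bool = True
    seed: int = 0
    # stage toggles
    stages: tuple[str, ...] = ("call", "test", "select", "motif", "expression", "report")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)}")
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        return d


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _read_groups(path: str) -> dict[str, str]:
    if not os.path.exists(path):
        raise PipelineError(f"stage call: groups file not found: {path}")
    df = pd.read_csv(path, sep="\t")
    if not {"sample", "group"} <= set(df.columns):
        raise PipelineError("stage call: groups file needs 'sample' and 'group' columns")
    return dict(zip(df["sample"], df["group"]))


def _sj_paths(sj_dir: str) -> dict[str, str]:
    paths = sorted(glob.glob(os.path.join(sj_dir, "*.SJ.out.tab")))
    if not paths:
        raise PipelineError(f"stage call: no *.SJ.out.tab files under {sj_dir}")
    return {os.path.basename(p)[: -len(".SJ.out.tab")]: p for p in paths}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns in-memory results by name.

    Every stage writes its tables under ``config.out_dir`` and appends row
    counts to the run manifest. Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    _setup_logging(config.out_dir)
    stage_counts: dict[str, int] = {}
    results: dict = {"config": config}
    out = lambda name: os.path.join(config.out_dir, name)

    # ---- stage: call -------------------------------------------------
    try:
        groups = _read_groups(config.groups)
        table = junction_io.read_junction_table(_sj_paths(config.sj_dir))
        ann = junction_io.read_annotation(config.gtf)
        genome = junction_io.GenomeSequence.from_fasta(config.fasta)
        filtered = cryptic_caller.filter_low_coverage(table, config.min_total_reads)
        classified = cryptic_caller.classify_junctions(filtered, ann)
        events = cryptic_caller.pair_with_canonical(classified, ann)
        psi = cryptic_caller.compute_psi(events, classified)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage call: {exc}") from exc
    stage_counts["junctions_raw"] = len(table)
    stage_counts["junctions_filtered"] = len(filtered)
    stage_counts["events"] = len(events)
    results.update(table=classified, annotation=ann, genome=genome,
                   events=events, psi=psi, groups=groups)
    logger.info("call: %d junctions -> %d after filter -> %d events",
                len(table), len(filtered), len(events))

    if "test" not in config.stages:
        _write_manifest(config, stage_counts, results)
        return results

    # ---- stage: test -------------------------------------------------
    try:
        mut_groups = {
            s: ("MUT" if g in (config.k_group, config.r_group) else g)
            for s, g in groups.items()
        }
        res_mut = splicing_stats.test_differential_psi(
            psi, mut_groups, "MUT", config.wt_group, welch=config.welch
        )
        res_rk = splicing_stats.test_differential_psi(
            psi, groups, config.r_group, config.k_group, welch=config.welch
        )
    except Exception as exc:
        raise PipelineError(f"stage test: {exc}") from exc
    results.update(results_mut_vs_wt=res_mut, results_r_vs_k=res_rk)
    stage_counts["events_tested"] = sum(r.tested for r in res_mut)
    _write_results_tsv(res_mut, events, out("diff_splicing_mut_vs_wt.tsv"))
    _write_results_tsv(res_rk, events, out("diff_splicing_r_vs_k.tsv"))

    # ---- stage: select -----------------------------------------------
    significant = top = selection = controls = None
    if "select" in config.stages:
        try:
            significant = splicing_stats.select_significant_events(
                res_mut, events, config.p_threshold, config.max_upstream
            )
            sig_ids = {e.event_id for e in significant}
            top = splicing_stats.rank_top_events(
                [r for r in res_mut if r.event_id in sig_ids], config.top_n
            )
            selection = splicing_stats.split_preferred_sets(
                res_rk, events, config.n_r_set, config.n_k_set,
                config.p_threshold, config.max_upstream,
            )
            controls = splicing_stats.select_control_introns(
                ann, events, classified, config.n_controls, config.seed
            )
            selection.control_introns = controls
        except Exception as exc:
            raise PipelineError(f"stage select: {exc}") from exc
        stage_counts["events_significant"] = len(significant)
        stage_counts["r_preferred"] = len(selection.r_preferred)
        stage_counts["k_preferred"] = len(selection.k_preferred)
        stage_counts["control_introns"] = len(controls)
        results.update(significant=significant, top_events=top, selection=selection)
        res_by_id = {r.event_id: r for r in res_mut}
        junction_io.write_events(
            significant, psi, [res_by_id[e.event_id] for e in significant],
            out("significant"),
        )
        _write_selection_tsv(selection, out("event_selection.tsv"))

    # ---- stage: motif ------------------------------------------------
    if "motif" in config.stages and selection is not None:
        try:
            motif = _motif_stage(config, genome, events, selection)
        except Exception as exc:
            raise PipelineError(f"stage motif: {exc}") from exc
        results["motif"] = motif
        for name, df in motif["tables"].items():
            df.to_csv(out(name), sep="\t")
        stage_counts["windows_cryptic_r"] = motif["n_windows"]["cryptic_r"]
        stage_counts["windows_cryptic_k"] = motif["n_windows"]["cryptic_k"]
        stage_counts["windows_control"] = motif["n_windows"]["control"]

    # ---- stage: expression -------------------------------------------
    if "expression" in config.stages:
        try:
            counts = pd.read_csv(config.counts, sep="\t", index_col=0)
            norm = expression_stats.normalize_expression(
                counts, ann.gene_lengths, config.min_gene_mean
            )
            de = expression_stats.differential_expression(
                norm, mut_groups, "MUT", config.wt_group
            )
            pca_expr = expression_stats.pca(norm)
            psi_complete = splicing_stats.complete_psi_matrix(psi)
            if significant is not None:
                keep = [e.event_id for e in significant if e.event_id in psi_complete.index]
                psi_for_pca = psi_complete.loc[keep] if keep else psi_complete
            else:
                psi_for_pca = psi_complete
            pca_psi = expression_stats.pca(psi_for_pca)
            clust = expression_stats.hierarchical_cluster(
                splicing_stats.zscore_rows(psi_for_pca)
            )
        except Exception as exc:
            raise PipelineError(f"stage expression: {exc}") from exc
        results.update(norm_expression=norm, de=de, pca_expression=pca_expr,
                       pca_psi=pca_psi, clustering=clust)
        stage_counts["genes_normalized"] = len(norm)
        stage_counts["genes_de_significant"] = int(de["significant"].sum())
        norm.rename_axis("gene_id").to_csv(out("expression_normalized.tsv"), sep="\t")
        de.rename_axis("gene_id").to_csv(out("diff_expression.tsv"), sep="\t")
        pca_expr.scores.rename_axis("sample").to_csv(out("pca_expression_scores.tsv"), sep="\t")
        pca_psi.scores.rename_axis("sample").to_csv(out("pca_psi_scores.tsv"), sep="\t")
        with open(out("dendrogram_psi.newick"), "w") as fh:
            fh.write(expression_stats.dendrogram_newick(clust) + "\n")

    # ---- stage: report -----------------------------------------------
    if "report" in config.stages:
        rep = report(results)
        with open(out("report.json"), "w") as fh:
            json.dump(rep, fh, indent=2, sort_keys=True)
        results["report"] = rep

    _write_manifest(config, stage_counts, results)
    return results


def _write_manifest(config: PipelineConfig, stage_counts: dict, results: dict) -> None:
    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "inputs": {
            "sj_dir": config.sj_dir, "gtf": config.gtf, "fasta": config.fasta,
            "counts": config.counts, "groups": config.groups,
        },
        "stage_counts": stage_counts,
    }
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest


def _motif_stage(config, genome, events, selection):
    ev_by_id = {e.event_id: e for e in events}

    def event_sites(ids, site_class, which):
        sites = []
        for eid in ids:
            ev = ev_by_id[eid]
            pos = ev.cryptic_pos if which == "cryptic" else ev.canonical_pos
            sites.append((f"{eid}|{which}", site_class, ev.chrom, ev.strand, pos))
        return sites

    up, down = config.window_up, config.window_down
    win_r = seqf.extract_windows(
        event_sites(selection.r_preferred, "cryptic", "cryptic"), genome, up, down)
    win_k = seqf.extract_windows(
        event_sites(selection.k_preferred, "cryptic", "cryptic"), genome, up, down)
    win_canon = seqf.extract_windows(
        event_sites(selection.r_preferred + selection.k_preferred,
                    "canonical", "canonical"), genome, up, down)
    control_sites = []
    for chrom, strand, start, end in selection.control_introns:
        _, acceptor = junction_io.intron_sites(chrom, strand, start, end)
        control_sites.append(
            (f"{chrom}:{start + 1}-{end}:{strand}|control", "control",
             chrom, strand, acceptor[2])
        )
    win_control = seqf.extract_windows(control_sites, genome, up, down)
    if not win_control:
        raise ValueError("no control windows could be extracted")

    prof_control = seqf.composition_profile(win_control)
    tables = {}
    fisher_tracks = {}
    for name, wins in (("cryptic_r", win_r), ("cryptic_k", win_k),
                       ("canonical", win_canon)):
        if not wins:
            continue
        prof = seqf.composition_profile(wins)
        tables[f"composition_{name}.tsv"] = seqf.logo_matrix(prof).rename_axis("position")
        fisher_tracks[name] = seqf.fisher_position_enrichment(prof, prof_control)
        tables[f"fisher_{name}_vs_control.tsv"] = fisher_tracks[name].rename_axis("base")
    tables["composition_control.tsv"] = seqf.logo_matrix(prof_control).rename_axis("position")

    region = (-config.run_region, -1)
    runs = {}
    for name, wins in (("cryptic_r", win_r), ("cryptic_k", win_k),
                       ("control", win_control)):
        if wins:
            runs[name] = seqf.polyA_run_features(wins, region)
    run_means = pd.DataFrame(
        {name: rf.feature_means() for name, rf in runs.items()}
    ).rename_axis("feature")
    tables["polyA_run_means.tsv"] = run_means

    comparisons = []
    if "cryptic_r" in runs and "cryptic_k" in runs:
        for feat in seqf.RUN_FEATURES:
            w, p = seqf.compare_run_frequencies(runs["cryptic_r"], runs["cryptic_k"], feat)
            comparisons.append({"feature": feat, "comparison": "R625H_vs_K700E",
                                "W_plus": w, "p_value": p})
    comp_df = pd.DataFrame(comparisons).set_index("feature") if comparisons else pd.DataFrame()
    if len(comp_df):
        tables["polyA_run_tests.tsv"] = comp_df

    kmer_region = (-config.kmer_region, -1)
    kmers = {}
    for name, wins in (("cryptic_r", win_r), ("cryptic_k", win_k)):
        if wins:
            kmers[name] = seqf.kmer_enrichment(wins, win_control, config.kmer_k, kmer_region)
            tables[f"kmer_{name}_vs_control.tsv"] = kmers[name]

    return {
        "windows": {"cryptic_r": win_r, "cryptic_k": win_k,
                    "canonical": win_canon, "control": win_control},
        "fisher": fisher_tracks,
        "runs": runs,
        "run_tests": comp_df,
        "kmers": kmers,
        "tables": tables,
        "n_windows": {"cryptic_r": len(win_r), "cryptic_k": len(win_k),
                      "canonical": len(win_canon), "control": len(win_control)},
    }


def report(results: dict) -> dict:
    """Aggregate a machine-readable summary of a pipeline run."""
    events = results.get("events", [])
    side_dir: dict[str, int] = {}
    for ev in events:
        key = f"{ev.side}_{ev.direction}"
        side_dir[key] = side_dir.get(key, 0) + 1
    rep: dict = {
        "n_events": len(events),
        "events_by_side_direction": side_dir,
        "distance_histogram": {
            str(k): v
            for k, v in sorted(cryptic_caller.distance_histogram(events).items())
        },
    }
    if "significant" in results:
        rep["n_significant"] = len(results["significant"])
        rep["top_events"] = [
            {"event_id": r.event_id, "delta_psi": round(r.delta_psi, 6),
             "p_value": r.p_value, "q_value": r.q_value}
            for r in (results.get("top_events") or [])
        ]
        sel = results.get("selection")
        if sel is not None:
            rep["n_r_preferred"] = len(sel.r_preferred)
            rep["n_k_preferred"] = len(sel.k_preferred)
            rep["n_control_introns"] = len(sel.control_introns)
    motif = results.get("motif")
    if motif is not None and len(motif["run_tests"]):
        rep["polyA_run_tests"] = {
            feat: {"W_plus": float(row["W_plus"]), "p_value": float(row["p_value"])}
            for feat, row in motif["run_tests"].iterrows()
        }
        rep["polyA_run_means"] = {
            name: {f: float(v) for f, v in rf.feature_means().items()}
            for name, rf in motif["runs"].items()
        }
    if "de" in results:
        de = results["de"]
        rep["n_genes_tested"] = int(len(de))
        rep["n_de_significant"] = int(de["significant"].sum())
    if "pca_psi" in results:
        rep["pca_psi_variance_fraction"] = [
            round(float(v), 6) for v in results["pca_psi"].variance_fraction[:5]
        ]
    if "pca_expression" in results:
        rep["pca_expression_variance_fraction"] = [
            round(float(v), 6) for v in results["pca_expression"].variance_fraction[:5]
        ]
    if "clustering" in results:
        rep["psi_dendrogram_leaves"] = results["clustering"].leaves
    return rep


def _write_results_tsv(results, events, path):
    ev_by_id = {e.event_id: e for e in events}
    rows = []
    for r in results:
        ev = ev_by_id.get(r.event_id)
        row = {"event_id": r.event_id}
        for g, m in r.group_means.items():
            row[f"mean_psi_{g}"] = m
        row.update(delta_psi=r.delta_psi, p_value=r.p_value, q_value=r.q_value,
                   tested=r.tested)
        if ev is not None:
            row.update(side=ev.side, direction=ev.direction, distance=ev.distance)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_selection_tsv(selection, path):
    rows = [
        {"set": "r_preferred", "id": eid} for eid in selection.r_preferred
    ] + [
        {"set": "k_preferred", "id": eid} for eid in selection.k_preferred
    ] + [
        {"set": "control_intron", "id": f"{c}:{s + 1}-{e}:{st}"}
        for c, st, s, e in selection.control_introns
    ]
    pd.DataFrame(rows, columns=["set", "id"]).to_csv(path, sep="\t", index=False)


def _setup_logging(out_dir: str) -> None:
    log_path = os.path.join(out_dir, "pipeline.log")
    root = logging.getLogger("crypticsplice")
    root.setLevel(logging.INFO)
    if not any(
        isinstance(h, logging.FileHandler)
        and getattr(h, "baseFilename", None) == os.path.abspath(log_path)
        for h in root.handlers
    ):
        handler = logging.FileHandler(log_path, mode="w")
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        root.addHandler(handler)
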