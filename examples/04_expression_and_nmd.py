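"""Expression stage: normalisation, differential expression, PCA, clustering.

Genes carrying a cryptic event are simulated with NMD-coupled depression
(mean scaled by 1 - efficiency * PSI); the example normalises counts
(RPKM -> log2 -> quantile), tests mutant vs wild-type expression, and shows
that the PSI matrix separates the three genotypes.
"""

import tempfile

import numpy as np

from crypticsplice import expression_stats as es
from crypticsplice import synthetic_data as sd
from crypticsplice import splicing_stats as ss

cfg = sd.SimulationConfig(seed=4)
genome, ann, truth = sd.simulate_genome(cfg)
counts = sd.simulate_expression(truth, cfg)

norm = es.normalize_expression(counts, ann.gene_lengths)
groups = cfg.sample_groups
mut_vs_wt = {s: ("MUT" if g != "WT" else "WT") for s, g in groups.items()}
de = es.differential_expression(norm, mut_vs_wt, "MUT", "WT")

event_genes = set(truth.events[truth.events.event_class != "null"].gene_id)
print(f"genes tested                    : {len(de)}")
print(f"significant at q<0.05           : {int(de['significant'].sum())}")
affected = de.loc[[g for g in event_genes if g in de.index]]
frac_down = float((affected["log_diff"] < 0).mean())
print(f"event genes lower in mutants    : {frac_down:.1%} of {len(affected)}")
print(f"median log2 shift (event genes) : {affected['log_diff'].median():+.3f}")

# PSI-based genotype separation
tables = sd.simulate_junction_tables(truth, cfg)
import crypticsplice.cryptic_caller as cc
import crypticsplice.junction_io as jio
with tempfile.TemporaryDirectory() as tmp:
    paths = sd.write_sj_files(tables, tmp)
    table = cc.classify_junctions(
        cc.filter_low_coverage(jio.read_junction_table(paths)), ann)
events = cc.pair_with_canonical(table, ann)
psi = ss.complete_psi_matrix(cc.compute_psi(events, table))
pca = es.pca(psi, n_components=2)
print(f"PSI PCA variance fractions      : "
      f"{np.round(pca.variance_fraction[:2], 3).tolist()}")
clust = es.hierarchical_cluster(ss.zscore_rows(psi))
print(f"dendrogram leaf order           : {clust.leaves}")
print()
print("NMD coupling pulls misspliced genes down in the mutant groups: the")
print("direction of change is consistent even where single genes do not")
print("clear genome-wide significance at this cohort size. The PSI matrix")
print("clusters samples cleanly by genotype; expression separates them")
print("less sharply, mirroring the analysis this emulates.")
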