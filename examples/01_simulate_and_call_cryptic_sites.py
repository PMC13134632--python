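"""Simulate a small cohort and call cryptic 3' splice sites from junctions.

Builds a synthetic genome with planted cryptic acceptors, writes per-sample
SJ.out.tab junction files, then runs the caller: coverage filter (>= 50
summed reads), one-end-annotated classification, canonical pairing with the
minimum-distance rule, and per-sample PSI.
"""

import os
import tempfile

from crypticsplice import cryptic_caller as cc
from crypticsplice import junction_io as jio
from crypticsplice import synthetic_data as sd

with tempfile.TemporaryDirectory() as tmp:
    cfg = sd.SimulationConfig(seed=1, n_genes=200, n_r_preferred=20,
                              n_k_preferred=20, n_shared=5, n_null=10,
                              genes_per_chrom=100)
    sim = sd.simulate_all(cfg, tmp)

    table = jio.read_junction_table(sim["sj_paths"])
    table = cc.filter_low_coverage(table, min_total=50)
    table = cc.classify_junctions(table, sim["annotation"])
    events = cc.pair_with_canonical(table, sim["annotation"])
    psi = cc.compute_psi(events, table)

print(f"junctions after coverage filter : {len(table)}")
print(f"cryptic events called           : {len(events)}")
hist = cc.distance_histogram(events)
print(f"distance histogram (nt -> count): {dict(sorted(hist.items()))}")
first = events[0]
print(f"example event: {first.event_id}  side={first.side} "
      f"direction={first.direction} distance={first.distance} nt")
print(f"  mean PSI across samples: {psi.psi.loc[first.event_id].mean():.3f}")
print()
print("Every called event is a novel acceptor paired to its canonical")
print("acceptor; distances concentrate in the planted 10-24 nt range")
print("upstream, the hallmark localisation of these cryptic 3' sites.")
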