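"""Compare the sequence context of R625H- vs K700E-preferred cryptic sites.

Extracts -100..+10 acceptor windows, computes per-position composition with
Fisher enrichment against control acceptors, counts consecutive-A runs
(A/AA/AAA/AAAA) in the 50 nt upstream, and runs the position-paired Wilcoxon
signed-rank comparison between the two mutation classes.
"""

import numpy as np

from crypticsplice import sequence_features as seqf
from crypticsplice import synthetic_data as sd

cfg = sd.SimulationConfig(seed=3)
rng = np.random.default_rng(3)
win_r = sd.simulate_acceptor_windows(cfg, "r_preferred", 350, rng)
win_k = sd.simulate_acceptor_windows(cfg, "k_preferred", 348, rng)
win_ctrl = sd.simulate_acceptor_windows(cfg, "control", 500, rng)

runs_r = seqf.polyA_run_features(win_r, region=(-50, -1))
runs_k = seqf.polyA_run_features(win_k, region=(-50, -1))
runs_c = seqf.polyA_run_features(win_ctrl, region=(-50, -1))

print("mean consecutive-A occurrences per window (-50..-1):")
print(f"  {'feature':8s} {'R625H':>7s} {'K700E':>7s} {'control':>8s}")
for f in seqf.RUN_FEATURES:
    print(f"  {f:8s} {runs_r.feature_means()[f]:7.3f} "
          f"{runs_k.feature_means()[f]:7.3f} {runs_c.feature_means()[f]:8.3f}")

print("position-paired Wilcoxon signed-rank, R625H vs K700E:")
for f in ("AA", "AAA", "AAAA"):
    w, p = seqf.compare_run_frequencies(runs_r, runs_k, f)
    print(f"  {f:5s} W+={w:7.1f}  p={p:.2e}")

prof_r = seqf.composition_profile(win_r)
prof_ctrl = seqf.composition_profile(win_ctrl)
pvals = seqf.fisher_position_enrichment(prof_r, prof_ctrl)
enriched = ((pvals.loc["A"] < 0.05)
            & (prof_r.frequencies.loc["A"] > prof_ctrl.frequencies.loc["A"]))
print(f"positions with significant A enrichment vs control: "
      f"{int(enriched.sum())} (all at negative offsets: "
      f"{bool(enriched[[p for p in enriched.index if p > 0]].sum() == 0)})")

kmers = seqf.kmer_enrichment(win_r, win_ctrl, k=6, region=(-30, -1))
print("top 3 six-mers upstream of R625H-preferred cryptic AGs:")
print(kmers.head(3)[["target_freq", "control_freq", "fisher_p"]].to_string())
print()
print("R625H-preferred windows carry more and longer A-runs than K700E-")
print("preferred ones near the branch-point region; control (canonical)")
print("acceptors show the T/C-rich polypyrimidine tract instead.")
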