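"""Track epithelial cell centroids during a base-case run.

Centroids are sampled every 10 MCS; per-cell net displacement, total
path length, velocity (path/time) and meandering index (displacement/
path) summarize how motile the T=10 epithelium is.  Expect a meandering
index well below 1: cells jiggle locally much more than they translate.
"""

from cleftsim import motility_stats, run_condition

res = run_condition("base", seed=3, mcs=600, track=True)
rec = res["simulation"].recorder
df, summary = motility_stats(rec.tracks())
print(f"tracked cells            : {summary['n_tracks']}")
print(f"mean net displacement    : {summary['mean_net_displacement_um']:.1f} um")
print(f"mean path length         : {summary['mean_path_length_um']:.1f} um")
print(f"mean velocity            : {summary['mean_velocity_um_per_h']:.1f} um/h")
print(f"mean meandering index    : {summary['mean_meandering_index']:.2f}")
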