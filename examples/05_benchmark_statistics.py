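"""Recompute the six-femur virtual-vs-physical benchmark statistics.

The embedded per-bone table records, for each of six fragmented femurs,
the reconstruction time, mean reconstruction-to-intact distance and the
number of re-associated fragments under both methods.
"""
import vrakit as vk
from vrakit.benchmark import benchmark_summary, femur_benchmark, retention_percent
from vrakit.evaluation import intraclass_correlation

print(femur_benchmark().to_string(index=False))
print()
for key, value in benchmark_summary().items():
    print(f"{key}: {value}")
# e.g. mean_dist_vra_mm 1.0 vs mean_dist_pra_mm 1.1: virtual re-association
# matches the physical method's accuracy while taking 38% less time.
print()
df = femur_benchmark()
print("ICC(1,1) of the distance columns:",
      round(intraclass_correlation(df["mean_dist_vra_mm"], df["mean_dist_pra_mm"]), 4))
print("field triage: ", retention_percent(), "% of 983 fragments retained at >= 2 cm")
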