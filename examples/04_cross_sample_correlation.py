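"""Cross-sample correlations: chromosomes vs centromeres vs a matched null.

Simulates three cell lines that share chromosome-arm timing but each redraw
their centromere timing independently, then compares pairwise Pearson
correlations per chromosome (centromere excluded) and per centromere, and
tests the centromere correlations against a size-matched random-region null.
"""

from centrotime import (build_toy_genome, run_pipeline, simulate_reads,
                        simulate_rt_truth)
from centrotime.compare import (compare_distributions, correlation_table,
                                size_matched_null)
from centrotime.simulate import resample_centromere_truth

layout = build_toy_genome(n_chrom=4, chrom_length=5_000_000,
                          centromere_span=1_000_000)
base = simulate_rt_truth(layout, n_control_points=10, seed=100)

profiles = {}
for i in range(3):
    truth_i = resample_centromere_truth(base, layout, seed=200 + i,
                                        n_control_points=10)
    g1 = simulate_reads(layout, truth_i, "G1", n_fragments=400_000, seed=300 + i)
    s = simulate_reads(layout, truth_i, "S", n_fragments=400_000, seed=400 + i)
    profiles[f"line{i}"] = run_pipeline(g1, s, layout).normalized

tab = correlation_table(profiles, layout)
for cls, sub in tab.groupby("region_class"):
    print(f"{cls}: n={len(sub)}, "
          f"r range [{sub['pearson_r'].min():+.2f}, {sub['pearson_r'].max():+.2f}], "
          f"SD {sub['pearson_r'].std():.3f}")

lengths = (layout.centromeres["end"] - layout.centromeres["start"]).tolist()
null = size_matched_null(profiles, lengths, layout, n_draws=300, seed=7)
summary = compare_distributions(tab[tab["region_class"] == "centromere"], null)
print(f"\nKS test, centromere r vs size-matched null: "
      f"D={summary['ks_statistic']:.3f}, p={summary['p_value']:.2e}")
print(f"SD ratio (observed / null): {summary['sd_ratio']:.2f}")
print("\nArm timing is shared, so chromosome correlations sit near 1; the")
print("independently drawn centromeres give a much broader r distribution")
print("than random regions of the same size — the signature of genuine")
print("between-line centromere variability rather than small-region noise.")
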