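"""Contrast growth layouts by their cross-instance statistics.

Simulates a few instances of one layout per set (same axon rules, same
final density gradient where applicable) and prints the aggregated
signature columns: only the realistically oriented planar layout should
show a significant negative correlation between connection frequency and
density difference, and between area degree and density.
"""

import corticodev as cd

N_INSTANCES = 5  # increase for tighter medians

header = f"{'layout':24s} {'frac':>6s} {'rho(f,|dd|)':>12s} {'sign p':>9s} {'rho(deg,d)':>11s} {'sign p':>9s}"
print(header)
for abbr in (
    "1D-1row-2or",
    "inverse-1D-1row-2or",
    "static-1D-1row-2or",
    "radial-1D-1row-2or",
    "random-1D-1row-2or",
):
    result = cd.analyze_layout(cd.get_layout(abbr), N_INSTANCES, base_seed=0)
    a = result.aggregate
    print(
        f"{abbr:24s} {a['median_fraction_connected']:6.3f} "
        f"{a['median_rho_freq_absdens']:12.2f} {a['sign_p_freq_absdens']:9.2g} "
        f"{a['median_rho_degree_density']:11.2f} {a['sign_p_degree_density']:9.2g}"
    )

# Reading: 'frac' is the median fraction of connected ordered area pairs;
# the rho columns are median Spearman correlations across instances with
# the left-tailed sign test on their p-values (small = consistently
# significant across instances).
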