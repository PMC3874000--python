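"""Colocalization of two fluorescence channels and relapse stratification.

Generates matched relapse / non-relapse stacks whose channel pairs realize
prescribed Pearson correlations (0.73 non-relapse vs 0.60 relapse), computes
the per-stack Pearson colocalization coefficient and the paired group test.
"""

import numpy as np

from ihcquant import (
    FluorSpec,
    compare_coloc_groups,
    generate_fluorescence_stack,
    max_project,
    pearson_coloc,
)

pairs = []
for i in range(4):
    rs = []
    for arm, rho in (("non-relapse", 0.73), ("relapse", 0.60)):
        spec = FluorSpec(
            n_slices=1,
            channels=("FITC", "Cy3"),
            pairwise_rho=(("FITC", "Cy3", rho),),
            n_pixels_per_slice=10_000,
            seed=100 + 10 * i + (arm == "relapse"),
        )
        st = generate_fluorescence_stack(spec)
        res = pearson_coloc(
            max_project(st.channels["FITC"]),
            max_project(st.channels["Cy3"]),
            channel_pair=("FITC", "Cy3"),
        )
        rs.append(res.pearson_r)
        print(f"pair {i} {arm:12s}: r = {res.pearson_r:.3f} "
              f"({res.n_pixels_used} px)")
    pairs.append(tuple(rs))

out = compare_coloc_groups(pairs)
print(f"\nnon-relapse: r = {out['nonrelapse_mean']:.2f} +/- {out['nonrelapse_sd']:.2f} (SD)")
print(f"relapse:     r = {out['relapse_mean']:.2f} +/- {out['relapse_sd']:.2f} (SD)")
print(f"paired t = {out['t']:.2f}, two-sided p = {out['p_two_sided']:.3f}")

# A drop in the Pearson colocalization coefficient between two markers in
# relapse tissue indicates their co-expression pattern changes with disease
# progression — a candidate stratification signal.
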