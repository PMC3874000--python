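"""Compare malignant vs benign expression in a synthetic cohort.

Draws a cohort of per-core area fractions at the group means and standard
errors of a typical tissue-microarray study (benign 1.66 +/- 0.12 %, malignant
4.09 +/- 0.27 %, ~230 cores per group), then computes the fold increase and
the Mann-Whitney test the group comparison rests on.
"""

from ihcquant import CohortSpec, fold_change, generate_cohort, mann_whitney_u
from ihcquant.stats import ks_normality

spec = CohortSpec(
    n_benign=236, n_malignant=228,
    benign_mean_af=1.66, malignant_mean_af=4.09,
    benign_se=0.12, malignant_se=0.27,
    seed=7,
)
cohort = generate_cohort(spec)
ben = cohort.loc[cohort.diagnosis == "benign", "area_fraction"].to_numpy()
mal = cohort.loc[cohort.diagnosis == "malignant", "area_fraction"].to_numpy()

u, p = mann_whitney_u(ben, mal, method="normal_approx")
d, p_norm = ks_normality(mal)

print(f"benign   n={len(ben)}  mean AF = {ben.mean():.2f} %")
print(f"malignant n={len(mal)}  mean AF = {mal.mean():.2f} %")
print(f"fold increase (mean ratio):    {fold_change(ben, mal):.2f}")
print(f"fold increase (mountain AUC):  {fold_change(ben, mal, method='mountain_auc_ratio'):.2f}")
print(f"Mann-Whitney U = {u:.0f}, two-sided p = {p:.3g}")
print(f"KS normality of malignant group: D = {d:.3f}, p = {p_norm:.3g}")

# A fold around 2.5 with p far below 1e-4 mirrors what a marker that more than
# doubles its expression in malignant tissue looks like at this cohort size;
# the KS test shows the skewed area fractions are not normal, which is why the
# comparison uses ranks.
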