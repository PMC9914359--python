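"""Generate a calibrated synthetic cohort and run the group-statistics battery.

The default cohort spec reproduces the published three-class structure:
42 unresponsive-wakefulness (UWS), 61 minimally-conscious (MCS) and 99
emerged (EMCS) patients, with per-class ApEn medians/IQRs, EEG-descriptor
prevalences and etiology mixes taken from the printed cohort table.
"""

from edrcomplex.report import descriptive_report, factorial_report
from edrcomplex.synthetic import CohortSpec, generate_cohort

cohort = generate_cohort(CohortSpec(seed=11))
desc = descriptive_report(cohort)

print(f"cohort: n = {desc['n_total']}, groups = {desc['groups']}")
for g, block in desc["apen"]["by_group"].items():
    print(f"  {g:4s}: ApEn median {block['median']:.2f} [IQR {block['iqr']:.2f}]")
kw = desc["apen"]["kruskal_wallis"]
print(f"Kruskal-Wallis: H = {kw['H']:.2f}, df = {kw['df']}, p = {kw['p']:.2e}")
for row in desc["apen"]["dunn_bonferroni"]:
    print(f"  Dunn {row['pair']}: z = {row['z']:.2f}, corrected p = {row['p_corrected']:.4f}")

react = desc["descriptors"]["reactivity"]
print(f"reactivity present: {react['present']} "
      f"(LR chi-square p = {react['chi_square']['likelihood_ratio']['p']:.4f}, "
      f"subsets {react['subset_letters']})")

fact = factorial_report(cohort)
for term, row in fact["terms"].items():
    print(f"factorial {term}: F = {row['F']:.2f}, p = {row['p']:.3f}")
# Lower ApEn concentrates in the unresponsive class, the omnibus rank test
# is significant, and the post hocs separate UWS from the two higher classes
# — the pattern the cohort spec was calibrated to produce.
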