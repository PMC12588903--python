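"""Select hepatotoxicity marker compounds between a safe and a toxic group.

Builds a two-group study in which THSG and EG carry the between-group
difference, fits OPLS-DA (orthogonal variation removed before the single
predictive component), validates it with a 200x label-permutation test, and
flags markers with the VIP > 1 AND BH-FDR q < 0.05 rule.
"""

import numpy as np

from pmtox import autoscale, fit_oplsda, generate_compound_table, permutation_test, two_group_config
from pmtox.markers import benjamini_hochberg, select_markers, welch_t_test

cfg = two_group_config({"THSG": (12.5, 45.0), "EG": (0.3, 3.0)}, seed=7)
table = generate_compound_table(cfg)
y = np.array([table.group[b] for b in table.batch_ids])
scaled = autoscale(table.concentrations)

model = fit_oplsda(scaled, y, n_orthogonal=1)
print(f"OPLS-DA: R2X={model.r2x:.3f}  R2Y={model.r2y:.3f}  Q2={model.q2:.3f}")
print("(values near 1 mean the single predictive component separates the groups)")

report = permutation_test(scaled, y, n_orthogonal=1, n_permutations=200, seed=1)
print(f"permutation test: valid={report.valid}, Q2 intercept={report.q2_intercept:.3f} "
      "(validity requires all permuted Q2 below the original and a negative intercept)")

p_values = [
    welch_t_test(table.concentrations[y == "G1", j], table.concentrations[y == "G2", j])[1]
    for j in range(len(table.compound_ids))
]
q_values = benjamini_hochberg(p_values)
results = select_markers(table.compound_ids, model.vip, q_values, p_values=p_values)

print("\ncompound            VIP      q       marker")
for r in results[:6]:
    print(f"{r.compound_id:<18s} {r.vip:6.3f}  {r.q_value:8.1e}  {r.is_marker}")
print("\nflagged markers:", [r.compound_id for r in results if r.is_marker])
print("(a borderline chance flag can appear in a single comparison: the BH-FDR")
print("level tolerates ~5% false discoveries per family)")

# The study design suppresses such chance flags by keeping only compounds
# flagged in BOTH the safe-vs-high and safe-vs-medium comparisons.
from pmtox import generate_compound_table as gen  # noqa: E402
from pmtox.markers import common_markers  # noqa: E402
from pmtox.synthetic import three_group_config  # noqa: E402

cfg3 = three_group_config({"THSG": (12.5, 45.0, 25.0), "EG": (0.3, 3.0, 1.5)}, seed=7)
table3 = gen(cfg3)
y3 = np.array([table3.group[b] for b in table3.batch_ids])


def markers_for(ga, gb):
    sel = np.isin(y3, [ga, gb])
    X, yy = table3.concentrations[sel], y3[sel]
    m = fit_oplsda(autoscale(X), yy, 1)
    p = [welch_t_test(X[yy == ga, j], X[yy == gb, j])[1] for j in range(X.shape[1])]
    return select_markers(table3.compound_ids, m.vip, benjamini_hochberg(p))


common = common_markers(markers_for("B", "C"), markers_for("B", "D"))
print("\nmarkers common to both group comparisons:", common)
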