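"""Cohort-level statistics: subset comparisons and learning curves.

Simulates a small cohort (12 subjects x 30 trials; the study design uses
80) and runs the full statistical battery: initial/middle/final subset
comparisons with paired t-tests, post-hoc power and required sample
size; Pearson correlations between the five indices; and logarithmic
learning-curve fits.
"""

from scopeskill import compare_subsets, correlation_matrix, learning_curve, simulate_cohort
from scopeskill.analysis import FINAL, INITIAL, MIDDLE, format_comparison
from scopeskill.exercise import make_setup
from scopeskill.metrics import metrics_table

setup = make_setup()
print("simulating 12 subjects x 30 trials ...")
sessions = simulate_cohort(12, setup, seed=5, n_trials=30)
df = metrics_table(sessions, setup)

print()
print(format_comparison(compare_subsets(df, INITIAL, FINAL)))
print()
print(format_comparison(compare_subsets(df, INITIAL, MIDDLE)))

r, p = correlation_matrix(df)
print("\nPearson correlations (ET, AC, EO, TT, TR):")
print(r.round(2).to_string())

print("\nLog-fit slopes, mean ~ a + b ln(trial):")
for m in ("exec_time_s", "accuracy_pct", "traj_length_mm", "total_rotation_deg"):
    lc = learning_curve(df, m)
    print(f"  {m:<22} b = {lc.slope:9.2f}   R^2 = {lc.r_squared:.3f}")

print("\nNegative slopes for time/path/rotation and a positive slope for"
      "\naccuracy indicate the expected training effect; the paired tests"
      "\nquantify initial-vs-final improvement per metric.")
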