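"""Simulate one synthetic surgeon's 30-trial session and score it.

The synthetic surgeon reaches each target with a minimum-jerk movement,
jitters, corrects its aim, and presses the pedal when its perceived focus
score reaches 100.  Skill parameters improve over trials along an
exponential-approach schedule, producing a logarithmic-looking learning
curve.
"""

import numpy as np

from scopeskill import sample_cohort, simulate_session
from scopeskill.agents import make_protocols
from scopeskill.exercise import make_setup
from scopeskill.io import write_session
from scopeskill.metrics import compute_trial_metrics

setup = make_setup()
params = sample_cohort(1, rng=12)[0]
print(f"subject {params.subject_id} ({params.experience_class}): "
      f"time level {params.a['time']:.1f} -> {params.c['time']:.1f} s/target, "
      f"k = {params.k['time']:.3f}\n")

protocols = make_protocols(30, order_seed=4)
session = simulate_session(params, protocols, setup, np.random.default_rng(99))

print(f"{'trial':>5} {'time (s)':>9} {'accuracy':>9} {'orient err':>11} "
      f"{'path (mm)':>10} {'rotation':>9}")
for log in session.trials[::5]:
    m = compute_trial_metrics(log, setup, params.subject_id)
    print(f"{m.trial_index:>5} {m.exec_time_s:>9.1f} {m.accuracy_pct:>9.1f} "
          f"{m.orientation_error_deg:>11.2f} {m.traj_length_mm:>10.0f} "
          f"{m.total_rotation_deg:>9.0f}")

write_session(session, "session_example.jsonl")
print("\nExecution time and path length fall trial over trial while accuracy"
      "\nrises; the full encoder-level log was written to session_example.jsonl.")
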