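"""Score target focus: percentage of the reticle ellipse inside the ring.

Each wall target is a black ring around an LED.  The trainee centres a
fixed on-screen ellipse inside the ring; accuracy at the pedal press is
the percentage of ellipse area inside the ring's outer boundary.  Here we
project the fundus target from its ideal focusing pose and from
progressively misaimed poses, and print the scores.
"""

import numpy as np

from scopeskill import accuracy_score, is_focused, project_ring
from scopeskill.exercise import make_setup
from scopeskill.kinematics import angles_from_shaft, pose_from_shaft

setup = make_setup()
target = setup.target_by_id(1)          # fundus
ideal = setup.ideal_poses[target.id]
a, b = angles_from_shaft(ideal.shaft_dir)

print(f"target: {target.anatomical_label}, ring outer radius "
      f"{target.ring_outer_radius} mm, nominal roll {target.nominal_roll:.1f} deg\n")
print(f"{'pan offset (rad)':>18} {'score (%)':>10} {'focused':>8}")
for misaim in (0.0, 0.01, 0.02, 0.04, 0.08, 0.15):
    pose = pose_from_shaft(float(a) + misaim, float(b), ideal.insertion_depth,
                           ideal.roll, setup.geom)
    try:
        ring = project_ring(target, pose, setup.cam)
        s = accuracy_score(setup.overlay, ring, setup.cam)
        f = is_focused(setup.overlay, ring, setup.cam)
    except Exception:
        s, f = 0.0, False
    print(f"{misaim:>18.3f} {s:>10.2f} {str(f):>8}")

print("\nA perfectly aimed pose scores 100 (ellipse fully inside the ring);"
      "\nthe score falls monotonically as the aim drifts off the target.")
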