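"""Tendon path length as a function of ankle flexion.

Treats the talus as a cam (base circle = trochlear radius, rise = the
posterior trochlear shelf) and the flexor fibularis tendon as a taut
string from a proximal origin to a distal insertion. Prints the
path-length excursion for several PTS indices: indices <= 1 produce no
cam effect, and excursion grows with the rise.
"""

import numpy as np

from taluscam import cam_excursion, profile_from_index

print("PTS index | rise (mm) | excursion (mm) | peak angle (deg)")
for index in (0.7, 1.0, 1.17, 1.33, 1.5):
    profile = profile_from_index(index, base_radius=3.0)
    curve = cam_excursion(
        profile, np.deg2rad(-60), np.deg2rad(60), n=41
    )
    print(
        f"  {index:5.2f}   |  {profile.rise_height:+5.2f}   |"
        f"    {curve.excursion:7.4f}   |"
        f"   {np.rad2deg(curve.argmax_angle):+6.1f}"
    )
# Excursion is max - min tendon path length over the flexion range: the
# extra tendon travel the cam mechanism imposes. The peak sits in
# dorsiflexion (positive angles) because the rise is posterior.
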