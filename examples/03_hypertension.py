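"""Hypertension experiments under the three mechanosensing hypotheses.

Runs isolated systolic (ISH), isolated diastolic (IDH) and combined (CH)
hypertension with Notch production sensitive to systolic, mean or dynamic
circumferential stretch, and prints the wall-mean NICD relative to the
normotensive reference (120/80 mmHg).  Values below 1 mean a shift to the
synthetic, remodeling-active VSMC phenotype (arterial thickening); above 1
a shift to the contractile phenotype.
"""

from arterynotch import (
    ArteryGeometry,
    CouplingSpec,
    MaterialParameters,
    NotchParameters,
    build_fiber_set,
    calibrate_opening_angle,
    prestretch_profile,
    run_coupled,
)

params = MaterialParameters()
fibers = build_fiber_set(params)
geom = ArteryGeometry()
notch = NotchParameters()
phi = calibrate_opening_angle(geom, params, fibers)
resid = prestretch_profile(geom, phi)

conditions = {"ISH": (160, 80), "IDH": (120, 100), "CH": (160, 100)}

print("wall-mean normalized NICD (1.0 = normotensive reference)")
print(f"{'':>10}" + "".join(f"{h:>10}" for h in ("systolic", "mean", "dynamic")))
for name, (ps, pd) in conditions.items():
    row = []
    for hyp in ("systolic", "mean", "dynamic"):
        res = run_coupled(
            geom, resid, params, fibers, notch,
            CouplingSpec(hypothesis=hyp, p_sys=ps, p_dia=pd),
            n_repeats=2, seed=0,
        )
        row.append(res.normalized_nicd.mean())
    print(f"{name:>10}" + "".join(f"{v:>10.3f}" for v in row))

print(
    "\nonly the mean-stretch hypothesis predicts a synthetic shift (NICD < 1)\n"
    "for all three hypertension types, consistent with the observed\n"
    "thickening of arteries in each of them"
)
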