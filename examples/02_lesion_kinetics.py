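"""Expected DSB (γ-H2AX focus) kinetics for acute vs protracted delivery.

The model tracks reparable lesions (PLLs, produced at k_N per Gy and
removed at rate a+c) and the lethal lesions (LLs) they convert into; the
focus count is their sum δ_N(t).  Protracting the dose lets repair run
during delivery, so fewer lesions are present when the beam stops.
"""

import numpy as np

from imkdose import (
    LesionCurve,
    load_reference_params,
    make_acute,
    make_continuous,
    ll_plateau,
)

hlec = load_reference_params()["HLEC"]
acute = make_acute(1.0, 1.82)
slow = make_continuous(1.0, 0.00081)

times = np.array([0.5, 1.0, 2.5, 6.0, 24.0, 48.0])
for name, sched in (("acute 1.82 Gy/min", acute), ("continuous 0.00081 Gy/min", slow)):
    curve = LesionCurve.evaluate(times, sched, hlec)
    print(f"\n{name} (1 Gy):")
    print(f"  {'t (h)':>6} {'PLL':>8} {'LL':>8} {'foci':>8}")
    for t, x, w, f in zip(curve.times, curve.pll, curve.ll, curve.foci):
        print(f"  {t:>6.1f} {x:>8.3f} {w:>8.4f} {f:>8.3f}")
    print(f"  residual plateau w(inf) = {ll_plateau(sched, hlec):.4f}")

print(
    "\nAcutely, ~35 foci remain at 0.5 h and decay exponentially at a+c = "
    "0.309/h;\nunder 20.6 h of continuous delivery the 0.5 h and 1 h counts are "
    "far lower\n(repair during exposure) while the late residual plateau is "
    "only slightly reduced."
)
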