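"""Bifurcation structure of the biased cell: where automaticity lives.

Sustained oscillation exists only on a window of bias current bounded by
two cycle folds (~2.55 and ~4.70 uA/cm^2 here); the resting and depolarized
fixed-point branches destabilize through subcritical Hopf points just
inside (~2.55 and ~4.46).  The stable cycle length falls monotonically from
~2 s at the lower fold to ~0.53 s at the upper one; the lower Hopf point
and the lower fold nearly coincide, the signature of the subcritical
scenario.
"""

import numpy as np

from myopace import cycle_fold_scan, cycle_length_curve, find_equilibria, hopf_scan

for ibias in (0.0, 3.5):
    eqs = find_equilibria(ibias)
    desc = ", ".join(f"V={e.state.V:.1f} mV ({'stable' if e.stable else 'unstable'})"
                     for e in eqs)
    print(f"Ibias = {ibias}: equilibria {desc}")

h1 = hopf_scan((2.3, 2.8), tol=1e-3, branch="lower")
h2 = hopf_scan((4.0, 4.8), tol=1e-3, branch="upper")
print(f"Hopf points: lower branch {np.round(h1.hopf_points, 3)}, "
      f"upper branch {np.round(h2.hopf_points, 3)} uA/cm^2")

folds = cycle_fold_scan(tol=1e-3, dt=0.01)
flo, fhi = folds.cycle_folds
print(f"stable-cycle folds: {flo:.3f} / {fhi:.3f} uA/cm^2")

ib, cl = cycle_length_curve(flo, fhi, step=0.05, dt=0.01)
print(f"cycle length falls from {cl.max():.0f} ms (near {ib[cl.argmax()]:.2f})"
      f" to {cl.min():.0f} ms (near {ib[cl.argmin()]:.2f})")
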