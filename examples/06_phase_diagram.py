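"""Assemble a pressure/temperature phase diagram from labeled points.

Each lattice condition is classified from its gauche fraction (gel
below 0.20, liquid above 0.24, metastable between); at each temperature
the fluid-gel boundary is bracketed by the last liquid and first gel
pressures, and a logistic fit of the gauche-vs-pressure curve gives the
transition midpoint Pm.
"""

import numpy as np

from bilayerscope import phase

# synthetic per-condition gauche fractions: midpoint rises with T
lattice = np.arange(1.0, 2001.0, 250.0)
points = []
for T, Pm in ((15.0, 200.0), (25.0, 600.0), (35.0, 1200.0)):
    f = 0.14 + 0.14 / (1 + np.exp((lattice - Pm) / 60.0))
    fit = phase.transition_midpoint(lattice, f)
    print(f"T = {T:.0f} °C: fitted Pm = {fit.Pm:6.0f} bar "
          f"(width {fit.width:.0f} bar)")
    for P, v in zip(lattice, f):
        label = phase.classify_phase({"f_gauche": v})
        points.append(phase.PhasePoint(P, T, {"f_gauche": v}, label=label))

diagram = phase.phase_diagram(points)
for T, lo, hi in diagram.boundary:
    print(f"T = {T:.0f} °C: boundary between {lo:.0f} and {hi:.0f} bar")
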