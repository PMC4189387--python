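"""Fixed-point eigenstructure and bifurcation landmarks of the
deterministic Hodgkin-Huxley membrane.

The complex eigenvalue pair -lambda +/- i*omega of the fixed-point
Jacobian sets the subthreshold oscillation: omega is its angular
frequency (the ISI-histogram bumps are spaced at 2*pi/omega) and lambda
its damping.  The Hopf current I1 and the cycle-onset current Iv bracket
the bistable window where quiescence and tonic spiking coexist.
"""

from stochhh import find_cycle_onset, find_hopf, linearize

for I in (5.0, 9.0):
    L = linearize(I)
    print(f"I = {I}: lambda +/- i omega = {L.lambda_re:.3f} +/- {L.omega:.3f}i, "
          f"real eigenvalues {L.ev_slow:.3f}, {L.ev_fast:.2f}")
print(f"subthreshold period at I=5: 2*pi/omega = {linearize(5.0).subthreshold_period:.2f} ms")
print(f"Hopf bifurcation I1 = {find_hopf():.3f} uA/cm^2")
print(f"cycle onset Iv = {find_cycle_onset():.3f} uA/cm^2")
print("-> between Iv and I1 the deterministic membrane is bistable.")
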