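"""Model parameters for the stochastic Hodgkin-Huxley membrane patch.

Voltages follow the modern convention (resting potential near -65 mV),
which is the frame the standard squid-axon rate functions are written in.
Channel counts are derived from fixed channel densities and the membrane
area of the simulated patch, so the area is the single knob that sets the
channel-noise amplitude (noise standard deviation scales as area^-1/2).
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace


@dataclass(frozen=True)
class HHParameters:
    """Constants of the Hodgkin-Huxley membrane, squid-axon values.

    Attributes
    ----------
    C : float
        Membrane capacitance, uF/cm^2.
    gK_max, gNa_max, gL : float
        Maximal potassium / sodium conductance and leak conductance,
        mS/cm^2.
    VK, VNa, VL : float
        Reversal potentials, mV (modern convention).
    rhoK, rhoNa : float
        Channel densities, channels/um^2.
    area : float
        Membrane area of the patch, um^2. Sets the channel counts and
        thereby the channel-noise level.
    """

    C: float = 1.0
    gK_max: float = 36.0
    gNa_max: float = 120.0
    gL: float = 0.3
    VK: float = -77.0
    VNa: float = 50.0
    VL: float = -54.4
    rhoK: float = 18.0
    rhoNa: float = 60.0
    area: float = 400.0

    def __post_init__(self) -> None:
        for name in ("C", "gK_max", "gNa_max", "gL", "rhoK", "rhoNa", "area"):
            v = getattr(self, name)
            if not (v > 0):
                raise ValueError(f"{name} must be strictly positive, got {v!r}")

    @property
    def NK(self) -> int:
        """Number of potassium channels in the patch."""
        return int(round(self.rhoK * self.area))

    @property
    def NNa(self) -> int:
        """Number of sodium channels in the patch."""
        return int(round(self.rhoNa * self.area))

    def with_area(self, area: float) -> "HHParameters":
        return replace(self, area=area)


_FIELD_NAMES = {f.name for f in fields(HHParameters)}


def params_from_config(text: str) -> HHParameters:
    """Build parameters from a plain-text ``key = value`` configuration.

    Lines starting with ``#`` and blank lines are ignored.  Keys are the
    attribute names of :class:`HHParameters`; unknown keys raise.
    """
    overrides: dict[str, float] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in _FIELD_NAMES:
            raise ValueError(f"line {lineno}: unknown parameter {key!r}")
        overrides[key] = float(value)
    return HHParameters(**overrides)
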