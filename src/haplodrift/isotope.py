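"""Stable-isotope estimation of the marine fraction of dietary carbon.

Skeletal collagen delta-13C reflects the mix of terrestrial and marine
protein in the diet.  With endmember means measured on faunal bone from
the same shell middens (terrestrial land mammals vs marine fish), the
marine fraction follows from linear two-endmember mixing; it is the input
to marine-reservoir correction of radiocarbon dates (the reservoir offset
``delta_R`` is carried here for downstream calibration software, which is
out of scope for this package).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ReservoirParams", "marine_fraction"]


@dataclass(frozen=True)
class ReservoirParams:
    """Endmember and reservoir-correction parameters.

    Defaults are the Tokyo Bay / Chiba shell-midden values: terrestrial
    endmember -22.6 permil, marine endmember -10.9 permil, a 5% margin of
    error on the fraction, and a regional reservoir correction
    delta_R = -98 +/- 37 years.
    """

    delta13C_terrestrial: float = -22.6
    delta13C_marine: float = -10.9
    margin: float = 0.05
    delta_R: float = -98.0
    delta_R_error: float = 37.0

    def __post_init__(self) -> None:
        if not self.delta13C_marine > self.delta13C_terrestrial:
            raise ValueError("marine endmember must exceed terrestrial endmember")
        if not 0.0 <= self.margin <= 1.0:
            raise ValueError("margin must be a fraction in [0, 1]")


def marine_fraction(
    delta13C_observed: float, params: ReservoirParams | None = None
) -> tuple[float, float]:
    """Marine dietary fraction from an observed collagen delta-13C.

    Linear mixing between the terrestrial and marine endmembers,
    ``(obs - terrestrial) / (marine - terrestrial)``, clipped to [0, 1];
    observed values outside the endmember range therefore map to the
    nearest endmember.  Returns ``(fraction, margin)``.
    """
    p = params if params is not None else ReservoirParams()
    span = p.delta13C_marine - p.delta13C_terrestrial
    fraction = (delta13C_observed - p.delta13C_terrestrial) / span
    return min(1.0, max(0.0, fraction)), p.margin
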