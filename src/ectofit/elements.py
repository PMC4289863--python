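"""Atomic masses and soft-sphere radii for the elements that occur in proteins.

Masses are standard atomic weights (Da). Radii are per-element soft-sphere
radii (Å) used by the repulsive nonbonded term and the clash criterion; they
are deliberately smaller than van der Waals radii so that only genuinely
bad contacts are penalised.
"""

from __future__ import annotations

ATOMIC_MASS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "SE": 78.971,
    "FE": 55.845,
    "ZN": 65.38,
    "MG": 24.305,
    "CA": 40.078,
    "MN": 54.938,
    "NA": 22.990,
    "K": 39.098,
    "CL": 35.45,
}

SOFT_RADIUS: dict[str, float] = {
    "H": 0.9,
    "C": 1.35,
    "N": 1.25,
    "O": 1.2,
    "S": 1.45,
    "P": 1.45,
}
_DEFAULT_SOFT_RADIUS = 1.35


def mass_of(element: str) -> float:
    """Atomic mass in Da; raises ``KeyError`` for unknown elements."""
    m = ATOMIC_MASS.get(element.upper())
    if m is None:
        raise KeyError(f"no mass tabulated for element {element!r}")
    return m


def soft_radius_of(element: str) -> float:
    return SOFT_RADIUS.get(element.upper(), _DEFAULT_SOFT_RADIUS)
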