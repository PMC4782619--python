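"""Named benchmark phantoms.

A small catalogue of circular-phantom configurations on the standard 75 mm
domain (background 0.21 S/m, anomalies 0.005 S/m) used across the test
suite and the demo command: a single off-centre object, centred objects of
decreasing size, and symmetric two- and three-object arrangements.
"""

from __future__ import annotations

import math

from .phantom import Inhomogeneity, PhantomSpec

__all__ = ["make_fixture", "FIXTURE_NAMES"]

_RP = 0.075  # domain radius, m
_SB = 0.21  # background conductivity, S/m
_SI = 0.005  # anomaly conductivity, S/m


def _spec(*inhs: tuple[float, float, float]) -> PhantomSpec:
    """Build a spec from (center_r_mm, theta_deg, radius_mm) triples."""
    return PhantomSpec(
        domain_radius=_RP,
        background_conductivity=_SB,
        inhomogeneities=tuple(
            Inhomogeneity(
                center_r=r_mm * 1e-3,
                center_theta=math.radians(th_deg),
                radius=ri_mm * 1e-3,
                conductivity=_SI,
            )
            for r_mm, th_deg, ri_mm in inhs
        ),
    )


_CATALOGUE = {
    # Single off-centre object at r = 37.5 mm, theta = 45 deg, ri = 25 mm.
    "fig1": _spec((37.5, 45.0, 25.0)),
    "fig4": _spec((37.5, 45.0, 25.0)),
    # ri = 30 mm object, centred and off-centre.
    "fig6a": _spec((0.0, 0.0, 30.0)),
    "fig6c": _spec((37.5, 0.0, 30.0)),
    # Centred objects of decreasing radius: 40, 30, 20, 10 mm.
    "fig7a": _spec((0.0, 0.0, 40.0)),
    "fig7c": _spec((0.0, 0.0, 30.0)),
    "fig7e": _spec((0.0, 0.0, 20.0)),
    "fig7g": _spec((0.0, 0.0, 10.0)),
    # Two objects 180 deg apart and three objects 120 deg apart,
    # all ri = 25 mm at r = 37.5 mm.
    "fig8a": _spec((37.5, 0.0, 25.0), (37.5, 180.0, 25.0)),
    "fig8c": _spec((37.5, 0.0, 25.0), (37.5, 120.0, 25.0), (37.5, 240.0, 25.0)),
}

FIXTURE_NAMES = tuple(sorted(_CATALOGUE))


def make_fixture(name: str) -> PhantomSpec:
    """Return the phantom specification registered under *name*."""
    try:
        return _CATALOGUE[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        ) from None
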