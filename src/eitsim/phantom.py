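"""Circular phantoms: geometric specification and per-element conductivity.

A phantom is a disk of background conductivity sigma_b containing zero or
more circular inhomogeneities, each placed by the polar coordinates of its
centre (r, theta) and given its own radius and conductivity.  Realizing a
phantom on a mesh assigns each element the conductivity of the region its
centroid falls in, so the discrete map is exactly two-valued per region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import TriMesh, element_centroids, element_geometry_arrays

__all__ = [
    "Inhomogeneity",
    "PhantomSpec",
    "ConductivityMap",
    "PhantomSummary",
    "realize_phantom",
    "phantom_summary",
]

# Centroids exactly on an inhomogeneity rim (to within this relative slack)
# count as background: membership is strictly "inside".
_RIM_RTOL = 1e-12


@dataclass(frozen=True)
class Inhomogeneity:
    """One circular anomaly: centre in polar coordinates (metres, radians),
    radius in metres, conductivity in S/m."""

    center_r: float
    center_theta: float
    radius: float
    conductivity: float

    @property
    def center(self) -> np.ndarray:
        return np.array(
            [
                self.center_r * np.cos(self.center_theta),
                self.center_r * np.sin(self.center_theta),
            ]
        )


@dataclass(frozen=True)
class PhantomSpec:
    """Validated phantom description.

    Invariants enforced at construction: positive conductivities, every
    anomaly disk inside the domain, and pairwise disjoint anomalies.
    """

    domain_radius: float
    background_conductivity: float
    inhomogeneities: tuple[Inhomogeneity, ...] = field(default_factory=tuple)

    def __post_init__(self):
        object.__setattr__(self, "inhomogeneities", tuple(self.inhomogeneities))
        if not self.domain_radius > 0:
            raise ValueError(f"domain_radius must be positive, got {self.domain_radius}")
        if not self.background_conductivity > 0:
            raise ValueError(
                f"background_conductivity must be positive, got {self.background_conductivity}"
            )
        tol = 1e-12 * self.domain_radius
        for i, inh in enumerate(self.inhomogeneities):
            if not inh.radius > 0:
                raise ValueError(f"inhomogeneity {i}: radius must be positive")
            if not inh.conductivity > 0:
                raise ValueError(f"inhomogeneity {i}: conductivity must be positive")
            if inh.center_r < 0:
                raise ValueError(f"inhomogeneity {i}: center_r must be >= 0")
            if inh.center_r + inh.radius > self.domain_radius + tol:
                raise ValueError(
                    f"inhomogeneity {i} extends outside the domain: "
                    f"center_r + radius = {inh.center_r + inh.radius:g} > "
                    f"R = {self.domain_radius:g}"
                )
        for i in range(len(self.inhomogeneities)):
            for j in range(i + 1, len(self.inhomogeneities)):
                a, b = self.inhomogeneities[i], self.inhomogeneities[j]
                d = float(np.hypot(*(a.center - b.center)))
                if d < a.radius + b.radius - tol:
                    raise ValueError(
                        f"inhomogeneities {i} and {j} overlap "
                        f"(centre distance {d:g} < {a.radius + b.radius:g})"
                    )


@dataclass(frozen=True)
class ConductivityMap:
    """Per-element conductivity vector in S/m."""

    sigma: np.ndarray

    def __post_init__(self):
        sigma = np.asarray(self.sigma, dtype=float)
        if np.any(~np.isfinite(sigma)) or np.any(sigma <= 0):
            raise ValueError("conductivity map must be finite and positive")
        object.__setattr__(self, "sigma", sigma)

    def __len__(self) -> int:
        return len(self.sigma)


@dataclass(frozen=True)
class PhantomSummary:
    """Region areas and element counts of a realized phantom.

    ``area_domain`` is the summed element area A_D, ``area_inhomogeneity``
    the summed area A_I of all anomaly-assigned elements, and the background
    area is their difference A_B = A_D - A_I.
    """

    area_domain: float
    area_inhomogeneity: float
    area_background: float
    element_counts: tuple[int, ...]  # per inhomogeneity
    element_areas: tuple[float, ...]  # per inhomogeneity
    n_background_elements: int


def _region_masks(spec: PhantomSpec, mesh: TriMesh) -> list[np.ndarray]:
    centroids = element_centroids(mesh)
    masks = []
    for inh in spec.inhomogeneities:
        d = np.hypot(centroids[:, 0] - inh.center[0], centroids[:, 1] - inh.center[1])
        masks.append(d < inh.radius * (1.0 - _RIM_RTOL))
    return masks


def realize_phantom(spec: PhantomSpec, mesh: TriMesh) -> ConductivityMap:
    """Assign each mesh element the conductivity of its centroid's region."""
    if not np.isclose(mesh.radius, spec.domain_radius, rtol=1e-9, atol=0.0):
        raise ValueError(
            f"mesh radius {mesh.radius:g} does not match phantom domain radius "
            f"{spec.domain_radius:g}"
        )
    sigma = np.full(mesh.n_elements, spec.background_conductivity, dtype=float)
    for inh, mask in zip(spec.inhomogeneities, _region_masks(spec, mesh)):
        sigma[mask] = inh.conductivity
    return ConductivityMap(sigma=sigma)


def phantom_summary(spec: PhantomSpec, mesh: TriMesh) -> PhantomSummary:
    """Areas and element counts of each region of the realized phantom."""
    areas, _, _ = element_geometry_arrays(mesh)
    masks = _region_masks(spec, mesh)
    counts = tuple(int(m.sum()) for m in masks)
    region_areas = tuple(float(areas[m].sum()) for m in masks)
    a_d = float(areas.sum())
    a_i = float(sum(region_areas))
    any_inh = (
        np.any(masks, axis=0) if masks else np.zeros(mesh.n_elements, dtype=bool)
    )
    return PhantomSummary(
        area_domain=a_d,
        area_inhomogeneity=a_i,
        area_background=a_d - a_i,
        element_counts=counts,
        element_areas=region_areas,
        n_background_elements=int((~any_inh).sum()),
    )
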