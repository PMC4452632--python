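"""Synthetic liver-parenchyma microanatomy.

The normal liver is modelled as a lattice of hexagonal-prism lobules
(circumradius 0.6 mm, length 1.5 mm, ≈2 mg each).  Microspheres are trapped
in the hepatic arterioles of the portal tracts that sit at the hexagon
corners; each corner is shared by up to three lobules, so deduplicating the
six corners of a 2 mg lobule leaves two tracts per lobule — about one portal
tract per milligram of tissue.  A tumour compartment, when requested, is a
contiguous ball of lobules relabelled ``tumour``; its tract lattice is kept
(the chaotic deposition mode ignores it anyway).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "LobuleParams",
    "LiverModel",
    "Cylinder",
    "Box",
    "build_lattice",
    "tracts_in_region",
]

_SQRT3 = np.sqrt(3.0)


@dataclass(frozen=True)
class LobuleParams:
    """Geometry and bulk properties of one hexagonal-prism lobule.

    The nominal ``lobule_mass_mg`` (2 mg) sets how many lobules make up a
    target tissue mass and hence the portal-tract density (~1 per nominal
    mg).  The quoted hexagon geometry encloses ~1.4 mm³, so nominal mass
    and geometric volume differ by ~1.4×; all concentration and dose
    bookkeeping downstream is volumetric (geometric volume × density).
    """

    radius_mm: float = 0.6          # centre to hexagon corner
    length_mm: float = 1.5          # prism length (axial)
    lobule_mass_mg: float = 2.0
    tracts_per_lobule: float = 2.0  # bulk value implied by corner sharing
    density_mg_per_mm3: float = 1.0

    def __post_init__(self) -> None:
        for name in ("radius_mm", "length_mm", "lobule_mass_mg",
                     "tracts_per_lobule", "density_mg_per_mm3"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    @property
    def lobule_volume_mm3(self) -> float:
        """Geometric volume of one hexagonal prism."""
        return 1.5 * np.sqrt(3.0) * self.radius_mm**2 * self.length_mm


@dataclass(frozen=True)
class Cylinder:
    """Axis-aligned (z-axis) cylinder; closed boundaries."""

    centre: tuple[float, float, float]
    diameter_mm: float
    thickness_mm: float

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        cx, cy, cz = self.centre
        r2 = (pts[:, 0] - cx) ** 2 + (pts[:, 1] - cy) ** 2
        in_disc = r2 <= self.radius_mm**2 + 1e-12
        in_slab = np.abs(pts[:, 2] - cz) <= self.thickness_mm / 2.0 + 1e-12
        return in_disc & in_slab

    @property
    def volume_mm3(self) -> float:
        return np.pi * self.radius_mm**2 * self.thickness_mm


@dataclass(frozen=True)
class Box:
    """Axis-aligned box; closed boundaries."""

    lo: tuple[float, float, float]
    hi: tuple[float, float, float]

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        lo = np.asarray(self.lo, dtype=float)
        hi = np.asarray(self.hi, dtype=float)
        return np.all((pts >= lo - 1e-12) & (pts <= hi + 1e-12), axis=1)


@dataclass
class LiverModel:
    """Lobule lattice with shared portal tracts and a compartment labelling."""

    lobule_centres: np.ndarray            # (n_lobules, 3) mm
    lobule_compartment: np.ndarray        # (n_lobules,) 'normal'/'tumour'
    tracts: pd.DataFrame                  # tract_id, x_mm, y_mm, z_mm, compartment
    params: LobuleParams
    total_mass_mg: float
    bbox_lo: np.ndarray
    bbox_hi: np.ndarray
    _lobule_tree: cKDTree | None = field(default=None, repr=False)

    @property
    def n_lobules(self) -> int:
        return len(self.lobule_centres)

    @property
    def n_tracts(self) -> int:
        return len(self.tracts)

    @property
    def tract_points(self) -> np.ndarray:
        return self.tracts[["x_mm", "y_mm", "z_mm"]].to_numpy()

    def compartment_mass_mg(self, compartment: str) -> float:
        """Volumetric mass of a compartment (geometric volume × density)."""
        n = int(np.sum(self.lobule_compartment == compartment))
        return n * self.params.lobule_volume_mm3 * self.params.density_mg_per_mm3

    @property
    def volumetric_mass_mg(self) -> float:
        return (
            self.n_lobules
            * self.params.lobule_volume_mm3
            * self.params.density_mg_per_mm3
        )

    def compartment_at(self, points: np.ndarray) -> np.ndarray:
        """Compartment label of the nearest lobule for each query point."""
        if self._lobule_tree is None:
            self._lobule_tree = cKDTree(self.lobule_centres)
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        _, idx = self._lobule_tree.query(pts)
        return self.lobule_compartment[idx]

    def export_tracts(self, path) -> None:
        self.tracts.to_csv(path, sep="\t", index=False)


def _hex_centres(n: int, cols: int, rows: int, radius: float) -> np.ndarray:
    """xy centres of the first ``n`` cells of a cols×rows flat-top hex grid."""
    c, r = np.meshgrid(np.arange(cols), np.arange(rows), indexing="ij")
    c = c.ravel()[:n]
    r = r.ravel()[:n]
    x = 1.5 * radius * c
    y = _SQRT3 * radius * (r + 0.5 * (c % 2))
    return np.column_stack([x, y])


_CORNER_ANGLES = np.deg2rad(np.arange(0, 360, 60))
_CORNER_OFFSETS = np.column_stack([np.cos(_CORNER_ANGLES), np.sin(_CORNER_ANGLES)])


def build_lattice(
    target_mass_mg: float,
    params: LobuleParams | None = None,
    tumour_fraction: float = 0.0,
    tumour_centre: tuple[float, float, float] | None = None,
    rng_seed: int = 0,
    lobules_per_layer: int = 1000,
) -> LiverModel:
    """Build a hexagonal-prism lobule lattice of ``target_mass_mg`` total mass.

    Lobules are tiled in axial layers of ``length_mm`` with aligned columns;
    portal tracts are the deduplicated hexagon corners of each layer.  The
    construction is deterministic; ``rng_seed`` is accepted for interface
    symmetry with the stochastic stages and recorded nowhere.

    ``tumour_fraction`` of the lobules (the ball nearest ``tumour_centre``,
    default the lattice centroid) is relabelled ``tumour``.
    """
    params = params or LobuleParams()
    n_lobules = int(round(target_mass_mg / params.lobule_mass_mg))
    if n_lobules < 1:
        raise ValueError(
            f"target_mass_mg={target_mass_mg} is below one lobule "
            f"({params.lobule_mass_mg} mg)"
        )
    if not (0.0 <= tumour_fraction < 1.0):
        raise ValueError(f"tumour_fraction must be in [0, 1), got {tumour_fraction}")

    n_layers = max(1, round(n_lobules / lobules_per_layer))
    per_layer = -(-n_lobules // n_layers)  # ceil
    rows = int(np.ceil(np.sqrt(per_layer)))
    cols = -(-per_layer // rows)

    R, L = params.radius_mm, params.length_mm
    centres = []
    corners = []
    remaining = n_lobules
    for layer in range(n_layers):
        n_here = min(per_layer, remaining)
        if n_here <= 0:
            break
        remaining -= n_here
        xy = _hex_centres(n_here, cols, rows, R)
        z = (layer + 0.5) * L
        centres.append(np.column_stack([xy, np.full(n_here, z)]))
        # all 6 corners of every lobule in this layer, deduplicated
        cxy = (xy[:, None, :] + R * _CORNER_OFFSETS[None, :, :]).reshape(-1, 2)
        cxy = np.unique(np.round(cxy, 6), axis=0)
        corners.append(np.column_stack([cxy, np.full(len(cxy), z)]))
    lobule_centres = np.vstack(centres)
    tract_points = np.vstack(corners)

    compartment = np.full(n_lobules, "normal", dtype=object)
    if tumour_fraction > 0:
        k = int(round(tumour_fraction * n_lobules))
        if k > 0:
            centre = (
                np.asarray(tumour_centre, dtype=float)
                if tumour_centre is not None
                else lobule_centres.mean(axis=0)
            )
            d2 = np.sum((lobule_centres - centre) ** 2, axis=1)
            compartment[np.argsort(d2)[:k]] = "tumour"

    # a tract belongs to the tumour if at least half its adjacent lobules do
    lob_tree = cKDTree(lobule_centres)
    neighbours = lob_tree.query_ball_point(tract_points, R * 1.001)
    tumour_mask = compartment == "tumour"
    tract_comp = np.array(
        [
            "tumour"
            if len(nb) > 0 and np.mean(tumour_mask[nb]) >= 0.5
            else "normal"
            for nb in neighbours
        ],
        dtype=object,
    )

    tracts = pd.DataFrame(
        {
            "tract_id": np.arange(len(tract_points)),
            "x_mm": tract_points[:, 0],
            "y_mm": tract_points[:, 1],
            "z_mm": tract_points[:, 2],
            "compartment": tract_comp,
        }
    )
    bbox_lo = np.array([tract_points[:, 0].min(), tract_points[:, 1].min(), 0.0])
    bbox_hi = np.array(
        [tract_points[:, 0].max(), tract_points[:, 1].max(), n_layers * L]
    )
    return LiverModel(
        lobule_centres=lobule_centres,
        lobule_compartment=compartment,
        tracts=tracts,
        params=params,
        total_mass_mg=n_lobules * params.lobule_mass_mg,
        bbox_lo=bbox_lo,
        bbox_hi=bbox_hi,
        _lobule_tree=lob_tree,
    )


def tracts_in_region(model: LiverModel, region: Cylinder | Box) -> np.ndarray:
    """Identifiers of all portal tracts inside ``region`` (closed boundaries)."""
    mask = region.contains(model.tract_points)
    return model.tracts.loc[mask, "tract_id"].to_numpy()
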