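"""Serial sectioning and light-microscopy sphere counting.

A biopsy is cut into thin serial sections (default 10 × 20 μm from the top
of the cylinder).  Spheres observed across adjacent sections are grouped
into *locations* by single-linkage clustering with a 200 μm radius — the
same distance that defines an isolated single sphere (no neighbour within
200 μm, ≈7 sphere diameters, consistent with the span of the largest
portal tract, so two singles never share a tract).  The stack covers only
part of the biopsy; the sectioned fraction is tracked explicitly so that
count-based concentration estimates can be compared with whole-biopsy
detector measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .biopsy import Biopsy
from .deposition import DepositionResult
from .dosimetry import spheres_to_concentration
from .heterogeneity import coefficient_of_variation, skewness_adjusted

__all__ = [
    "SectionStack",
    "LocationStats",
    "section_biopsy",
    "find_locations",
    "location_stats",
    "concentration_from_counts",
]

DEFAULT_N_SECTIONS = 10
DEFAULT_SECTION_THICKNESS_UM = 20.0
DEFAULT_ISOLATION_DISTANCE_UM = 200.0


@dataclass
class SectionStack:
    """Spheres of one biopsy partitioned into serial axial sections."""

    biopsy_id: int
    n_sections: int
    section_thickness_um: float
    records: pd.DataFrame        # sphere_id, x_mm, y_mm, z_mm, section_index
    sectioned_fraction: float    # stack depth / biopsy thickness
    sectioned_volume_mm3: float

    @property
    def n_spheres(self) -> int:
        return len(self.records)


def section_biopsy(
    biopsy: Biopsy,
    deposition: DepositionResult,
    n_sections: int = DEFAULT_N_SECTIONS,
    section_thickness_um: float = DEFAULT_SECTION_THICKNESS_UM,
) -> SectionStack:
    """Cut ``n_sections`` serial sections from the top of the biopsy.

    Sphere→section assignment is plain axial binning; a sphere exactly on
    the boundary between two sections goes to the upper one.
    """
    depth_mm = n_sections * section_thickness_um / 1000.0
    if depth_mm > biopsy.thickness_mm + 1e-9:
        raise ValueError(
            f"stack depth {depth_mm} mm exceeds biopsy thickness "
            f"{biopsy.thickness_mm} mm"
        )
    spheres = deposition.spheres.loc[biopsy.sphere_ids]
    z_top = biopsy.centre[2] + biopsy.thickness_mm / 2.0
    depth_from_top = z_top - spheres["z_mm"].to_numpy()
    idx = np.floor(depth_from_top / (section_thickness_um / 1000.0)).astype(int)
    idx[np.isclose(depth_from_top, 0.0)] = 0
    keep = (idx >= 0) & (idx < n_sections)
    records = pd.DataFrame(
        {
            "sphere_id": spheres["sphere_id"].to_numpy()[keep],
            "x_mm": spheres["x_mm"].to_numpy()[keep],
            "y_mm": spheres["y_mm"].to_numpy()[keep],
            "z_mm": spheres["z_mm"].to_numpy()[keep],
            "section_index": idx[keep],
        }
    )
    area = np.pi * (biopsy.diameter_mm / 2.0) ** 2
    return SectionStack(
        biopsy_id=biopsy.biopsy_id,
        n_sections=n_sections,
        section_thickness_um=section_thickness_um,
        records=records,
        sectioned_fraction=depth_mm / biopsy.thickness_mm,
        sectioned_volume_mm3=area * depth_mm,
    )


def _link_points(points: np.ndarray, radius_mm: float) -> np.ndarray:
    """Single-linkage component label per point (pairs within ``radius_mm``)."""
    n = len(points)
    if n == 0:
        return np.array([], dtype=int)
    pairs = cKDTree(points).query_pairs(radius_mm, output_type="ndarray")
    graph = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, labels = connected_components(graph, directed=False)
    return labels


def find_locations(
    stack: SectionStack,
    isolation_distance_um: float = DEFAULT_ISOLATION_DISTANCE_UM,
) -> pd.DataFrame:
    """Group the stack's spheres into locations (single-linkage, 3-D).

    Coordinates are the in-section (x, y) positions plus the section-centre
    offset as z, mirroring what aligning adjacent sections under the
    microscope reconstructs.  A location of one sphere is an isolated
    single by construction: any neighbour within the linkage radius would
    have been merged.
    """
    if isolation_distance_um <= 0:
        raise ValueError(
            f"isolation_distance_um must be > 0, got {isolation_distance_um}"
        )
    rec = stack.records
    dz = stack.section_thickness_um / 1000.0
    pts = np.column_stack(
        [
            rec["x_mm"].to_numpy(),
            rec["y_mm"].to_numpy(),
            (rec["section_index"].to_numpy() + 0.5) * dz,
        ]
    )
    labels = _link_points(pts, isolation_distance_um / 1000.0)
    if labels.size == 0:
        return pd.DataFrame(
            columns=[
                "location_id", "biopsy_id", "n_spheres",
                "first_section", "last_section", "is_isolated_single",
            ]
        )
    df = rec.assign(location=labels)
    grouped = df.groupby("location")
    out = pd.DataFrame(
        {
            "location_id": np.arange(grouped.ngroups),
            "biopsy_id": stack.biopsy_id,
            "n_spheres": grouped.size().to_numpy(),
            "first_section": grouped["section_index"].min().to_numpy(),
            "last_section": grouped["section_index"].max().to_numpy(),
        }
    )
    out["is_isolated_single"] = out["n_spheres"] == 1
    return out


@dataclass(frozen=True)
class LocationStats:
    n_locations: int
    n_spheres: int
    mean_size: float
    cv: float
    sk: float
    fraction_singles_of_locations: float
    fraction_singles_of_spheres: float
    histogram: pd.Series  # index: location size, value: number of locations


def location_stats(records) -> LocationStats:
    """Summary of the location-size distribution.

    ``records`` is a :func:`find_locations` frame (frames from several
    stacks may be concatenated first) or a plain sequence of location sizes.
    """
    if isinstance(records, pd.DataFrame):
        sizes = records["n_spheres"].to_numpy(dtype=int)
        singles = int(records["is_isolated_single"].sum())
    else:
        sizes = np.asarray(records, dtype=int)
        singles = int(np.sum(sizes == 1))
    if sizes.size == 0:
        raise ValueError("location_stats requires at least one location")
    n_loc = int(sizes.size)
    n_sph = int(sizes.sum())
    hist = pd.Series(sizes).value_counts().sort_index()
    hist.index.name = "location_size"
    hist.name = "n_locations"
    return LocationStats(
        n_locations=n_loc,
        n_spheres=n_sph,
        mean_size=n_sph / n_loc,
        cv=coefficient_of_variation(sizes) if n_loc >= 2 else float("nan"),
        sk=(
            skewness_adjusted(sizes)
            if n_loc >= 3 and np.std(sizes, ddof=1) > 0
            else float("nan")
        ),
        fraction_singles_of_locations=singles / n_loc,
        fraction_singles_of_spheres=singles / n_sph,
        histogram=hist,
    )


def concentration_from_counts(
    n_spheres: int,
    sectioned_volume_mm3: float,
    per_sphere_activity_bq: float = 50.0,
    density_mg_per_mm3: float = 1.0,
) -> float:
    """Concentration (Bq/mg) implied by counting spheres in sectioned volume."""
    if sectioned_volume_mm3 <= 0:
        raise ValueError(
            f"sectioned_volume_mm3 must be > 0, got {sectioned_volume_mm3}"
        )
    mass_mg = sectioned_volume_mm3 * density_mg_per_mm3
    return spheres_to_concentration(n_spheres, per_sphere_activity_bq, mass_mg)
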