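"""Virtual biopsy punching and mass stratification.

Biopsies are axis-aligned cylindrical punches through a tissue slice.
Sphere membership is by centre-point inclusion (spheres are ≤60 μm across,
negligible against punch diameters of millimetres).  Measured activities
are the administered-time activities decayed to the measurement time
(default 216 h ≈ 9 days, the patients' surgery-to-administration interval).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dosimetry import NuclideParams, Y90, decay_fraction
from .deposition import DepositionResult

__all__ = [
    "Biopsy",
    "MassGroupSpec",
    "DEFAULT_DIAMETERS_MM",
    "DEFAULT_MASS_GROUPS",
    "punch",
    "punch_plan",
    "stratify",
    "biopsies_to_frame",
]

DEFAULT_DIAMETERS_MM = (3.0, 4.0, 6.0, 8.0)
DEFAULT_MEASURE_AT_H = 216.0


@dataclass(frozen=True)
class MassGroupSpec:
    """Inclusive mass bounds of one stratum."""

    label: str
    lo_mg: float
    hi_mg: float

    def __post_init__(self) -> None:
        if not (0 < self.lo_mg <= self.hi_mg):
            raise ValueError(f"invalid bounds for {self.label}: {self.lo_mg}..{self.hi_mg}")

    def contains(self, mass_mg: float) -> bool:
        return self.lo_mg <= mass_mg <= self.hi_mg


#: default strata bounds (small / medium / large)
DEFAULT_MASS_GROUPS = (
    MassGroupSpec("small", 6.0, 14.0),
    MassGroupSpec("medium", 15.0, 39.0),
    MassGroupSpec("large", 40.0, 91.0),
)


@dataclass
class Biopsy:
    """One cylindrical tissue sample."""

    biopsy_id: int
    centre: tuple[float, float, float]
    diameter_mm: float
    thickness_mm: float
    mass_mg: float
    n_spheres: int
    activity_at_admin_bq: float
    measured_activity_bq: float
    measure_time_h: float
    compartment: str
    sphere_ids: np.ndarray = field(repr=False)
    mass_group: str | None = None

    @property
    def concentration_bq_per_mg(self) -> float:
        """Activity concentration at administration time, Bq/mg."""
        return self.activity_at_admin_bq / self.mass_mg

    @property
    def volume_mm3(self) -> float:
        return np.pi * (self.diameter_mm / 2.0) ** 2 * self.thickness_mm


def _overlaps(
    centre: np.ndarray, radius: float, thickness: float, others: list[Biopsy]
) -> bool:
    for b in others:
        oc = np.asarray(b.centre)
        dz = abs(centre[2] - oc[2])
        if dz >= (thickness + b.thickness_mm) / 2.0 - 1e-9:
            continue
        dxy = np.hypot(centre[0] - oc[0], centre[1] - oc[1])
        if dxy < radius + b.diameter_mm / 2.0 - 1e-9:
            return True
    return False


def punch(
    deposition: DepositionResult,
    centre: tuple[float, float, float],
    diameter_mm: float,
    thickness_mm: float,
    biopsy_id: int = 0,
    allowed_diameters: tuple[float, ...] | None = DEFAULT_DIAMETERS_MM,
    measure_at_h: float = DEFAULT_MEASURE_AT_H,
    prior: list[Biopsy] | None = None,
    allow_overlap: bool = False,
    require_inside: bool = True,
    nuclide: NuclideParams = Y90,
) -> Biopsy:
    """Punch one cylinder out of a deposition.

    Rejects diameters outside the configured punch set, cylinders that do
    not fit inside the tissue bounding volume (unless ``require_inside`` is
    dropped, e.g. for a whole-tissue conservation check), and overlaps with
    ``prior`` punches unless ``allow_overlap``.
    """
    if allowed_diameters is not None and not any(
        np.isclose(diameter_mm, d) for d in allowed_diameters
    ):
        raise ValueError(
            f"diameter_mm={diameter_mm} not in configured set {allowed_diameters}"
        )
    model = deposition.model
    c = np.asarray(centre, dtype=float)
    r = diameter_mm / 2.0
    lo, hi = model.bbox_lo, model.bbox_hi
    if require_inside and (
        c[0] - r < lo[0] - 1e-9 or c[0] + r > hi[0] + 1e-9
        or c[1] - r < lo[1] - 1e-9 or c[1] + r > hi[1] + 1e-9
        or c[2] - thickness_mm / 2 < lo[2] - 1e-9
        or c[2] + thickness_mm / 2 > hi[2] + 1e-9
    ):
        raise ValueError(
            f"cylinder (centre={tuple(c)}, d={diameter_mm}, t={thickness_mm}) "
            "extends outside the tissue bounding volume"
        )
    if prior and not allow_overlap and _overlaps(c, r, thickness_mm, prior):
        raise ValueError("punch overlaps a previously punched region")

    cand = deposition.xy_tree().query_ball_point(c[:2], r + 1e-9)
    cand = np.asarray(cand, dtype=int)
    if cand.size:
        sub = deposition.spheres.iloc[cand]
        xy_ok = (sub["x_mm"] - c[0]) ** 2 + (sub["y_mm"] - c[1]) ** 2 <= r**2 + 1e-12
        z_ok = np.abs(sub["z_mm"] - c[2]) <= thickness_mm / 2.0 + 1e-12
        members = sub.index.to_numpy()[(xy_ok & z_ok).to_numpy()]
    else:
        members = np.array([], dtype=int)

    activity = float(deposition.spheres.loc[members, "activity_bq"].sum())
    mass = np.pi * r**2 * thickness_mm * model.params.density_mg_per_mm3
    comp = str(model.compartment_at(c[None, :])[0])
    return Biopsy(
        biopsy_id=biopsy_id,
        centre=tuple(c),
        diameter_mm=diameter_mm,
        thickness_mm=thickness_mm,
        mass_mg=mass,
        n_spheres=len(members),
        activity_at_admin_bq=activity,
        measured_activity_bq=activity * decay_fraction(measure_at_h, nuclide),
        measure_time_h=measure_at_h,
        compartment=comp,
        sphere_ids=members,
    )


def punch_plan(
    deposition: DepositionResult,
    plan: list[tuple[float, int, float | tuple[float, float]]],
    rng_seed: int | np.random.Generator = 0,
    compartment: str | None = "normal",
    allowed_diameters: tuple[float, ...] | None = DEFAULT_DIAMETERS_MM,
    measure_at_h: float = DEFAULT_MEASURE_AT_H,
    max_attempts: int = 400,
    nuclide: NuclideParams = Y90,
) -> tuple[list[Biopsy], int]:
    """Place a set of non-overlapping punches uniformly at random.

    ``plan`` entries are ``(diameter_mm, count, thickness)`` where thickness
    is a fixed value or an inclusive ``(lo, hi)`` range sampled per punch.
    Punch centres are drawn uniformly inside the tissue bounds (inset by the
    punch radius), restricted to the requested ``compartment`` (None = any).
    Returns the accepted biopsies and the number that could not be placed
    (partial plans are returned rather than failing).
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    model = deposition.model
    lo, hi = model.bbox_lo, model.bbox_hi
    accepted: list[Biopsy] = []
    n_failed = 0
    bid = 0
    for diameter, count, thickness in plan:
        r = diameter / 2.0
        for _ in range(count):
            t = (
                float(rng.uniform(*thickness))
                if isinstance(thickness, (tuple, list))
                else float(thickness)
            )
            placed = False
            for _attempt in range(max_attempts):
                c = np.array(
                    [
                        rng.uniform(lo[0] + r, hi[0] - r),
                        rng.uniform(lo[1] + r, hi[1] - r),
                        rng.uniform(lo[2] + t / 2, hi[2] - t / 2),
                    ]
                )
                if compartment is not None:
                    if str(model.compartment_at(c[None, :])[0]) != compartment:
                        continue
                if _overlaps(c, r, t, accepted):
                    continue
                accepted.append(
                    punch(
                        deposition,
                        tuple(c),
                        diameter,
                        t,
                        biopsy_id=bid,
                        allowed_diameters=allowed_diameters,
                        measure_at_h=measure_at_h,
                        prior=None,
                        nuclide=nuclide,
                    )
                )
                bid += 1
                placed = True
                break
            if not placed:
                n_failed += 1
    return accepted, n_failed


def stratify(
    biopsies: list[Biopsy],
    groups: tuple[MassGroupSpec, ...] = DEFAULT_MASS_GROUPS,
) -> list[Biopsy]:
    """Label each biopsy with the unique group containing its mass.

    Biopsies outside every group are labelled ``unassigned``.  Overlapping
    group bounds are rejected.
    """
    ordered = sorted(groups, key=lambda g: g.lo_mg)
    for a, b in zip(ordered, ordered[1:]):
        if b.lo_mg <= a.hi_mg:
            raise ValueError(
                f"overlapping mass groups: {a.label}({a.lo_mg}-{a.hi_mg}) and "
                f"{b.label}({b.lo_mg}-{b.hi_mg})"
            )
    out = []
    for b in biopsies:
        label = next((g.label for g in ordered if g.contains(b.mass_mg)), "unassigned")
        out.append(replace_mass_group(b, label))
    return out


def replace_mass_group(b: Biopsy, label: str) -> Biopsy:
    b.mass_group = label
    return b


def biopsies_to_frame(biopsies: list[Biopsy]) -> pd.DataFrame:
    """Delimited-text-ready biopsy table."""
    return pd.DataFrame(
        {
            "biopsy_id": [b.biopsy_id for b in biopsies],
            "x_mm": [b.centre[0] for b in biopsies],
            "y_mm": [b.centre[1] for b in biopsies],
            "z_mm": [b.centre[2] for b in biopsies],
            "diameter_mm": [b.diameter_mm for b in biopsies],
            "thickness_mm": [b.thickness_mm for b in biopsies],
            "mass_mg": [b.mass_mg for b in biopsies],
            "n_spheres": [b.n_spheres for b in biopsies],
            "activity_bq_admin": [b.activity_at_admin_bq for b in biopsies],
            "measured_bq": [b.measured_activity_bq for b in biopsies],
            "compartment": [b.compartment for b in biopsies],
            "mass_group": [b.mass_group for b in biopsies],
        }
    )
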