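"""Absorbed dose and biologically effective dose for ⁹⁰Y microspheres.

Dosimetry follows the *local deposition* model: every β decay deposits its
mean energy in the tissue element where the sphere lodged.  For complete
decay of an activity concentration ``c0`` (referenced to administration
time) the absorbed dose is

    D = c0 · Ē · T½ / ln 2                                   [Gy]

with ``c0`` in Bq/kg, the mean β energy ``Ē`` in joules and the physical
half-life ``T½`` in seconds.  The biologically effective dose of a
permanently implanted, exponentially decaying source with mono-exponential
sublethal-damage repair is

    BED = D · [1 + λ/(μ + λ) · D/(α/β)]

where λ = ln2/T½ is the decay constant and μ = ln2/T_rep the repair
constant.  Cross-fire between tissue elements is deliberately ignored
(the mean β range of ⁹⁰Y is 2.5 mm, the maximum 11 mm; smoothing at that
scale is out of scope here).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "NuclideParams",
    "RadiobiologyParams",
    "DoseResult",
    "Y90",
    "NORMAL_LIVER",
    "TUMOUR",
    "absorbed_dose",
    "bed",
    "decay_fraction",
    "spheres_to_concentration",
    "concentration_from_dose",
    "tnc",
    "relative_difference",
    "dose_report",
]

#: joules per MeV
MEV_TO_J = 1.602176634e-13
#: Bq/mg -> Bq/kg
BQ_PER_MG_TO_BQ_PER_KG = 1.0e6
_LN2 = math.log(2.0)


@dataclass(frozen=True)
class NuclideParams:
    """Physical constants of the therapeutic nuclide (defaults: ⁹⁰Y resin spheres).

    ``per_sphere_activity_bq`` is the nominal activity per microsphere at
    administration; the range brackets sphere-to-sphere variability.
    """

    half_life_h: float = 64.0
    mean_energy_mev: float = 0.934
    per_sphere_activity_bq: float = 50.0
    per_sphere_activity_range_bq: tuple[float, float] = (40.0, 70.0)
    mean_range_mm: float = 2.5
    max_range_mm: float = 11.0

    def __post_init__(self) -> None:
        if self.half_life_h <= 0:
            raise ValueError(f"half_life_h must be > 0, got {self.half_life_h}")
        if self.mean_energy_mev <= 0:
            raise ValueError(f"mean_energy_mev must be > 0, got {self.mean_energy_mev}")
        lo, hi = self.per_sphere_activity_range_bq
        if not (0 < lo <= self.per_sphere_activity_bq <= hi):
            raise ValueError(
                "per_sphere_activity_range_bq must bracket per_sphere_activity_bq: "
                f"{lo} <= {self.per_sphere_activity_bq} <= {hi} violated"
            )
        if not (0 < self.mean_range_mm <= self.max_range_mm):
            raise ValueError("ranges must satisfy 0 < mean_range_mm <= max_range_mm")

    @property
    def decay_constant_per_h(self) -> float:
        return _LN2 / self.half_life_h


@dataclass(frozen=True)
class RadiobiologyParams:
    """Linear-quadratic tissue parameters for the BED calculation."""

    alpha_beta_gy: float
    repair_half_time_h: float

    def __post_init__(self) -> None:
        if self.alpha_beta_gy <= 0:
            raise ValueError(f"alpha_beta_gy must be > 0, got {self.alpha_beta_gy}")
        if self.repair_half_time_h <= 0:
            raise ValueError(
                f"repair_half_time_h must be > 0, got {self.repair_half_time_h}"
            )


#: default nuclide: ⁹⁰Y resin microspheres
Y90 = NuclideParams()
#: normal liver parenchyma preset: α/β = 2.5 Gy, repair half-time 2.5 h
NORMAL_LIVER = RadiobiologyParams(alpha_beta_gy=2.5, repair_half_time_h=2.5)
#: tumour preset: α/β = 10 Gy, repair half-time 1.5 h
TUMOUR = RadiobiologyParams(alpha_beta_gy=10.0, repair_half_time_h=1.5)

PRESETS: dict[str, RadiobiologyParams] = {"normal": NORMAL_LIVER, "tumour": TUMOUR}


@dataclass(frozen=True)
class DoseResult:
    """Absorbed dose, BED and the concentration they were derived from."""

    absorbed_dose_gy: float
    bed_gy: float
    activity_concentration_bq_per_mg: float

    def __post_init__(self) -> None:
        if not (self.bed_gy >= self.absorbed_dose_gy >= 0):
            raise ValueError("DoseResult requires bed >= absorbed_dose >= 0")


def absorbed_dose(c0_bq_per_mg: float, nuclide: NuclideParams = Y90) -> float:
    """Absorbed dose in Gy from complete local decay of ``c0`` (Bq/mg at administration).

    Linear in ``c0``; 620 Bq/mg of ⁹⁰Y gives ≈31 Gy.
    """
    if c0_bq_per_mg < 0:
        raise ValueError(f"c0_bq_per_mg must be >= 0, got {c0_bq_per_mg}")
    c0_si = c0_bq_per_mg * BQ_PER_MG_TO_BQ_PER_KG          # Bq/kg
    energy_j = nuclide.mean_energy_mev * MEV_TO_J           # J per decay
    half_life_s = nuclide.half_life_h * 3600.0
    return c0_si * energy_j * half_life_s / _LN2


def concentration_from_dose(dose_gy: float, nuclide: NuclideParams = Y90) -> float:
    """Invert :func:`absorbed_dose`: concentration (Bq/mg) giving ``dose_gy``."""
    if dose_gy < 0:
        raise ValueError(f"dose_gy must be >= 0, got {dose_gy}")
    unit = absorbed_dose(1.0, nuclide)
    return dose_gy / unit


def bed(
    dose_gy: float,
    radiobio: RadiobiologyParams,
    nuclide: NuclideParams = Y90,
) -> float:
    """Biologically effective dose (Gy) of a permanent exponentially decaying source.

    BED = D·[1 + λ/(μ+λ)·D/(α/β)].  BED → D as the repair half-time → 0 or
    α/β → ∞; BED ≥ D always.
    """
    if dose_gy < 0:
        raise ValueError(f"dose_gy must be >= 0, got {dose_gy}")
    lam = _LN2 / nuclide.half_life_h
    mu = _LN2 / radiobio.repair_half_time_h
    return dose_gy * (1.0 + lam / (mu + lam) * dose_gy / radiobio.alpha_beta_gy)


def decay_fraction(t_hours: float, nuclide: NuclideParams = Y90) -> float:
    """Fraction of activity remaining ``t_hours`` after administration: 2^(−t/T½)."""
    if t_hours < 0:
        raise ValueError(f"t_hours must be >= 0, got {t_hours}")
    return 2.0 ** (-t_hours / nuclide.half_life_h)


def spheres_to_concentration(
    n_spheres: float, per_sphere_activity_bq: float, mass_mg: float
) -> float:
    """Activity concentration (Bq/mg) of ``n_spheres`` in a sample of ``mass_mg``."""
    if mass_mg <= 0:
        raise ValueError(f"mass_mg must be > 0, got {mass_mg}")
    if n_spheres < 0:
        raise ValueError(f"n_spheres must be >= 0, got {n_spheres}")
    return n_spheres * per_sphere_activity_bq / mass_mg


def tnc(tumour_conc_bq_per_mg: float, normal_conc_bq_per_mg: float) -> float:
    """Tumour-to-normal-liver activity concentration ratio."""
    if normal_conc_bq_per_mg <= 0:
        raise ValueError(
            f"normal_conc_bq_per_mg must be > 0, got {normal_conc_bq_per_mg}"
        )
    return tumour_conc_bq_per_mg / normal_conc_bq_per_mg


def relative_difference(a_bq_per_mg: float, b_bq_per_mg: float) -> float:
    """How much lower ``a`` is than the reference ``b``, in percent: 100·(1 − a/b)."""
    if b_bq_per_mg <= 0:
        raise ValueError(f"reference b_bq_per_mg must be > 0, got {b_bq_per_mg}")
    return 100.0 * (1.0 - a_bq_per_mg / b_bq_per_mg)


def dose_report(
    conc_bq_per_mg: float,
    tissue: str = "normal",
    measured_at_hours: float = 0.0,
    nuclide: NuclideParams = Y90,
    radiobio: RadiobiologyParams | None = None,
) -> DoseResult:
    """Full dose/BED result from a concentration measured ``measured_at_hours``
    after administration (decay-corrected back to administration time).
    """
    if radiobio is None:
        try:
            radiobio = PRESETS[tissue]
        except KeyError:
            raise ValueError(
                f"tissue must be one of {sorted(PRESETS)}, got {tissue!r}"
            ) from None
    c0 = conc_bq_per_mg / decay_fraction(measured_at_hours, nuclide)
    d = absorbed_dose(c0, nuclide)
    return DoseResult(
        absorbed_dose_gy=d,
        bed_gy=bed(d, radiobio, nuclide),
        activity_concentration_bq_per_mg=c0,
    )
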