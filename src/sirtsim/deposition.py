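"""Synthetic microsphere deposition.

Microspheres arrive in *clusters* that lodge at single trapping sites.
The cluster-size law is a two-component mixture: a point mass at size 1
(isolated singles, fraction ``p_single`` of locations) and a truncated
heavy tail on sizes 2…``max_cluster``.  The defaults are calibrated so
that singles make up ≈64 % of locations while the mean location size is
≈3.3 spheres — with the consequence that a small number of large clusters
carries about half of all spheres.

Two placement modes are provided:

``deposit``
    Structured (normal-parenchyma) mode.  Every cluster occupies exactly
    one portal tract of the lobule lattice.  Tract weights combine an
    optional lognormal "element" intensity field (repetitive regional
    heterogeneity at a configurable length scale), an optional linear
    gradient, and a tumour enrichment factor.

``chaotic_deposit``
    Unstructured (tumour) mode.  Clusters ignore the tract lattice and are
    placed by a doubly stochastic process: a uniform background modulated
    by an optional large-scale linear drift, plus scattered spherical foci
    (fibrotic/necrotic remodelling) that attract a configurable share of
    the clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from .dosimetry import NuclideParams, Y90
from .liver_model import LiverModel

__all__ = [
    "ClusterSizeDistribution",
    "DepositionResult",
    "default_cluster_distribution",
    "sample_cluster_sizes",
    "deposit",
    "chaotic_deposit",
]

SPHERE_TABLE_COLUMNS = [
    "sphere_id",
    "x_mm",
    "y_mm",
    "z_mm",
    "cluster_id",
    "tract_id",
    "compartment",
    "activity_bq",
    "diameter_um",
]

#: spheres of one cluster are jittered within this radius of the trapping site
CLUSTER_JITTER_MM = 0.1


@dataclass(frozen=True)
class ClusterSizeDistribution:
    """Mixture law for spheres-per-location.

    ``tail_parameter`` is the power-law exponent (``tail_law='power_law'``)
    or the geometric success probability (``tail_law='geometric'``) of the
    truncated tail on sizes 2…``max_cluster``.
    """

    p_single: float = 0.64
    tail_law: str = "power_law"
    tail_parameter: float | None = None
    max_cluster: int = 59
    mean_size: float = 3.3   # calibration target used when tail_parameter is None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_single <= 1.0):
            raise ValueError(f"p_single must be in [0, 1], got {self.p_single}")
        if self.max_cluster < 1:
            raise ValueError(f"max_cluster must be >= 1, got {self.max_cluster}")
        if self.p_single < 1.0 and self.max_cluster < 2:
            raise ValueError(
                "p_single < 1 requires max_cluster >= 2 (no room for a tail)"
            )
        if self.tail_law not in ("power_law", "geometric"):
            raise ValueError(f"unknown tail_law {self.tail_law!r}")
        if self.p_single < 1.0:
            mean_tail = self._target_tail_mean()
            if not (2.0 <= mean_tail <= self.max_cluster):
                raise ValueError(
                    f"mean_size={self.mean_size} with p_single={self.p_single} "
                    f"requires a tail mean of {mean_tail:.2f}, outside "
                    f"[2, {self.max_cluster}]"
                )

    def _target_tail_mean(self) -> float:
        return (self.mean_size - self.p_single) / (1.0 - self.p_single)

    def tail_support(self) -> tuple[np.ndarray, np.ndarray]:
        """Sizes 2…max_cluster and their probabilities."""
        k = np.arange(2, self.max_cluster + 1, dtype=float)
        par = self.tail_parameter
        if par is None:
            par = self.calibrated_tail_parameter()
        if self.tail_law == "power_law":
            w = k**-par
        else:
            w = (1.0 - par) ** (k - 2)
        return k.astype(int), w / w.sum()

    def calibrated_tail_parameter(self) -> float:
        """Root-find the tail parameter reproducing the target tail mean."""
        target = self._target_tail_mean()
        k = np.arange(2, self.max_cluster + 1, dtype=float)

        def mean_at(par: float) -> float:
            w = k**-par if self.tail_law == "power_law" else (1.0 - par) ** (k - 2)
            return float((k * w).sum() / w.sum())

        if self.tail_law == "power_law":
            lo, hi = -10.0, 20.0
        else:
            lo, hi = 1e-9, 1.0 - 1e-9
        return brentq(lambda p: mean_at(p) - target, lo, hi, xtol=1e-10)

    def resolved(self) -> "ClusterSizeDistribution":
        """Copy with ``tail_parameter`` made explicit."""
        if self.tail_parameter is not None or self.p_single == 1.0:
            return self
        return replace(self, tail_parameter=self.calibrated_tail_parameter())

    @property
    def theoretical_mean(self) -> float:
        if self.p_single == 1.0:
            return 1.0
        k, p = self.tail_support()
        return self.p_single + (1 - self.p_single) * float((k * p).sum())


def default_cluster_distribution() -> ClusterSizeDistribution:
    return ClusterSizeDistribution().resolved()


@dataclass
class DepositionResult:
    """All deposited microspheres plus bookkeeping.

    ``spheres`` columns follow :data:`SPHERE_TABLE_COLUMNS`; activities are
    per-sphere Bq at administration time.
    """

    spheres: pd.DataFrame
    model: LiverModel
    rng_seed: int
    mode: str
    _xy_tree: cKDTree | None = field(default=None, repr=False)

    @property
    def n_spheres(self) -> int:
        return len(self.spheres)

    @property
    def total_activity_bq(self) -> float:
        return float(self.spheres["activity_bq"].sum())

    @property
    def positions(self) -> np.ndarray:
        return self.spheres[["x_mm", "y_mm", "z_mm"]].to_numpy()

    def xy_tree(self) -> cKDTree:
        """2-D KD-tree over sphere (x, y), cached; used by the biopsy puncher."""
        if self._xy_tree is None:
            self._xy_tree = cKDTree(self.spheres[["x_mm", "y_mm"]].to_numpy())
        return self._xy_tree

    def compartment_concentration_bq_per_mg(self, compartment: str) -> float:
        mass = self.model.compartment_mass_mg(compartment)
        if mass <= 0:
            raise ValueError(f"model has no {compartment!r} mass")
        act = self.spheres.loc[
            self.spheres["compartment"] == compartment, "activity_bq"
        ].sum()
        return float(act) / mass

    def export(self, path) -> None:
        self.spheres.to_csv(path, sep="\t", index=False)


def sample_cluster_sizes(
    n_spheres_target: int,
    dist: ClusterSizeDistribution | None = None,
    rng_seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw cluster sizes until exactly ``n_spheres_target`` spheres are covered.

    The last cluster is truncated so the sum hits the target exactly
    (sphere-count conservation for downstream assertions).
    """
    if n_spheres_target < 1:
        raise ValueError(f"n_spheres_target must be >= 1, got {n_spheres_target}")
    dist = (dist or ClusterSizeDistribution()).resolved()
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    if dist.p_single == 1.0:
        return np.ones(n_spheres_target, dtype=int)
    k, p = dist.tail_support()
    chunks = []
    total = 0
    while total < n_spheres_target:
        m = max(64, int((n_spheres_target - total) / dist.theoretical_mean * 1.2))
        tail = rng.choice(k, size=m, p=p)
        sizes = np.where(rng.random(m) < dist.p_single, 1, tail)
        chunks.append(sizes)
        total += int(sizes.sum())
    sizes = np.concatenate(chunks)
    cum = np.cumsum(sizes)
    last = int(np.searchsorted(cum, n_spheres_target))
    sizes = sizes[: last + 1].copy()
    sizes[-1] -= int(cum[last]) - n_spheres_target
    assert sizes[-1] >= 1 and sizes.sum() == n_spheres_target
    return sizes


def _sphere_attributes(
    rng: np.random.Generator, n: int, nuclide: NuclideParams
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sphere activities (triangular: exact range, mean preserved) and diameters."""
    lo, hi = nuclide.per_sphere_activity_range_bq
    mean = nuclide.per_sphere_activity_bq
    mode = 3.0 * mean - lo - hi
    mode = min(max(mode, lo), hi)
    activity = rng.triangular(lo, mode, hi, size=n)
    # diameters: lognormal with mean 30 um, clipped to the manufacturing range
    sigma = 0.2
    diam = rng.lognormal(np.log(30.0) - sigma**2 / 2, sigma, size=n)
    diam = np.clip(diam, 20.0, 60.0)
    return activity, diam


def _jitter(rng: np.random.Generator, n: int, radius: float = CLUSTER_JITTER_MM) -> np.ndarray:
    """Uniform displacements in a ball of ``radius`` mm."""
    d = rng.normal(size=(n, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    return d * (radius * rng.random(n) ** (1.0 / 3.0))[:, None]


def _build_result(
    rng: np.random.Generator,
    model: LiverModel,
    cluster_sizes: np.ndarray,
    cluster_pos: np.ndarray,
    tract_ids: np.ndarray,
    compartment: np.ndarray,
    nuclide: NuclideParams,
    rng_seed: int,
    mode: str,
) -> DepositionResult:
    sizes = np.asarray(cluster_sizes, dtype=int)
    n = int(sizes.sum())
    cluster_of_sphere = np.repeat(np.arange(sizes.size), sizes)
    pos = cluster_pos[cluster_of_sphere] + _jitter(rng, n)
    activity, diam = _sphere_attributes(rng, n, nuclide)
    spheres = pd.DataFrame(
        {
            "sphere_id": np.arange(n),
            "x_mm": pos[:, 0],
            "y_mm": pos[:, 1],
            "z_mm": pos[:, 2],
            "cluster_id": cluster_of_sphere,
            "tract_id": tract_ids[cluster_of_sphere],
            "compartment": compartment[cluster_of_sphere],
            "activity_bq": activity,
            "diameter_um": diam,
        }
    )
    return DepositionResult(spheres=spheres, model=model, rng_seed=rng_seed, mode=mode)


def _element_field_weights(
    rng: np.random.Generator,
    points: np.ndarray,
    lo: np.ndarray,
    element_cv: float,
    element_size_mm: float,
) -> np.ndarray:
    """Lognormal intensity per cubic cell of ``element_size_mm``, evaluated at points."""
    idx = np.floor((points - lo) / element_size_mm).astype(int)
    shape = idx.max(axis=0) + 1
    sigma = np.sqrt(np.log(1.0 + element_cv**2))
    cells = rng.lognormal(-(sigma**2) / 2.0, sigma, size=shape)
    return cells[idx[:, 0], idx[:, 1], idx[:, 2]]


def deposit(
    model: LiverModel,
    cluster_sizes: np.ndarray,
    tnc_target: float = 1.0,
    gradient_per_mm: float = 0.0,
    element_cv: float = 0.0,
    element_size_mm: float = 1.6,
    nuclide: NuclideParams = Y90,
    rng_seed: int = 0,
    exclusive_tracts: bool | None = None,
) -> DepositionResult:
    """Assign every cluster to one portal tract and realise the spheres.

    Tract selection probability ∝ base weight × (1 + gradient·(x − x_mid))
    × (``tnc_target`` for tumour tracts).  The base weight is 1 everywhere
    unless ``element_cv`` > 0, in which case it is a lognormal intensity
    field with unit mean and the given CV on cells of ``element_size_mm``.

    When the number of clusters does not exceed the number of tracts
    (``exclusive_tracts`` defaults to that test), tracts are sampled
    *without* replacement (weighted, Gumbel top-k), so no two clusters share
    a tract and isolated singles are ≥200 μm from any other location; with
    more clusters than tracts, sampling is with replacement.
    """
    if model.n_tracts < 1:
        raise ValueError("model has no portal tracts")
    if tnc_target <= 0:
        raise ValueError(f"tnc_target must be > 0, got {tnc_target}")
    sizes = np.asarray(cluster_sizes, dtype=int)
    if sizes.size == 0 or np.any(sizes < 1):
        raise ValueError("cluster_sizes must be a non-empty sequence of sizes >= 1")
    rng = np.random.default_rng(rng_seed)

    pts = model.tract_points
    w = np.ones(model.n_tracts)
    if element_cv > 0:
        w = w * _element_field_weights(
            rng, pts, model.bbox_lo, element_cv, element_size_mm
        )
    if gradient_per_mm != 0.0:
        x_mid = 0.5 * (model.bbox_lo[0] + model.bbox_hi[0])
        grad = 1.0 + gradient_per_mm * (pts[:, 0] - x_mid)
        if grad.min() <= 0:
            half = 0.5 * (model.bbox_hi[0] - model.bbox_lo[0])
            raise ValueError(
                f"gradient_per_mm={gradient_per_mm} drives tract weights "
                f"non-positive; |gradient_per_mm| must be < {1.0 / half:.4g} "
                "for this model extent"
            )
        w = w * grad
    tumour_tract = (model.tracts["compartment"] == "tumour").to_numpy()
    if tnc_target != 1.0 and tumour_tract.any() and not tumour_tract.all():
        # scale tumour weights so the expected concentration ratio equals
        # tnc_target exactly, independent of per-compartment tract density
        w_t, w_n = w[tumour_tract].sum(), w[~tumour_tract].sum()
        m_t = model.compartment_mass_mg("tumour")
        m_n = model.compartment_mass_mg("normal")
        factor = tnc_target * (w_n / m_n) * (m_t / w_t)
        w = w * np.where(tumour_tract, factor, 1.0)

    n_clusters = sizes.size
    if exclusive_tracts is None:
        exclusive_tracts = n_clusters <= model.n_tracts
    if exclusive_tracts:
        if n_clusters > model.n_tracts:
            raise ValueError(
                f"exclusive_tracts requires n_clusters ({n_clusters}) <= "
                f"n_tracts ({model.n_tracts})"
            )
        # weighted sampling without replacement via Gumbel keys
        keys = np.log(w) + rng.gumbel(size=w.size)
        chosen = np.argpartition(-keys, n_clusters - 1)[:n_clusters]
        chosen = rng.permutation(chosen)
    else:
        chosen = rng.choice(model.n_tracts, size=n_clusters, p=w / w.sum())

    compartment = model.tracts["compartment"].to_numpy()[chosen]
    return _build_result(
        rng, model, sizes, pts[chosen], chosen, compartment,
        nuclide, int(rng_seed) if np.isscalar(rng_seed) else 0, "structured",
    )


def chaotic_deposit(
    model: LiverModel,
    cluster_sizes: np.ndarray,
    patchiness: float,
    rng_seed: int = 0,
    systematic_gradient: float = 0.0,
    n_patches: int | None = None,
    patch_radius_median_mm: float = 5.0,
    patch_radius_sigma: float = 0.3,
    nuclide: NuclideParams = Y90,
) -> DepositionResult:
    """Unstructured (tumour-like) deposition ignoring the tract lattice.

    ``patchiness``/(1+``patchiness``) of the clusters fall in spherical foci
    (radius lognormal around ``patch_radius_median_mm``, foci weighted by
    volume); the remainder is background.  ``systematic_gradient`` g ∈ [0, 1)
    tilts *all* intensity linearly along z with density ∝ 1 + g·ẑ (random
    sign), modelling a large-scale drift such as rim-to-core perfusion
    differences.  ``patchiness=0`` with zero gradient is complete spatial
    randomness.
    """
    if patchiness < 0:
        raise ValueError(f"patchiness must be >= 0, got {patchiness}")
    if not (0.0 <= systematic_gradient < 1.0):
        raise ValueError(
            f"systematic_gradient must be in [0, 1), got {systematic_gradient}"
        )
    sizes = np.asarray(cluster_sizes, dtype=int)
    if sizes.size == 0 or np.any(sizes < 1):
        raise ValueError("cluster_sizes must be a non-empty sequence of sizes >= 1")
    rng = np.random.default_rng(rng_seed)
    lo, hi = model.bbox_lo, model.bbox_hi
    extent = hi - lo
    g = systematic_gradient
    sign = rng.choice([-1.0, 1.0])

    def sample_background(m: int) -> np.ndarray:
        """Rejection-sample from density ∝ 1 + g·ẑ over the bounding box."""
        out: list[np.ndarray] = []
        got = 0
        while got < m:
            cand = lo + rng.random((int(1.2 * (m - got)) + 64, 3)) * extent
            if g > 0:
                t = sign * (cand[:, 2] - (lo[2] + hi[2]) / 2) / (extent[2] / 2)
                keep = rng.random(len(cand)) < (1.0 + g * t) / (1.0 + g)
                cand = cand[keep]
            out.append(cand)
            got += len(cand)
        return np.vstack(out)[:m]

    n_clusters = sizes.size
    pos = sample_background(n_clusters)
    if patchiness > 0:
        if n_patches is None:
            volume = float(np.prod(extent))
            n_patches = max(1, round(volume / 2000.0))
        centres = sample_background(n_patches)
        radii = rng.lognormal(
            np.log(patch_radius_median_mm), patch_radius_sigma, n_patches
        )
        in_patch = rng.random(n_clusters) < patchiness / (1.0 + patchiness)
        k = int(in_patch.sum())
        if k:
            pick = rng.choice(n_patches, size=k, p=radii**3 / (radii**3).sum())
            disp = rng.normal(size=(k, 3))
            disp /= np.linalg.norm(disp, axis=1, keepdims=True)
            disp *= (radii[pick] * rng.random(k) ** (1.0 / 3.0))[:, None]
            pos[in_patch] = np.clip(centres[pick] + disp, lo, hi - 1e-9)

    compartment = model.compartment_at(pos)
    tract_ids = np.full(n_clusters, -1)
    return _build_result(
        rng, model, sizes, pos, tract_ids, compartment,
        nuclide, int(rng_seed) if np.isscalar(rng_seed) else 0, "chaotic",
    )
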