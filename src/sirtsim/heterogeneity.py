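"""Heterogeneity statistics on biopsy activity concentrations.

Per mass stratum the analysis reports the coefficient of variation and the
adjusted Fisher-Pearson standardised moment coefficient of skewness,

    SK = n/((n−1)(n−2)) · Σ((xᵢ − x̄)/s)³,

with s the (n−1)-denominator sample standard deviation.  A positive SK
means hot spots are more common than cold spots.  The CV trend across
strata of increasing biopsy mass is the diagnostic of the heterogeneity
pattern: a strong, consistent fall indicates a repetitive structure with a
basic element at or above the largest biopsy size; no consistent trend
indicates chaotic, unstructured heterogeneity; a weak fall at uniformly
small CVs indicates elements smaller than the biopsies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .biopsy import Biopsy, MassGroupSpec, DEFAULT_MASS_GROUPS, stratify

__all__ = [
    "coefficient_of_variation",
    "skewness_adjusted",
    "summarize",
    "classify_pattern",
    "ClassifierThresholds",
    "PatternClassification",
]


def coefficient_of_variation(values) -> float:
    """Sample standard deviation (n−1 denominator) over the mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError(f"CV requires n >= 2 values, got {x.size}")
    mean = x.mean()
    if mean <= 0:
        raise ValueError(f"CV requires a positive mean, got {mean}")
    return float(x.std(ddof=1) / mean)


def skewness_adjusted(values) -> float:
    """Adjusted Fisher-Pearson skewness: n/((n−1)(n−2))·Σ((xᵢ−x̄)/s)³."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError(f"adjusted skewness requires n >= 3 values, got {n}")
    s = x.std(ddof=1)
    if s == 0:
        raise ValueError("adjusted skewness undefined for zero variance")
    return float(n / ((n - 1) * (n - 2)) * np.sum(((x - x.mean()) / s) ** 3))


def summarize(
    biopsies: list[Biopsy],
    groups: tuple[MassGroupSpec, ...] = DEFAULT_MASS_GROUPS,
) -> pd.DataFrame:
    """One row per mass stratum plus an ``all`` row spanning their union.

    Columns mirror the per-group study tables: n, mean mass, mean spheres
    per biopsy, mean activity concentration (ratio of totals, Σactivity/Σmass,
    at administration time), CV and SK of the per-biopsy concentrations.
    Undersized strata get NaN CV/SK rather than an error.
    """
    biopsies = stratify(biopsies, groups)
    ordered = sorted(groups, key=lambda g: g.lo_mg)
    rows = []

    def row(label, lo, hi, members):
        conc = np.array([b.concentration_bq_per_mg for b in members])
        masses = np.array([b.mass_mg for b in members])
        total_mass = masses.sum()
        rows.append(
            {
                "group": label,
                "lo_mg": lo,
                "hi_mg": hi,
                "n": len(members),
                "mean_mass_mg": masses.mean() if len(members) else np.nan,
                "mean_spheres_per_biopsy": (
                    np.mean([b.n_spheres for b in members]) if len(members) else np.nan
                ),
                "mean_conc_bq_per_mg": (
                    sum(b.activity_at_admin_bq for b in members) / total_mass
                    if total_mass > 0
                    else np.nan
                ),
                "cv": coefficient_of_variation(conc)
                if len(members) >= 2 and conc.mean() > 0
                else np.nan,
                "sk": skewness_adjusted(conc)
                if len(members) >= 3 and conc.std(ddof=1) > 0
                else np.nan,
            }
        )

    assigned: list[Biopsy] = []
    for g in ordered:
        members = [b for b in biopsies if b.mass_group == g.label]
        assigned.extend(members)
        row(g.label, g.lo_mg, g.hi_mg, members)
    row("all", ordered[0].lo_mg, ordered[-1].hi_mg, assigned)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ClassifierThresholds:
    """Decision thresholds for :func:`classify_pattern` (relative CV drops)."""

    strong_drop: float = 0.30    # total fall qualifying as a strong trend
    weak_drop: float = 0.15      # below this the trend is negligible
    small_cv: float = 0.30       # "consistently small" CV level
    plateau_drop: float = 0.15   # last-step fall below this = plateau reached


@dataclass(frozen=True)
class PatternClassification:
    label: str
    evidence: dict


def classify_pattern(
    summaries,
    thresholds: ClassifierThresholds | None = None,
) -> PatternClassification:
    """Classify the heterogeneity pattern from the ordered per-stratum CVs.

    ``summaries`` is either a :func:`summarize` frame (the ``all`` row is
    ignored) or a sequence of ≥3 CV values ordered small→large stratum.

    Rules (thresholds configurable):

    * CV not strictly decreasing → ``chaotic_unstructured``.
    * Strictly decreasing with total relative drop ≥ ``strong_drop`` →
      ``repetitive``; if the fall has not plateaued at the largest masses the
      evidence additionally flags ``element_larger_than_biopsies``.
    * Strictly decreasing, total drop < ``weak_drop`` and all CV <
      ``small_cv`` → ``element_smaller_than_biopsies``.
    * Any weaker monotone trend → ``chaotic_unstructured`` (a trend short of
      "strong" that is not the small-CV signature is treated as trendless).
    """
    thresholds = thresholds or ClassifierThresholds()
    if isinstance(summaries, pd.DataFrame):
        cvs = summaries.loc[summaries["group"] != "all", "cv"].to_numpy(dtype=float)
    else:
        cvs = np.asarray(summaries, dtype=float)
    if cvs.size < 3:
        raise ValueError(f"classification requires >= 3 ordered strata, got {cvs.size}")
    if np.any(~np.isfinite(cvs)):
        raise ValueError("classification requires finite CVs in every stratum")

    monotone = bool(np.all(np.diff(cvs) < 0))
    total_drop = float((cvs[0] - cvs[-1]) / cvs[0])
    last_drop = float((cvs[-2] - cvs[-1]) / cvs[-2])
    evidence = {
        "cvs": [float(c) for c in cvs],
        "monotone_decreasing": monotone,
        "total_relative_drop": total_drop,
        "last_step_relative_drop": last_drop,
        "element_larger_than_biopsies": False,
        "thresholds": thresholds.__dict__,
    }
    if not monotone:
        label = "chaotic_unstructured"
    elif total_drop >= thresholds.strong_drop:
        label = "repetitive"
        evidence["element_larger_than_biopsies"] = (
            last_drop >= thresholds.plateau_drop
        )
    elif total_drop < thresholds.weak_drop and cvs.max() < thresholds.small_cv:
        label = "element_smaller_than_biopsies"
    else:
        label = "chaotic_unstructured"
    return PatternClassification(label=label, evidence=evidence)
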