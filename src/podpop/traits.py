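"""Pod-dehiscence trait preparation.

The field score is an ordinal 1-5 rating of the percentage of open pods
at harvest (1 = 0%, 2 = 12.5%, 3 = 25%, 4 = 37.5%, 5 = 50% or more).
This module converts ratings to open-pod fractions, applies the
variance-stabilizing arcsine-square-root transform used for the
association and prediction models, and implements the population
screening rule: a panel is kept for mapping when its rating standard
deviation exceeds the upper limit of the pooled 95% confidence interval
for the population standard deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TraitRecord", "PopulationSummary", "RATING_PERCENT",
    "rating_to_percent", "arcsine_transform", "sigma_confidence_interval",
    "select_populations", "read_traits", "write_traits",
]

#: printed anchor percentages for the integer ratings (5 is floored at 50)
RATING_PERCENT = {1: 0.0, 2: 12.5, 3: 25.0, 4: 37.5, 5: 50.0}


@dataclass
class TraitRecord:
    """One accession's dehiscence phenotype."""

    accession_id: str
    rating: float
    open_pod_fraction: float | None = None
    transformed: float | None = None

    def __post_init__(self) -> None:
        if (self.open_pod_fraction is not None and self.transformed is not None
                and not math.isclose(
                    self.transformed,
                    math.asin(math.sqrt(self.open_pod_fraction)),
                    abs_tol=1e-9)):
            raise ValueError("transformed value inconsistent with open-pod fraction")


@dataclass
class PopulationSummary:
    """Rating dispersion summary for one candidate panel."""

    population_id: str
    n: int
    s: float
    rating_min: float
    rating_max: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("summary needs n >= 2")
        if self.s < 0:
            raise ValueError("standard deviation must be nonnegative")

    @classmethod
    def from_ratings(cls, population_id: str, ratings) -> "PopulationSummary":
        r = np.asarray(ratings, dtype=float)
        return cls(population_id, len(r), float(r.std(ddof=1)),
                   float(r.min()), float(r.max()))


def rating_to_percent(rating: float) -> float:
    """Open-pod percentage for a rating on the 1-5 scale.

    Integer ratings map to the printed anchors; averaged (non-integer)
    ratings are linearly interpolated between adjacent anchors.
    """
    if not 1.0 <= rating <= 5.0:
        raise ValueError(f"rating {rating} outside the 1-5 scale")
    if float(rating).is_integer():
        return RATING_PERCENT[int(rating)]
    lo = int(math.floor(rating))
    frac = rating - lo
    return RATING_PERCENT[lo] + frac * (RATING_PERCENT[lo + 1] - RATING_PERCENT[lo])


def arcsine_transform(fraction: float):
    """Arcsine-square-root transform Y(x) = asin(sqrt(x)), radians in [0, pi/2]."""
    x = np.asarray(fraction, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("fraction outside [0, 1]")
    out = np.arcsin(np.sqrt(x))
    return float(out) if np.isscalar(fraction) or out.ndim == 0 else out


def sigma_confidence_interval(values, alpha: float = 0.05) -> tuple[float, float]:
    """Chi-square confidence interval for the population standard deviation.

    lower = sqrt((n-1) s^2 / chi2_{alpha/2, n-1}),
    upper = sqrt((n-1) s^2 / chi2_{1-alpha/2, n-1}),
    where the chi-square quantiles are upper-tail critical values.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 2:
        raise ValueError("need at least two values")
    s2 = v.var(ddof=1)
    if s2 <= 0:
        raise ValueError("zero sample variance: sigma interval undefined")
    df = n - 1
    chi_hi = stats.chi2.isf(alpha / 2.0, df)      # chi2_{alpha/2}
    chi_lo = stats.chi2.isf(1.0 - alpha / 2.0, df)  # chi2_{1-alpha/2}
    return (math.sqrt(df * s2 / chi_hi), math.sqrt(df * s2 / chi_lo))


def select_populations(summaries: list[PopulationSummary], pooled_values,
                       alpha: float = 0.05) -> list[str]:
    """Panels whose rating s exceeds the pooled sigma CI's upper limit.

    ``pooled_values`` is the concatenation of all candidate panels'
    ratings; selection is strict (> upper limit).
    """
    if len(summaries) < 2:
        raise ValueError("need at least two candidate populations")
    _, upper = sigma_confidence_interval(pooled_values, alpha=alpha)
    return [s.population_id for s in summaries if s.s > upper]


# -- tabular I/O -------------------------------------------------------

def read_traits(path) -> list[TraitRecord]:
    """Read a tab-separated (accession_id, rating) file; blank rating = missing."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least 2 columns")
    out = []
    for acc, rating in zip(df.iloc[:, 0], pd.to_numeric(df.iloc[:, 1], errors="coerce")):
        out.append(TraitRecord(accession_id=acc,
                               rating=float(rating) if pd.notna(rating) else math.nan))
    return out


def write_traits(records: list[TraitRecord], path, derived: bool = True) -> None:
    """Write traits as TSV; with ``derived`` adds percent and transformed columns."""
    rows = []
    for r in records:
        row = {"accession_id": r.accession_id, "rating": r.rating}
        if derived and not math.isnan(r.rating):
            pct = rating_to_percent(r.rating)
            row["open_pod_percent"] = pct
            row["transformed"] = arcsine_transform(pct / 100.0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
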