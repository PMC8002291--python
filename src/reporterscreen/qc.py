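"""Assay-characterization statistics for plate-reader reporter assays.

Implements the standard screening QC toolkit: intra-/inter-assay coefficient
of variation, the Z'-factor screening-window statistic, and dilution-series
linearity with per-level Z'.  All standard deviations are sample (n-1) SDs:
replicate counts in assay characterization are small (typically n = 3) and
the biased estimator would systematically understate variability.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, UndefinedStatisticError

#: conventional threshold above which an assay window is considered excellent
OPTIMAL_Z_FACTOR = 0.5


@dataclasses.dataclass
class ReplicateSet:
    """A labelled set of replicate signal values (RLU).

    ``level`` distinguishes technical replicates (repeated measurement of one
    sample, feeding the intra-assay CV) from biological replicates
    (independent experiments, feeding the inter-assay CV).
    """

    label: str
    values: np.ndarray
    level: str = "technical"  # "technical" | "biological"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.level not in ("technical", "biological"):
            raise ValueError(f"unknown replicate level {self.level!r}")

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        if len(self.values) < 2:
            raise UndefinedStatisticError(
                f"{self.label}: sample SD undefined for n={len(self.values)}"
            )
        return float(np.std(self.values, ddof=1))


def _cv_percent(values: np.ndarray, label: str) -> float:
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise UndefinedStatisticError(f"{label}: CV undefined for n={len(values)}")
    mean = float(np.mean(values))
    if mean <= 0:
        raise UndefinedStatisticError(f"{label}: CV undefined for mean {mean} <= 0")
    return 100.0 * float(np.std(values, ddof=1)) / mean


def intra_assay_cv(replicates: ReplicateSet | Sequence[float]) -> float:
    """Coefficient of variation (%) across technical replicates.

    CV = 100 * SD(technical replicates) / mean(technical replicates).
    """
    if isinstance(replicates, ReplicateSet):
        return _cv_percent(replicates.values, replicates.label)
    return _cv_percent(np.asarray(replicates), "intra-assay")


def inter_assay_cv(per_experiment_means: ReplicateSet | Sequence[float]) -> float:
    """Coefficient of variation (%) across biological-replicate means.

    Same formula as :func:`intra_assay_cv`, applied to one summary value per
    independent experiment; quantifies assay reproducibility.
    """
    if isinstance(per_experiment_means, ReplicateSet):
        return _cv_percent(per_experiment_means.values, per_experiment_means.label)
    return _cv_percent(np.asarray(per_experiment_means), "inter-assay")


def z_factor(
    sample: ReplicateSet | Sequence[float], negative: ReplicateSet | Sequence[float]
) -> float:
    """Z'-factor between a positive sample and a negative control.

    Z' = 1 - 3 * (SD_sample + SD_negative) / |mean_sample - mean_negative|.

    The statistic is at most 1 (equality only when both SDs vanish) and may
    be arbitrarily negative when the distributions overlap; >= 0.5 is the
    conventional "excellent assay" band.
    """
    s = sample if isinstance(sample, ReplicateSet) else ReplicateSet("sample", np.asarray(sample))
    n = (
        negative
        if isinstance(negative, ReplicateSet)
        else ReplicateSet("negative", np.asarray(negative))
    )
    separation = abs(s.mean - n.mean)
    if separation == 0:
        raise UndefinedStatisticError("Z'-factor undefined: sample and control means equal")
    return 1.0 - 3.0 * (s.sd + n.sd) / separation


@dataclasses.dataclass
class DilutionSeries:
    """Replicate signal sets along a serial dilution, plus background."""

    dilution_factors: list[float]
    replicate_sets: list[ReplicateSet]
    negative_control: ReplicateSet

    def __post_init__(self) -> None:
        if len(self.dilution_factors) != len(self.replicate_sets):
            raise ValueError("one replicate set required per dilution factor")
        if any(f <= 0 for f in self.dilution_factors):
            raise ValueError("dilution factors must be positive")
        if any(
            b <= a for a, b in zip(self.dilution_factors, self.dilution_factors[1:])
        ):
            raise ValueError("dilution factors must be strictly increasing")


@dataclasses.dataclass
class LinearityResult:
    """Log-log linearity fit of a dilution series.

    ``slope`` is for log10(mean RLU) regressed on the log10 concentration
    surrogate -log10(dilution factor), so an ideally linear assay has slope
    +1.  Levels indistinguishable from background (mean <= control mean +
    2 * control SD) are excluded from the fit and listed in
    ``excluded_levels``.
    """

    r_squared: float
    slope: float
    intercept: float
    per_level_z: dict[float, float]
    excluded_levels: list[float]
    n_levels_fit: int


def dilution_linearity(series: DilutionSeries) -> LinearityResult:
    """Assess linearity and per-level sensitivity of a dilution series."""
    neg = series.negative_control
    background_ceiling = neg.mean + 2.0 * neg.sd

    per_level_z: dict[float, float] = {}
    xs, ys, excluded = [], [], []
    for factor, reps in zip(series.dilution_factors, series.replicate_sets):
        try:
            per_level_z[factor] = z_factor(reps, neg)
        except UndefinedStatisticError:
            per_level_z[factor] = float("nan")
        if reps.mean <= background_ceiling:
            excluded.append(factor)
            continue
        xs.append(-np.log10(factor))
        ys.append(np.log10(reps.mean))

    if len(xs) < 3:
        raise InsufficientDataError(
            f"dilution linearity needs >=3 levels above background, got {len(xs)}"
        )
    fit = stats.linregress(xs, ys)
    return LinearityResult(
        r_squared=float(fit.rvalue**2),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        per_level_z=per_level_z,
        excluded_levels=excluded,
        n_levels_fit=len(xs),
    )


@dataclasses.dataclass
class QcReport:
    """Bundle of assay-characterization statistics, CV in percent."""

    intra_cv: dict[str, float]
    inter_cv: dict[str, float]
    linearity: LinearityResult | None = None

    def to_dict(self) -> dict:
        out: dict = {
            "intra_assay_cv_percent": {k: round(v, 2) for k, v in self.intra_cv.items()},
            "inter_assay_cv_percent": {k: round(v, 2) for k, v in self.inter_cv.items()},
        }
        if self.linearity is not None:
            out["linearity"] = {
                "r_squared": self.linearity.r_squared,
                "slope": self.linearity.slope,
                "per_level_z_factor": {
                    str(k): v for k, v in self.linearity.per_level_z.items()
                },
                "excluded_levels": self.linearity.excluded_levels,
            }
        return out


def qc_report(
    replicate_sets: Sequence[ReplicateSet], linearity: LinearityResult | None = None
) -> QcReport:
    """Compute CVs for every replicate set, split by replicate level."""
    intra = {
        r.label: intra_assay_cv(r) for r in replicate_sets if r.level == "technical"
    }
    inter = {
        r.label: inter_assay_cv(r) for r in replicate_sets if r.level == "biological"
    }
    return QcReport(intra_cv=intra, inter_cv=inter, linearity=linearity)
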