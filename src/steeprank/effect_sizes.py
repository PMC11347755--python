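"""Effect-size construction: rank-benefit correlations, conversions from
foreign statistics, Fisher's Z, sampling variances and aggregation rules."""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable, Sequence

import numpy as np

from .dominance import OrdinalRanks

__all__ = [
    "BenefitTable",
    "EffectSizeRecord",
    "UndefinedCorrelationError",
    "WINSOR_LIMIT",
    "DIRECT_BENEFITS",
    "INDIRECT_BENEFITS",
    "benefit_category_for",
    "pearson_r",
    "signed_ordinal_r",
    "r_from_chi_square",
    "r_from_means_sd",
    "fisher_z",
    "z_variance",
    "aggregate_measures",
    "aggregate_steepness",
    "build_record",
]

log = logging.getLogger(__name__)

WINSOR_LIMIT = 1.0 - 1e-6
MIN_SAMPLE_SIZE = 4

DIRECT_BENEFITS = frozenset({"fecundity", "infant_survival"})
INDIRECT_BENEFITS = frozenset({"mating_success", "feeding_success"})


class UndefinedCorrelationError(ValueError):
    """Raised when a correlation is undefined (zero variance)."""


def benefit_category_for(benefit_type: str) -> str:
    if benefit_type in DIRECT_BENEFITS:
        return "direct"
    if benefit_type in INDIRECT_BENEFITS:
        return "indirect"
    raise ValueError(f"unknown benefit type: {benefit_type!r}")


@dataclasses.dataclass(frozen=True)
class BenefitTable:
    """Per-individual benefit values for one group and one measure."""

    ids: tuple[str, ...]
    values: np.ndarray
    benefit_type: str

    @property
    def benefit_category(self) -> str:
        return benefit_category_for(self.benefit_type)

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclasses.dataclass(frozen=True)
class EffectSizeRecord:
    """One meta-analytic data point."""

    z_r: float
    v: float
    r: float
    n: int
    rank_basis: str  # "cardinal" or "ordinal"
    method: str  # NDS_Dij | Elo_rpt | Elo_Bayes | DS_Bayes
    group: str
    species: str
    benefit_category: str
    duration_months: float
    setting: str
    sex: str
    dispersal: str
    social_org: str
    origin: str
    steepness: float = math.nan
    pub_year: float | None = None
    record_id: str | None = None


def _winsorize(r: float) -> float:
    if abs(r) >= 1.0:
        log.warning("|r| = 1 winsorized to %.6f", WINSOR_LIMIT)
        return math.copysign(WINSOR_LIMIT, r)
    return float(r)


def pearson_r(benefits: Sequence[float], scores: Sequence[float]) -> float:
    """Product-moment correlation; |r| = 1 winsorized to 1 - 1e-6."""
    x = np.asarray(benefits, dtype=float)
    y = np.asarray(scores, dtype=float)
    if x.shape != y.shape:
        raise ValueError("benefits and scores must be paired")
    if x.size < MIN_SAMPLE_SIZE:
        raise ValueError(f"n = {x.size} < {MIN_SAMPLE_SIZE}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in benefits or scores")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    return _winsorize(max(-1.0, min(1.0, r)))


def signed_ordinal_r(benefits: Sequence[float], ordinal: OrdinalRanks) -> float:
    """Correlation of benefits with ordinal rank, sign-flipped so that
    "dominants (rank 1) obtain more" comes out positive."""
    return _winsorize(-pearson_r(benefits, np.asarray(ordinal.rank, dtype=float)))


def r_from_chi_square(chi2: float, n: int, direction: int) -> float:
    """r = direction * sqrt(chi2 / n); direction (+1/-1) must be supplied."""
    if chi2 < 0:
        raise ValueError("chi2 must be >= 0")
    if n <= 0:
        raise ValueError("n must be positive")
    if direction not in (-1, 1):
        raise ValueError("direction must be +1 or -1")
    if chi2 > n:
        log.warning("chi2 = %g exceeds n = %d; |r| capped", chi2, n)
    r = direction * min(math.sqrt(chi2 / n), 1.0)
    return _winsorize(r)


def r_from_means_sd(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int
) -> float:
    """Correlation from two group means via pooled-SD Cohen's d.

    r = d / sqrt(d^2 + a) with a = (n1+n2)^2 / (n1 n2).
    """
    if n1 + n2 < MIN_SAMPLE_SIZE:
        raise ValueError("combined sample size < 4")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("negative standard deviation")
    pooled = math.sqrt(
        ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    )
    if pooled == 0:
        raise ValueError("zero pooled standard deviation")
    d = (m1 - m2) / pooled
    a = (n1 + n2) ** 2 / (n1 * n2)
    return _winsorize(d / math.sqrt(d * d + a))


def fisher_z(r: float) -> float:
    """z = atanh(r) = 0.5 ln((1+r)/(1-r)); requires |r| < 1."""
    if abs(r) >= 1.0:
        raise ValueError("|r| >= 1; winsorize upstream")
    return math.atanh(r)


def z_variance(n: int) -> float:
    """Sampling variance of Fisher's Z: 1 / (n - 3); requires n >= 4."""
    if n < MIN_SAMPLE_SIZE:
        raise ValueError(f"n = {n} < {MIN_SAMPLE_SIZE}")
    return 1.0 / (n - 3)


def aggregate_measures(rs: Iterable[float]) -> float:
    """Mean of several correlation coefficients (pre-Fisher scale)."""
    rs = list(rs)
    if not rs:
        raise ValueError("empty list of correlations")
    return float(np.mean(rs))


def aggregate_steepness(values: Iterable[float]) -> float:
    """Mean of steepness values from several matrices of the same period."""
    values = list(values)
    if not values:
        raise ValueError("empty list of steepness values")
    return float(np.mean(values))


_REQUIRED_MODERATORS = (
    "duration_months",
    "setting",
    "sex",
    "dispersal",
    "social_org",
    "origin",
)


def build_record(
    *,
    group: str,
    species: str,
    rank_basis: str,
    method: str,
    steepness_values: Sequence[float],
    rs: Sequence[float],
    n: int,
    benefit_type: str,
    moderators: dict,
    pub_year: float | None = None,
    record_id: str | None = None,
    r_is_spearman: bool = False,
) -> EffectSizeRecord:
    """Assemble one effect-size record.

    ``rs`` holds one correlation per available measure (they are averaged
    on the r scale); ``steepness_values`` one steepness per available
    matrix (averaged on the steepness scale).  Literature Spearman
    coefficients are accepted and treated as r, with a log line.
    """
    missing = [f for f in _REQUIRED_MODERATORS if f not in moderators]
    if missing:
        raise ValueError(f"missing moderator field(s): {missing}")
    if n < MIN_SAMPLE_SIZE:
        raise ValueError(
            f"group {group!r}: sample size {n} < {MIN_SAMPLE_SIZE}; excluded"
        )
    if r_is_spearman:
        log.info("group %s: Spearman coefficient treated as Pearson r", group)
    r = _winsorize(aggregate_measures(rs))
    steep = aggregate_steepness(steepness_values)
    return EffectSizeRecord(
        z_r=fisher_z(r),
        v=z_variance(n),
        r=r,
        n=int(n),
        rank_basis=rank_basis,
        method=method,
        group=group,
        species=species,
        benefit_category=benefit_category_for(benefit_type),
        duration_months=float(moderators["duration_months"]),
        setting=str(moderators["setting"]),
        sex=str(moderators["sex"]),
        dispersal=str(moderators["dispersal"]),
        social_org=str(moderators["social_org"]),
        origin=str(moderators["origin"]),
        steepness=steep,
        pub_year=pub_year,
        record_id=record_id,
    )
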