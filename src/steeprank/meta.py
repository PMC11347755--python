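"""Phylogenetic multilevel meta-regression with known sampling variances.

Model: y_i = x_i'beta + u_species + u_group + u_phylo + e_i, with
u_species ~ N(0, s2_s I), u_group ~ N(0, s2_g I),
u_phylo ~ N(0, s2_p A) (A the species correlation matrix) and
e_i ~ N(0, v_i) with v_i known.  Variance components are estimated by
(RE)ML over [0, inf)^3 via bounded quasi-Newton on the log scale with
multi-start; beta is GLS at the optimum.

Companion tests: full-vs-control likelihood-ratio tests, the omnibus
moderator Wald test (Q_M), fixed-effects residual heterogeneity (Q_E),
a phylogenetic-signal ratio with its own LRT, and small-study / time-lag
publication-bias meta-regressions.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .effect_sizes import EffectSizeRecord
from .phylo import PhyloCorrelation

__all__ = [
    "CATEGORICAL_LEVELS",
    "FULL_CONTROLS",
    "DesignSpec",
    "Design",
    "MetaFit",
    "LRTResult",
    "SignalResult",
    "records_to_frame",
    "build_design",
    "profile_loglik",
    "fit_at_sigma2",
    "fit",
    "lrt",
    "omnibus_qm",
    "qe_test",
    "phylo_signal",
    "small_study_test",
    "time_lag_test",
]

# declared level order; the first level is the dropped reference
CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "benefit_category": ("direct", "indirect"),
    "setting": ("wild", "provisioned", "captive"),
    "sex": ("female", "male", "both"),
    "dispersal": ("female_philopatry", "male_philopatry", "none"),
    "social_org": ("OMG", "MMG", "MLS"),
    "origin": ("published", "unpublished"),
}

# continuous predictors standardized to mean 0, sd 1
_STANDARDIZED = {"steepness", "duration_months", "pub_year"}
# continuous predictors entered on their raw scale
_RAW = {"inv_sqrt_n"}

FULL_CONTROLS: tuple[str, ...] = (
    "benefit_category",
    "duration_months",
    "setting",
    "sex",
    "dispersal",
    "social_org",
    "origin",
)

_VARCOMP_NAMES = ("species", "group", "phylo")


class DesignError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class DesignSpec:
    """Fixed-effect structure of one meta-regression model.

    ``predictors`` are column names: 'steepness', the control variables,
    or bias moderators ('inv_sqrt_n', 'pub_year').  ``interaction``
    optionally names a factor whose centered dummies are multiplied with
    standardized steepness.
    """

    predictors: tuple[str, ...]
    interaction: str | None = None

    @staticmethod
    def full() -> "DesignSpec":
        return DesignSpec(predictors=("steepness",) + FULL_CONTROLS)

    @staticmethod
    def control() -> "DesignSpec":
        return DesignSpec(predictors=FULL_CONTROLS)

    @staticmethod
    def intercept_only() -> "DesignSpec":
        return DesignSpec(predictors=())


@dataclasses.dataclass(frozen=True)
class Design:
    y: np.ndarray
    v: np.ndarray
    x: np.ndarray
    columns: tuple[str, ...]
    species: tuple[str, ...]
    groups: tuple[str, ...]

    @property
    def k(self) -> int:
        return self.y.size

    @property
    def p(self) -> int:
        return self.x.shape[1]


@dataclasses.dataclass(frozen=True)
class MetaFit:
    beta: np.ndarray
    se: np.ndarray
    vcov_beta: np.ndarray
    columns: tuple[str, ...]
    sigma2: np.ndarray  # (species, group, phylo); phylo entry 0 if excluded
    loglik: float
    method: str
    k: int
    p: int
    n_varcomp: int
    qm: float | None = None
    qm_df: int | None = None
    qm_p: float | None = None

    @property
    def df_model(self) -> int:
        """Fixed parameters + variance components."""
        return self.p + self.n_varcomp

    def coef_table(self) -> pd.DataFrame:
        z = np.divide(self.beta, self.se, out=np.zeros_like(self.beta),
                      where=self.se > 0)
        return pd.DataFrame(
            {
                "beta": self.beta,
                "se": self.se,
                "z": z,
                "p": 2 * stats.norm.sf(np.abs(z)),
            },
            index=list(self.columns),
        )


@dataclasses.dataclass(frozen=True)
class LRTResult:
    chi2: float
    df: int
    p: float


@dataclasses.dataclass(frozen=True)
class SignalResult:
    lambda_hat: float
    chi2: float
    p: float
    sigma2_full: np.ndarray
    loglik_full: float
    loglik_nophylo: float


def records_to_frame(records: Iterable[EffectSizeRecord]) -> pd.DataFrame:
    rows = [dataclasses.asdict(r) for r in records]
    if not rows:
        raise ValueError("no records")
    return pd.DataFrame(rows)


def _standardize(x: np.ndarray, name: str) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DesignError(f"zero-variance moderator: {name}")
    return (x - x.mean()) / sd


def _expand(df: pd.DataFrame, name: str) -> tuple[list[np.ndarray], list[str]]:
    """Columns for one predictor: standardized continuous or centered dummies."""
    if name in CATEGORICAL_LEVELS:
        levels = CATEGORICAL_LEVELS[name]
        vals = df[name].astype(str)
        bad = sorted(set(vals) - set(levels))
        if bad:
            raise DesignError(f"unknown level(s) {bad} for factor {name!r}")
        cols, names = [], []
        for lvl in levels[1:]:
            d = (vals == lvl).to_numpy(dtype=float)
            cols.append(d - d.mean())
            names.append(f"{name}[{lvl}]")
        return cols, names
    x = df[name].to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise DesignError(f"non-finite values in predictor {name!r}")
    if name in _STANDARDIZED:
        return [_standardize(x, name)], [name]
    if name in _RAW:
        if np.ptp(x) == 0:
            raise DesignError(f"zero-variance moderator: {name}")
        return [x], [name]
    raise DesignError(f"unknown predictor: {name!r}")


def build_design(
    records: Iterable[EffectSizeRecord] | pd.DataFrame, spec: DesignSpec
) -> Design:
    """Response, sampling variances, design matrix and grouping labels.

    Continuous predictors are standardized; categoricals are dummy-coded
    with the first declared level dropped and retained dummies centered.
    A rank-deficient design raises :class:`DesignError` listing the
    aliased columns.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    for req in ("z_r", "v", "group", "species"):
        if req not in df.columns:
            raise DesignError(f"records lack required field {req!r}")
    if "inv_sqrt_n" in spec.predictors and "inv_sqrt_n" not in df.columns:
        df = df.assign(inv_sqrt_n=np.sqrt(1.0 / df["n"].to_numpy(dtype=float)))
    cols: list[np.ndarray] = [np.ones(len(df))]
    names: list[str] = ["intercept"]
    for name in spec.predictors:
        c, n = _expand(df, name)
        cols.extend(c)
        names.extend(n)
    if spec.interaction is not None:
        if "steepness" not in spec.predictors:
            raise DesignError("interaction requires 'steepness' among predictors")
        if spec.interaction not in spec.predictors:
            raise DesignError("interaction factor must be among predictors")
        steep = _standardize(df["steepness"].to_numpy(dtype=float), "steepness")
        dcols, dnames = _expand(df, spec.interaction)
        for c, n in zip(dcols, dnames):
            cols.append(steep * c)
            names.append(f"steepness:{n}")
    x = np.column_stack(cols)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        _, r = np.linalg.qr(x)
        aliased = [names[j] for j in range(x.shape[1]) if abs(r[j, j]) < 1e-8]
        raise DesignError(f"rank-deficient design; aliased columns: {aliased}")
    v = df["v"].to_numpy(dtype=float)
    if np.any(v <= 0):
        raise DesignError("all sampling variances must be positive")
    return Design(
        y=df["z_r"].to_numpy(dtype=float),
        v=v,
        x=x,
        columns=tuple(names),
        species=tuple(df["species"].astype(str)),
        groups=tuple(df["group"].astype(str)),
    )


def _random_effect_gram(
    design: Design, A: PhyloCorrelation | None
) -> list[np.ndarray]:
    """Gram matrices of the random effects: Zs Zs', Zg Zg', Zs A Zs'."""
    sp = pd.Categorical(design.species)
    gr = pd.Categorical([f"{s}//{g}" for s, g in zip(design.species, design.groups)])
    zs = np.eye(len(sp.categories))[sp.codes]
    zg = np.eye(len(gr.categories))[gr.codes]
    grams = [zs @ zs.T, zg @ zg.T]
    if A is not None:
        missing = sorted(set(sp.categories) - set(A.ids))
        if missing:
            raise DesignError(f"species missing from correlation matrix: {missing}")
        asub = A.reorder(list(sp.categories)).matrix
        grams.append(zs @ asub @ zs.T)
    return grams


def _profile(
    sigma2: np.ndarray, design: Design, grams: list[np.ndarray], method: str
) -> tuple[float, np.ndarray, np.ndarray]:
    """Profiled log-likelihood, GLS beta and its covariance at sigma2."""
    vmat = np.diag(design.v).astype(float)
    for s2, g in zip(sigma2, grams):
        vmat += s2 * g
    c, low = cho_factor(vmat, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    viy = cho_solve((c, low), design.y)
    vix = cho_solve((c, low), design.x)
    xtvix = design.x.T @ vix
    xtviy = design.x.T @ viy
    cov_beta = np.linalg.inv(xtvix)
    beta = cov_beta @ xtviy
    resid = design.y - design.x @ beta
    vir = cho_solve((c, low), resid)
    quad = resid @ vir
    k, p = design.k, design.p
    if method == "ML":
        ll = -0.5 * (k * np.log(2 * np.pi) + logdet + quad)
    elif method == "REML":
        sign, logdet_x = np.linalg.slogdet(xtvix)
        if sign <= 0:
            raise np.linalg.LinAlgError("X'V^-1X not positive definite")
        ll = -0.5 * ((k - p) * np.log(2 * np.pi) + logdet + logdet_x + quad)
    else:
        raise ValueError("method must be 'ML' or 'REML'")
    return float(ll), beta, cov_beta


def profile_loglik(
    records,
    spec: DesignSpec,
    A: PhyloCorrelation | None,
    sigma2: Sequence[float],
    method: str = "ML",
) -> float:
    """Profiled log-likelihood at fixed variance components (oracle hook)."""
    design = records if isinstance(records, Design) else build_design(records, spec)
    grams = _random_effect_gram(design, A)
    sigma2 = np.asarray(sigma2, dtype=float)
    if sigma2.size != len(grams):
        raise ValueError(f"expected {len(grams)} variance components")
    return _profile(sigma2, design, grams, method)[0]


def fit_at_sigma2(
    records,
    spec: DesignSpec,
    A: PhyloCorrelation | None,
    sigma2: Sequence[float],
    method: str = "ML",
) -> MetaFit:
    """GLS fixed effects and likelihood at user-fixed variance components."""
    design = records if isinstance(records, Design) else build_design(records, spec)
    grams = _random_effect_gram(design, A)
    sigma2 = np.asarray(sigma2, dtype=float)
    if sigma2.size != len(grams):
        raise ValueError(f"expected {len(grams)} variance components")
    ll, beta, cov_beta = _profile(sigma2, design, grams, method)
    out = np.zeros(3)
    out[: sigma2.size] = sigma2
    fit_ = MetaFit(
        beta=beta,
        se=np.sqrt(np.diag(cov_beta)),
        vcov_beta=cov_beta,
        columns=design.columns,
        sigma2=out,
        loglik=ll,
        method=method,
        k=design.k,
        p=design.p,
        n_varcomp=len(grams),
    )
    if design.p > 1:
        qm, df, pv = omnibus_qm(fit_)
        fit_ = dataclasses.replace(fit_, qm=qm, qm_df=df, qm_p=pv)
    return fit_


_LOG_FLOOR = np.log(1e-10)


def fit(
    records,
    spec: DesignSpec,
    A: PhyloCorrelation | None,
    method: str = "ML",
    n_starts: int = 5,
    tol: float = 1e-8,
) -> MetaFit:
    """Maximize the (RE)ML likelihood over the variance components.

    ``A=None`` drops the phylogenetic component (two free components).
    Deterministic given the data: starting points are data-derived, and
    the best of ``n_starts`` bounded L-BFGS-B runs on log(sigma2) wins.
    """
    design = records if isinstance(records, Design) else build_design(records, spec)
    if design.k <= design.p:
        raise ValueError(f"k = {design.k} <= p = {design.p}")
    grams = _random_effect_gram(design, A)
    m = len(grams)

    def nll(theta: np.ndarray) -> float:
        try:
            return -_profile(np.exp(theta), design, grams, method)[0]
        except np.linalg.LinAlgError:
            return 1e12

    vy = max(float(np.var(design.y, ddof=1)) if design.k > 1 else 0.1, 1e-6)
    base = max(vy - float(np.mean(design.v)), vy / 10.0, 1e-6)
    starts = [
        np.log(np.full(m, base / m)),
        np.full(m, _LOG_FLOOR / 2),
        np.log(np.full(m, base)),
    ]
    for j in range(m):
        s = np.full(m, 1e-6)
        s[j] = base
        starts.append(np.log(s))
    starts = starts[: max(1, n_starts)]
    hi = np.log(10.0 * vy + 1.0)
    best = None
    for x0 in starts:
        res = optimize.minimize(
            nll,
            np.clip(x0, _LOG_FLOOR, hi),
            method="L-BFGS-B",
            bounds=[(_LOG_FLOOR, hi)] * m,
            options={"ftol": tol, "gtol": 1e-7, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("variance-component optimization failed to converge")
    sigma2_free = np.exp(best.x)
    ll, beta, cov_beta = _profile(sigma2_free, design, grams, method)
    sigma2 = np.zeros(3)
    sigma2[:2] = sigma2_free[:2]
    if m == 3:
        sigma2[2] = sigma2_free[2]
    # values at the lower bound are numerically zero
    sigma2[sigma2 <= 2e-10] = 0.0
    se = np.sqrt(np.diag(cov_beta))
    fit_ = MetaFit(
        beta=beta,
        se=se,
        vcov_beta=cov_beta,
        columns=design.columns,
        sigma2=sigma2,
        loglik=ll,
        method=method,
        k=design.k,
        p=design.p,
        n_varcomp=m,
    )
    if design.p > 1:
        qm, df, pv = omnibus_qm(fit_)
        fit_ = dataclasses.replace(fit_, qm=qm, qm_df=df, qm_p=pv)
    return fit_


def lrt(full: MetaFit, control: MetaFit, df: int | None = None) -> LRTResult:
    """Likelihood-ratio test of nested fixed-effect structures (ML fits)."""
    if full.method != "ML" or control.method != "ML":
        raise ValueError("LRTs across fixed-effect structures require ML fits")
    if not set(control.columns) <= set(full.columns):
        raise ValueError("models are not nested")
    if full.n_varcomp != control.n_varcomp:
        raise ValueError("random-effect structures differ")
    if df is None:
        df = full.p - control.p
    chi2 = max(0.0, 2.0 * (full.loglik - control.loglik))
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return LRTResult(chi2=chi2, df=df, p=p)


def omnibus_qm(fit_: MetaFit) -> tuple[float, int, float]:
    """Wald test of all non-intercept coefficients against zero."""
    idx = [j for j, c in enumerate(fit_.columns) if c != "intercept"]
    if not idx:
        raise ValueError("intercept-only model has no moderators to test")
    b = fit_.beta[idx]
    c = fit_.vcov_beta[np.ix_(idx, idx)]
    qm = float(b @ np.linalg.solve(c, b))
    df = len(idx)
    return qm, df, float(stats.chi2.sf(qm, df))


def qe_test(records, spec: DesignSpec) -> tuple[float, int, float]:
    """Fixed-effects residual heterogeneity: Q_E = sum w_i r_i^2, w = 1/v."""
    design = records if isinstance(records, Design) else build_design(records, spec)
    w = 1.0 / design.v
    xw = design.x * w[:, None]
    beta = np.linalg.solve(design.x.T @ xw, xw.T @ design.y)
    resid = design.y - design.x @ beta
    qe = float(np.sum(w * resid**2))
    df = design.k - design.p
    return qe, df, float(stats.chi2.sf(qe, df))


def phylo_signal(
    records,
    spec: DesignSpec,
    A: PhyloCorrelation,
    boundary_mixture: bool = False,
    n_starts: int = 5,
) -> SignalResult:
    """Share of random-effect variance that is phylogenetic, with an LRT.

    lambda_hat = s2_phylo / (s2_species + s2_group + s2_phylo) (0 when all
    components are 0).  The LRT compares the full ML fit against the fit
    with the phylogenetic component removed; the reference is chi2(1), or
    the 50:50 boundary mixture when ``boundary_mixture`` is set.
    """
    design = records if isinstance(records, Design) else build_design(records, spec)
    full = fit(design, spec, A, method="ML", n_starts=n_starts)
    nophylo = fit(design, spec, None, method="ML", n_starts=n_starts)
    total = float(full.sigma2.sum())
    lam = float(full.sigma2[2] / total) if total > 0 else 0.0
    chi2 = max(0.0, 2.0 * (full.loglik - nophylo.loglik))
    p = float(stats.chi2.sf(chi2, 1))
    if boundary_mixture:
        p = 0.5 * p if chi2 > 0 else 1.0
    return SignalResult(
        lambda_hat=lam,
        chi2=chi2,
        p=p,
        sigma2_full=full.sigma2,
        loglik_full=full.loglik,
        loglik_nophylo=nophylo.loglik,
    )


def _single_moderator_test(
    records, moderator: str, A: PhyloCorrelation | None, n_starts: int = 3
) -> tuple[float, float]:
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if len(df) == 0:
        raise ValueError("empty record subset")
    spec = DesignSpec(predictors=(moderator,))
    fit_ = fit(df, spec, A, method="ML", n_starts=n_starts)
    j = list(fit_.columns).index(moderator)
    z = float(fit_.beta[j] / fit_.se[j])
    return z, float(2 * stats.norm.sf(abs(z)))


def small_study_test(
    records, A: PhyloCorrelation | None = None, n_starts: int = 3
) -> tuple[float, float]:
    """Small-study-effect meta-regression: moderator sqrt(1/n).

    Call on the published-origin subset.  Returns (Z, two-sided p).
    """
    return _single_moderator_test(records, "inv_sqrt_n", A, n_starts)


def time_lag_test(
    records, A: PhyloCorrelation | None = None, n_starts: int = 3
) -> tuple[float, float]:
    """Time-lag meta-regression: moderator standardized publication year."""
    return _single_moderator_test(records, "pub_year", A, n_starts)
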