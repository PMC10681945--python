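"""Design-based estimation for stratified multistage survey samples.

Point estimates are weighted (Horvitz-Thompson style ratio) means; variances
use first-order Taylor linearization with the with-replacement first-stage
approximation that is standard for public-use health-survey microdata: per
subject scores are totaled within primary sampling units (PSUs), and the
variance is the stratified between-PSU sum

    Var = sum_h  n_h/(n_h - 1) * sum_j (z_hj - zbar_h)^2

with n_h the number of PSUs in stratum h. The same machinery yields sandwich
variances for weighted regression coefficients and covariate-adjusted
(least-squares) means. Degrees of freedom follow the usual survey rule,
(number of PSUs) - (number of strata).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class SurveyDesign:
    """Per-subject survey weights and the stratum/PSU clustering structure.

    When several survey cycles are pooled, the per-cycle weight is divided
    by ``n_cycles`` to form the analysis weight.
    """

    weight: np.ndarray
    stratum: np.ndarray
    psu: np.ndarray
    n_cycles: int = 1

    def __post_init__(self) -> None:
        self.weight = np.asarray(self.weight, dtype=float)
        self.stratum = np.asarray(self.stratum)
        self.psu = np.asarray(self.psu)
        if not (len(self.weight) == len(self.stratum) == len(self.psu)):
            raise ValueError("weight, stratum and psu must have equal length")
        if np.any(self.weight < 0):
            raise ValueError("survey weights must be nonnegative")
        if self.weight.sum() <= 0:
            raise ValueError("total survey weight must be positive")
        # PSU labels are only meaningful within their stratum (nested design)
        combo = pd.MultiIndex.from_arrays([self.stratum, self.psu])
        self._cluster, _ = pd.factorize(combo, sort=True)
        self._stratum_codes, self._strata = pd.factorize(self.stratum, sort=True)
        cluster_stratum = pd.Series(self._stratum_codes).groupby(self._cluster).first()
        self._cluster_stratum = cluster_stratum.to_numpy()
        self._n_psus_per_stratum = np.bincount(self._cluster_stratum,
                                               minlength=len(self._strata))

    def __len__(self) -> int:
        return len(self.weight)

    @classmethod
    def from_subjects(cls, subjects: pd.DataFrame, n_cycles: int = 1) -> "SurveyDesign":
        return cls(weight=subjects["day1_weight"].to_numpy(dtype=float),
                   stratum=subjects["stratum_id"].to_numpy(),
                   psu=subjects["psu_id"].to_numpy(),
                   n_cycles=n_cycles)

    @property
    def analysis_weight(self) -> np.ndarray:
        return self.weight / self.n_cycles

    @property
    def n_psus(self) -> int:
        return int(self._cluster.max()) + 1

    @property
    def n_strata(self) -> int:
        return len(self._strata)

    @property
    def degrees_of_freedom(self) -> int:
        return self.n_psus - self.n_strata

    def subset(self, mask: np.ndarray) -> "SurveyDesign":
        mask = np.asarray(mask, dtype=bool)
        return SurveyDesign(self.weight[mask], self.stratum[mask],
                            self.psu[mask], self.n_cycles)

    def _check_variance_strata(self) -> None:
        lonely = [str(self._strata[h]) for h in range(self.n_strata)
                  if self._n_psus_per_stratum[h] < 2]
        if lonely:
            raise ValueError(
                f"stratum {lonely[0]!r} has a single PSU; cannot estimate variance "
                "(no silent collapsing is performed)"
            )

    def linearized_variance(self, scores: np.ndarray) -> np.ndarray:
        """Stratified between-PSU variance of summed per-subject scores.

        ``scores`` is (n,) or (n, p); returns a scalar variance or a (p, p)
        covariance matrix of the score total.
        """
        self._check_variance_strata()
        z = np.asarray(scores, dtype=float)
        was_1d = z.ndim == 1
        if was_1d:
            z = z[:, None]
        # PSU totals
        p = z.shape[1]
        totals = np.zeros((self.n_psus, p))
        np.add.at(totals, self._cluster, z)
        cov = np.zeros((p, p))
        for h in range(self.n_strata):
            sel = self._cluster_stratum == h
            n_h = int(sel.sum())
            zh = totals[sel]
            dev = zh - zh.mean(axis=0)
            cov += n_h / (n_h - 1) * dev.T @ dev
        return float(cov[0, 0]) if was_1d else cov


@dataclass(frozen=True)
class MeanResult:
    estimate: float
    se: float
    n: int
    df: int


@dataclass(frozen=True)
class TrendFit:
    """Weighted age-trend regression: change in outcome per year of age."""

    beta: float
    se: float
    t: float
    p: float
    df: int
    n: int
    covariates: tuple[str, ...]
    dropped_terms: tuple[str, ...] = ()


@dataclass(frozen=True)
class RatioResult:
    percent: float
    se: float
    n: int


@dataclass(frozen=True)
class PairedTResult:
    mean_diff: float
    se: float
    t: float
    p: float
    df: int
    degenerate: bool = False


def weighted_mean(values: Sequence[float], design: SurveyDesign) -> MeanResult:
    """Design-weighted mean with Taylor-linearized standard error."""
    y = np.asarray(values, dtype=float)
    if len(y) != len(design):
        raise ValueError("values not aligned with design")
    w = design.analysis_weight
    wsum = w.sum()
    est = float(w @ y / wsum)
    scores = w * (y - est) / wsum
    var = design.linearized_variance(scores)
    return MeanResult(estimate=est, se=float(np.sqrt(max(var, 0.0))),
                      n=len(y), df=design.degrees_of_freedom)


def population_ratio(source: Sequence[float], total: Sequence[float],
                     design: SurveyDesign) -> RatioResult:
    """Percent contribution of a source to a total, population-ratio method.

    100 * (weighted sum of source intake) / (weighted sum of total intake),
    with a linearized SE for the ratio. Sources exceeding their totals are
    permitted but logged.
    """
    s = np.asarray(source, dtype=float)
    t = np.asarray(total, dtype=float)
    w = design.analysis_weight
    tsum = float(w @ t)
    if tsum == 0:
        raise ValueError("population ratio undefined: weighted total intake is zero")
    if np.any(s > t + 1e-9):
        logger.warning("population_ratio: %d subjects report source > total",
                       int((s > t + 1e-9).sum()))
    ratio = float(w @ s) / tsum
    scores = w * (s - ratio * t) / tsum
    var = design.linearized_variance(scores)
    return RatioResult(percent=100.0 * ratio, se=100.0 * float(np.sqrt(max(var, 0.0))),
                       n=len(s))


def _design_matrix(covariates: pd.DataFrame | None,
                   drop_first: bool = True) -> tuple[np.ndarray, list[str]]:
    if covariates is None or covariates.shape[1] == 0:
        return np.empty((0 if covariates is None else len(covariates), 0)), []
    dummies = pd.get_dummies(covariates.astype("category"), drop_first=drop_first,
                             dtype=float)
    return dummies.to_numpy(), list(dummies.columns)


def _drop_degenerate(X: np.ndarray, names: list[str], w: np.ndarray,
                     protect: int) -> tuple[np.ndarray, list[str], list[str]]:
    """Drop all-zero and collinear columns beyond the first ``protect`` ones."""
    keep = list(range(X.shape[1]))
    dropped: list[str] = []
    # all-(weighted-)zero columns first
    for j in range(X.shape[1] - 1, protect - 1, -1):
        if np.all(X[:, j] * w == 0):
            dropped.append(names[j])
            keep.remove(j)
    # collinear columns: unpivoted QR flags a dependent column by a tiny
    # diagonal entry at its own position; drop from the right and re-check
    while True:
        sw = np.sqrt(w)[:, None] * X[:, keep]
        r = np.linalg.qr(sw, mode="r")
        diag = np.abs(np.diag(r))
        tol = max(sw.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
        bad = [i for i in range(len(keep)) if diag[i] <= tol and keep[i] >= protect]
        if not bad:
            break
        j = keep[bad[-1]]
        dropped.append(names[j])
        keep.remove(j)
    if dropped:
        logger.info("dropped degenerate design columns: %s", dropped)
    return X[:, keep], [names[j] for j in keep], dropped


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(sw[:, None] * X, sw * y, rcond=None)
    return beta


def _sandwich(X: np.ndarray, resid: np.ndarray, w: np.ndarray,
              design: SurveyDesign) -> np.ndarray:
    A = X.T @ (w[:, None] * X)
    U = w[:, None] * X * resid[:, None]
    M = design.linearized_variance(U)
    Ainv = np.linalg.pinv(A)
    return Ainv @ M @ Ainv


def trend_regression(outcome: Sequence[float], age_years: Sequence[float],
                     design: SurveyDesign,
                     covariates: pd.DataFrame | None = None) -> TrendFit:
    """Weighted linear trend of an outcome across age, with design-based SE.

    Fits outcome ~ age + categorical covariates by weighted least squares;
    the age coefficient is the change per year of age. The variance is the
    stratified-PSU sandwich, and p comes from a t distribution on
    (PSUs - strata) degrees of freedom.
    """
    y = np.asarray(outcome, dtype=float)
    age = np.asarray(age_years, dtype=float)
    w = design.analysis_weight
    C, cnames = _design_matrix(covariates)
    if C.shape[0] == 0:
        C = np.empty((len(y), 0))
    X = np.column_stack([np.ones(len(y)), age, *C.T]) if C.size else \
        np.column_stack([np.ones(len(y)), age])
    names = ["intercept", "age"] + cnames
    df = design.degrees_of_freedom
    if df <= 0:
        raise ValueError("design has no degrees of freedom: #PSUs <= #strata")
    X, names, dropped = _drop_degenerate(X, names, w, protect=2)
    beta = _wls(X, y, w)
    resid = y - X @ beta
    V = _sandwich(X, resid, w, design)
    j = names.index("age")
    b = float(beta[j])
    se = float(np.sqrt(max(V[j, j], 0.0)))
    if se == 0:
        t = 0.0 if b == 0 else np.inf * np.sign(b)
        p = 1.0 if b == 0 else float(np.finfo(float).tiny)
    else:
        t = b / se
        p = float(2 * stats.t.sf(abs(t), df))
    p = min(max(p, float(np.finfo(float).tiny)), 1.0)
    covnames = tuple(covariates.columns) if covariates is not None else ()
    return TrendFit(beta=b, se=se, t=float(t), p=p, df=df, n=len(y),
                    covariates=covnames, dropped_terms=tuple(dropped))


def lsmeans_by_age_group(outcome: Sequence[float], age_group: Sequence,
                         design: SurveyDesign,
                         covariates: pd.DataFrame | None = None,
                         quantity: str = "outcome") -> pd.DataFrame:
    """Covariate-adjusted (least-squares) means per age group.

    Fits a weighted linear model with age-group cell indicators plus
    categorical covariate indicators, then reports each group's predicted
    marginal mean with covariates averaged over the pooled weighted sample
    distribution (observed-margins convention). SEs come from the
    stratified-PSU sandwich of the corresponding linear combination.

    Returns a tidy frame with columns quantity, age_group, estimate, se, n.
    """
    y = np.asarray(outcome, dtype=float)
    groups = pd.Categorical(age_group)
    w = design.analysis_weight
    G = pd.get_dummies(groups, dtype=float).to_numpy()  # one-hot, no intercept
    C, cnames = _design_matrix(covariates)
    if C.shape[0] == 0:
        C = np.empty((len(y), 0))
    X = np.column_stack([G, C]) if C.size else G
    names = [f"group:{g}" for g in groups.categories] + cnames
    ngroups = G.shape[1]
    X, names, dropped = _drop_degenerate(X, names, w, protect=ngroups)
    beta = _wls(X, y, w)
    resid = y - X @ beta
    V = _sandwich(X, resid, w, design)
    covbar = (w[:, None] * X[:, ngroups:]).sum(axis=0) / w.sum()
    rows = []
    for g_idx, g in enumerate(groups.categories):
        c = np.zeros(X.shape[1])
        c[g_idx] = 1.0
        c[ngroups:] = covbar
        est = float(c @ beta)
        se = float(np.sqrt(max(c @ V @ c, 0.0)))
        n = int((groups.codes == g_idx).sum())
        rows.append({"quantity": quantity, "age_group": str(g),
                     "estimate": est, "se": se, "n": n})
    return pd.DataFrame(rows)


def paired_t(baseline: Sequence[float], adjusted: Sequence[float],
             design: SurveyDesign, *, weighted: bool = True) -> PairedTResult:
    """Design-weighted paired t test of adjusted minus baseline intakes.

    With ``weighted=False`` a naive equal-weight variant is available for
    sensitivity analyses; the clustering structure is kept either way.
    """
    b = np.asarray(baseline, dtype=float)
    a = np.asarray(adjusted, dtype=float)
    if len(b) != len(a):
        raise ValueError("baseline and adjusted must pair the same subjects")
    d = a - b
    des = design if weighted else SurveyDesign(
        np.ones(len(design)), design.stratum, design.psu, design.n_cycles)
    res = weighted_mean(d, des)
    if res.se == 0:
        if res.estimate == 0:
            return PairedTResult(0.0, 0.0, 0.0, 1.0, res.df)
        logger.warning("paired_t: zero SE with nonzero mean difference")
        return PairedTResult(res.estimate, 0.0,
                             float(np.inf * np.sign(res.estimate)),
                             float(np.finfo(float).tiny), res.df, degenerate=True)
    t = res.estimate / res.se
    p = float(2 * stats.t.sf(abs(t), res.df))
    p = min(max(p, float(np.finfo(float).tiny)), 1.0)
    return PairedTResult(res.estimate, res.se, float(t), p, res.df)


def percent_change(from_value: float, to_value: float, mode: str) -> float:
    """Printed-style percent change between two means.

    ``increase`` reports 100*(to-from)/from, ``decrease`` reports
    100*(from-to)/from. Values are rounded half-up to a whole percent,
    keeping one decimal when the magnitude is below 10 — the convention the
    reported tables use.
    """
    if mode not in {"increase", "decrease"}:
        raise ValueError(f"mode must be 'increase' or 'decrease', got {mode!r}")
    if from_value <= 0:
        raise ValueError("percent change requires a positive starting value")
    pct = 100.0 * (float(to_value) - float(from_value)) / float(from_value)
    if mode == "decrease":
        pct = -pct
    quantum = Decimal("0.1") if abs(pct) < 10 else Decimal("1")
    return float(Decimal(repr(pct)).quantize(quantum, rounding=ROUND_HALF_UP))
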