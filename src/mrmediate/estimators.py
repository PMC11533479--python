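"""Two-sample Mendelian-randomization estimators.

All estimators operate on harmonized per-SNP summary statistics: exposure
effects ``beta_exp`` (one column per exposure), outcome effects ``beta_out``
and their standard errors.  They are written as scikit-learn style
estimators — ``fit(X, y, y_se=...)`` with fitted attributes ending in an
underscore — so they compose with sklearn tooling; the module-level
functions (:func:`ivw`, :func:`egger`, ...) are thin wrappers that accept a
:class:`~mrmediate.instruments.HarmonizedSet` and return a tidy
:class:`MREstimate`.

The battery of five methods (IVW, MR-Egger, weighted median, simple mode,
weighted mode) spans different horizontal-pleiotropy assumptions: IVW
requires all instruments valid, Egger allows directional pleiotropy
satisfying InSIDE, the median tolerates up to 50% invalid weight, and the
mode-based estimators require only that the largest cluster of ratio
estimates is valid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .instruments import HarmonizedSet, MultiHarmonizedSet

__all__ = [
    "MREstimate",
    "IVWEstimator",
    "EggerEstimator",
    "WeightedMedianEstimator",
    "ModeEstimator",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
    "mode_based",
    "run_method_battery",
    "bidirectional_check",
    "BidirectionalResult",
    "estimates_to_frame",
]

_Z95 = float(stats.norm.ppf(0.975))


@dataclass
class MREstimate:
    """A single causal-effect estimate with its diagnostics.

    ``beta`` is per unit of exposure, on the log-odds scale when the outcome
    is binary; ``exp(beta)`` is then the odds ratio, taken only at reporting
    time.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    q: float | None = None
    q_pval: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_pval: float | None = None
    outcome_type: str = "binary"

    def __post_init__(self) -> None:
        if not self.ci_low <= self.beta <= self.ci_high:
            raise ValueError("confidence bounds must bracket the point estimate")

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pval": self.pval,
            "n_snp": self.n_snp,
            "q": self.q,
            "q_pval": self.q_pval,
        }
        if self.method == "egger":
            d.update(
                egger_intercept=self.egger_intercept,
                egger_intercept_se=self.egger_intercept_se,
                egger_intercept_pval=self.egger_intercept_pval,
            )
        if self.outcome_type == "binary":
            d["odds_ratio"] = self.odds_ratio
            d["or_ci_low"], d["or_ci_high"] = self.or_ci
        return d


def estimates_to_frame(estimates: Sequence[MREstimate]) -> pd.DataFrame:
    """Tidy table of estimates (one row per method)."""
    return pd.DataFrame([e.to_dict() for e in estimates])


def _as_xy(X, y, y_se):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1:
        X = X.T
    y = np.asarray(y, dtype=float).ravel()
    y_se = np.asarray(y_se, dtype=float).ravel()
    if X.shape[0] != y.size or y_se.size != y.size:
        raise ValueError("X, y and y_se must share their first dimension")
    if (y_se <= 0).any():
        raise ValueError("y_se must be strictly positive")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite inputs")
    return X, y, y_se


class IVWEstimator(RegressorMixin, BaseEstimator):
    """Inverse-variance-weighted estimator (zero-intercept weighted regression).

    Regresses outcome betas on exposure betas through the origin with weights
    ``1/se_out^2``.  With one exposure column this is classical IVW, the
    precision-weighted average of per-SNP Wald ratios; with several columns
    it is multivariable MR, giving each exposure's direct effect conditional
    on the others.

    Parameters
    ----------
    effects_model
        ``"fixed"`` or ``"random"``.  The multiplicative random-effects model
        scales every standard error by ``max(1, sqrt(Q / dof))`` so it never
        shrinks below the fixed-effects value.

    Attributes
    ----------
    coef_ : (k,) causal effect per exposure
    se_, pval_, ci_low_, ci_high_ : per-exposure uncertainty
    q_, q_pval_ : Cochran's Q heterogeneity statistic and p (df = n - k)
    scale_ : multiplicative overdispersion factor applied to the SEs
    """

    def __init__(self, effects_model: str = "random"):
        self.effects_model = effects_model

    def fit(self, X, y, y_se=None):
        if y_se is None:
            raise ValueError("y_se (outcome standard errors) is required")
        if self.effects_model not in ("fixed", "random"):
            raise ValueError(f"unknown effects_model {self.effects_model!r}")
        X, y, y_se = _as_xy(X, y, y_se)
        n, k = X.shape
        if n == 0:
            raise ValueError("no instruments")
        if n < k:
            raise ValueError(f"{n} instruments cannot identify {k} exposures")
        w = 1.0 / y_se**2
        # all-zero columns carry no information: estimable part reduces to
        # the remaining exposures (their coefficient is 0 with infinite se)
        zero_cols = ~X.any(axis=0)
        k_eff = int((~zero_cols).sum())
        xtwx = (X * w[:, None]).T @ X
        if np.linalg.matrix_rank(xtwx) < k_eff:
            raise ValueError("rank-deficient exposure matrix")
        cov = np.linalg.pinv(xtwx)
        coef = cov @ (X * w[:, None]).T @ y
        resid = y - X @ coef
        q = float(np.sum(w * resid**2))
        dof = n - k_eff
        scale = 1.0
        if dof > 0:
            if self.effects_model == "random":
                scale = max(1.0, np.sqrt(q / dof))
            q_pval = float(stats.chi2.sf(q, dof))
        else:
            q_pval = float("nan")
        se = np.sqrt(np.diag(cov)) * scale
        se[zero_cols] = np.inf
        self.coef_ = coef
        self.se_ = se
        self.scale_ = float(scale)
        self.q_ = q
        self.q_pval_ = q_pval
        self.n_snp_ = n
        self.dof_ = dof
        z = np.zeros_like(coef)
        pos = se > 0
        z[pos] = coef[pos] / se[pos]
        z[~pos] = np.sign(coef[~pos]) * np.inf
        self.pval_ = 2.0 * stats.norm.sf(np.abs(z))
        self.ci_low_ = coef - _Z95 * se
        self.ci_high_ = coef + _Z95 * se
        return self

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.coef_


class EggerEstimator(RegressorMixin, BaseEstimator):
    """MR-Egger: weighted regression of outcome on exposure betas *with* intercept.

    The intercept estimates the average directional pleiotropic effect; a
    nonzero intercept flags violation of the no-pleiotropy assumption.  The
    slope is a pleiotropy-corrected causal effect under InSIDE (instrument
    strength independent of direct effects).  Exposure betas are oriented
    nonnegative before fitting (flipping the sign of both members of each
    SNP pair), the conventional identifiability constraint.  Inference uses
    the t distribution with n - 2 degrees of freedom and the same
    multiplicative random-effects floor as IVW.
    """

    def __init__(self, effects_model: str = "random"):
        self.effects_model = effects_model

    def fit(self, X, y, y_se=None):
        if y_se is None:
            raise ValueError("y_se (outcome standard errors) is required")
        X, y, y_se = _as_xy(X, y, y_se)
        if X.shape[1] != 1:
            raise ValueError("MR-Egger is a single-exposure method")
        x = X[:, 0]
        n = x.size
        if n < 3:
            raise ValueError(f"MR-Egger needs >= 3 instruments, got {n}")
        sign = np.where(x < 0, -1.0, 1.0)
        x, y = x * sign, y * sign
        w = 1.0 / y_se**2
        D = np.column_stack([np.ones(n), x])
        dtwd = (D * w[:, None]).T @ D
        cov = np.linalg.inv(dtwd)
        coef = cov @ (D * w[:, None]).T @ y
        resid = y - D @ coef
        q = float(np.sum(w * resid**2))
        dof = n - 2
        scale = 1.0
        if self.effects_model == "random":
            scale = max(1.0, np.sqrt(q / dof))
        se = np.sqrt(np.diag(cov)) * scale
        tq = float(stats.t.ppf(0.975, dof))
        self.intercept_, self.coef_ = float(coef[0]), coef[1:]
        self.intercept_se_, self.se_ = float(se[0]), se[1:]
        self.scale_ = float(scale)
        self.q_ = q
        self.q_pval_ = float(stats.chi2.sf(q, dof))
        self.n_snp_ = n
        self.dof_ = dof
        tvals = coef / se
        pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
        self.intercept_pval_ = float(pvals[0])
        self.pval_ = pvals[1:]
        self.ci_low_ = coef[1:] - tq * se[1:]
        self.ci_high_ = coef[1:] + tq * se[1:]
        return self

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.intercept_ + X @ self.coef_


def _wald_ratios(bx, by, sx, sy):
    """Per-SNP ratio estimates and their (second-order) variances."""
    ratio = by / bx
    var = sy**2 / bx**2 + by**2 * sx**2 / bx**4
    return ratio, var


def _weighted_median(ratio, weight):
    """Weight-0.5 crossing of the ordered ratios, linearly interpolated."""
    order = np.argsort(ratio)
    r = ratio[order]
    w = weight[order] / weight.sum()
    # cumulative weight at each ratio's centre of mass
    cum = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, cum, r))


class WeightedMedianEstimator(BaseEstimator):
    """Weighted-median MR estimator.

    Orders the per-SNP Wald ratios and takes the value at which the
    cumulative inverse-variance weight crosses one half (linear interpolation
    between bracketing ratios).  Consistent when valid instruments carry at
    least half the total weight.  The standard error comes from a seeded
    parametric bootstrap that redraws exposure and outcome betas from their
    sampling distributions.  ``weighted=False`` gives the simple median
    (equal weights).
    """

    def __init__(self, weighted: bool = True, n_boot: int = 1000, seed: int = 0):
        self.weighted = weighted
        self.n_boot = n_boot
        self.seed = seed

    def fit(self, X, y, y_se=None, x_se=None):
        if y_se is None or x_se is None:
            raise ValueError("both x_se and y_se are required")
        X, y, y_se = _as_xy(X, y, y_se)
        if X.shape[1] != 1:
            raise ValueError("weighted median is a single-exposure method")
        bx = X[:, 0]
        sx = np.asarray(x_se, dtype=float).ravel()
        n = bx.size
        if n < 3:
            raise ValueError(f"weighted median needs >= 3 instruments, got {n}")
        ratio, var = _wald_ratios(bx, y, sx, y_se)
        w = 1.0 / var if self.weighted else np.ones(n)
        est = _weighted_median(ratio, w)
        rng = np.random.default_rng(self.seed)
        bxs = rng.normal(bx, sx, size=(self.n_boot, n))
        bys = rng.normal(y, y_se, size=(self.n_boot, n))
        boots = np.empty(self.n_boot)
        for b in range(self.n_boot):
            rb, vb = _wald_ratios(bxs[b], bys[b], sx, y_se)
            wb = 1.0 / vb if self.weighted else np.ones(n)
            boots[b] = _weighted_median(rb, wb)
        se = float(boots.std(ddof=1))
        self.coef_ = np.array([est])
        self.se_ = np.array([se])
        self.n_snp_ = n
        z = est / se if se > 0 else np.inf * np.sign(est)
        self.pval_ = np.array([2.0 * stats.norm.sf(abs(z))])
        self.ci_low_ = self.coef_ - _Z95 * self.se_
        self.ci_high_ = self.coef_ + _Z95 * self.se_
        return self


def _mode_bandwidth(ratio, factor):
    """Modified Silverman rule, robustified with the MAD."""
    n = ratio.size
    s = np.std(ratio, ddof=1)
    mad = stats.median_abs_deviation(ratio, scale="normal")
    disp = min(s, mad) if mad > 0 else s
    if disp == 0:
        return 0.0
    return factor * 0.9 * disp * n ** (-1.0 / 5.0)


def _mode_estimate(ratio, weight, h):
    """Argmax of the weighted normal-kernel density of the ratios."""
    if h == 0 or np.ptp(ratio) == 0:
        # degenerate: all ratios identical (or zero dispersion)
        return float(np.average(ratio, weights=weight))
    w = weight / weight.sum()

    def neg_density(t):
        return -np.sum(w * np.exp(-0.5 * ((t - ratio) / h) ** 2))

    grid = np.linspace(ratio.min() - h, ratio.max() + h, 512)
    dens = (w[None, :] * np.exp(-0.5 * ((grid[:, None] - ratio[None, :]) / h) ** 2)).sum(axis=1)
    i = int(np.argmax(dens))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    res = optimize.minimize_scalar(neg_density, bounds=(lo, hi), method="bounded")
    return float(res.x)


class ModeEstimator(BaseEstimator):
    """Mode-based MR estimator (simple or weighted).

    Smooths the empirical density of per-SNP Wald ratios with a normal
    kernel (bandwidth = ``bandwidth_factor`` x a MAD-robustified Silverman
    rule) and returns the density argmax.  Consistent when the largest group
    of instruments sharing the same ratio is the valid one (ZEMPA).  The
    weighted variant weights each ratio by its inverse variance.  SEs by
    seeded parametric bootstrap.
    """

    def __init__(
        self,
        weighted: bool = True,
        bandwidth_factor: float = 1.0,
        n_boot: int = 1000,
        seed: int = 0,
    ):
        self.weighted = weighted
        self.bandwidth_factor = bandwidth_factor
        self.n_boot = n_boot
        self.seed = seed

    def fit(self, X, y, y_se=None, x_se=None):
        if y_se is None or x_se is None:
            raise ValueError("both x_se and y_se are required")
        X, y, y_se = _as_xy(X, y, y_se)
        if X.shape[1] != 1:
            raise ValueError("mode estimator is a single-exposure method")
        bx = X[:, 0]
        sx = np.asarray(x_se, dtype=float).ravel()
        n = bx.size
        if n < 3:
            raise ValueError(f"mode estimator needs >= 3 instruments, got {n}")
        ratio, var = _wald_ratios(bx, y, sx, y_se)
        w = 1.0 / var if self.weighted else np.ones(n)
        h = _mode_bandwidth(ratio, self.bandwidth_factor)
        est = _mode_estimate(ratio, w, h)
        rng = np.random.default_rng(self.seed)
        bxs = rng.normal(bx, sx, size=(self.n_boot, n))
        bys = rng.normal(y, y_se, size=(self.n_boot, n))
        boots = np.empty(self.n_boot)
        for b in range(self.n_boot):
            rb, vb = _wald_ratios(bxs[b], bys[b], sx, y_se)
            wb = 1.0 / vb if self.weighted else np.ones(n)
            boots[b] = _mode_estimate(rb, wb, _mode_bandwidth(rb, self.bandwidth_factor))
        se = float(boots.std(ddof=1))
        self.coef_ = np.array([est])
        self.se_ = np.array([se])
        self.bandwidth_ = h
        self.n_snp_ = n
        z = est / se if se > 0 else np.inf * np.sign(est) if est else 0.0
        self.pval_ = np.array([2.0 * stats.norm.sf(abs(z))])
        self.ci_low_ = self.coef_ - _Z95 * self.se_
        self.ci_high_ = self.coef_ + _Z95 * self.se_
        return self


# ---------------------------------------------------------------------------
# HarmonizedSet-level wrappers


def wald_ratio(h: HarmonizedSet) -> MREstimate:
    """Single-SNP causal estimate: beta_out / beta_exp, first-order SE."""
    if h.n_snp != 1:
        raise ValueError(f"wald_ratio needs exactly one SNP, got {h.n_snp}")
    bx, by, sy = float(h.beta_exp[0]), float(h.beta_out[0]), float(h.se_out[0])
    if bx == 0:
        raise ValueError("exposure beta is zero; Wald ratio undefined")
    beta = by / bx
    se = sy / abs(bx)
    z = beta / se
    return MREstimate(
        method="wald_ratio",
        beta=beta,
        se=se,
        ci_low=beta - _Z95 * se,
        ci_high=beta + _Z95 * se,
        pval=float(2 * stats.norm.sf(abs(z))),
        n_snp=1,
        outcome_type=h.outcome_type,
    )


def ivw(h: HarmonizedSet, effects_model: str = "random") -> MREstimate:
    """Inverse-variance-weighted estimate over all kept instruments."""
    if h.n_snp == 1:
        # exact reduction: one instrument's IVW is its Wald ratio
        est = wald_ratio(h)
        est.method = f"ivw_{effects_model}"
        est.q, est.q_pval = 0.0, float("nan")
        return est
    est = IVWEstimator(effects_model=effects_model).fit(
        h.beta_exp[:, None], h.beta_out, y_se=h.se_out
    )
    return MREstimate(
        method=f"ivw_{effects_model}",
        beta=float(est.coef_[0]),
        se=float(est.se_[0]),
        ci_low=float(est.ci_low_[0]),
        ci_high=float(est.ci_high_[0]),
        pval=float(est.pval_[0]),
        n_snp=est.n_snp_,
        q=est.q_,
        q_pval=est.q_pval_,
        outcome_type=h.outcome_type,
    )


def egger(h: HarmonizedSet, effects_model: str = "random") -> MREstimate:
    """MR-Egger slope with the intercept reported as a pleiotropy test."""
    est = EggerEstimator(effects_model=effects_model).fit(
        h.beta_exp[:, None], h.beta_out, y_se=h.se_out
    )
    return MREstimate(
        method="egger",
        beta=float(est.coef_[0]),
        se=float(est.se_[0]),
        ci_low=float(est.ci_low_[0]),
        ci_high=float(est.ci_high_[0]),
        pval=float(est.pval_[0]),
        n_snp=est.n_snp_,
        q=est.q_,
        q_pval=est.q_pval_,
        egger_intercept=est.intercept_,
        egger_intercept_se=est.intercept_se_,
        egger_intercept_pval=est.intercept_pval_,
        outcome_type=h.outcome_type,
    )


def weighted_median(h: HarmonizedSet, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    est = WeightedMedianEstimator(weighted=True, n_boot=n_boot, seed=seed).fit(
        h.beta_exp[:, None], h.beta_out, y_se=h.se_out, x_se=h.se_exp
    )
    return MREstimate(
        method="weighted_median",
        beta=float(est.coef_[0]),
        se=float(est.se_[0]),
        ci_low=float(est.ci_low_[0]),
        ci_high=float(est.ci_high_[0]),
        pval=float(est.pval_[0]),
        n_snp=est.n_snp_,
        outcome_type=h.outcome_type,
    )


def mode_based(
    h: HarmonizedSet,
    weighted: bool = True,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    est = ModeEstimator(
        weighted=weighted, bandwidth_factor=bandwidth_factor, n_boot=n_boot, seed=seed
    ).fit(h.beta_exp[:, None], h.beta_out, y_se=h.se_out, x_se=h.se_exp)
    return MREstimate(
        method="weighted_mode" if weighted else "simple_mode",
        beta=float(est.coef_[0]),
        se=float(est.se_[0]),
        ci_low=float(est.ci_low_[0]),
        ci_high=float(est.ci_high_[0]),
        pval=float(est.pval_[0]),
        n_snp=est.n_snp_,
        outcome_type=h.outcome_type,
    )


BATTERY_METHODS = ("ivw_random", "egger", "weighted_median", "simple_mode", "weighted_mode")


def run_method_battery(
    h: HarmonizedSet, seed: int = 0, n_boot: int = 1000
) -> list[MREstimate]:
    """The five-method sensitivity battery on one harmonized set.

    Returns, in fixed order: random-effects IVW, MR-Egger, weighted median,
    simple mode, weighted mode.  Deterministic given ``seed``.
    """
    if h.n_snp < 3:
        need3 = [m for m in BATTERY_METHODS if m != "ivw_random"]
        raise ValueError(
            f"{h.n_snp} instrument(s): methods requiring >= 3 SNPs cannot run: {need3}"
        )
    ss = np.random.SeedSequence(seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    return [
        ivw(h, "random"),
        egger(h),
        weighted_median(h, n_boot=n_boot, seed=seeds[0]),
        mode_based(h, weighted=False, n_boot=n_boot, seed=seeds[1]),
        mode_based(h, weighted=True, n_boot=n_boot, seed=seeds[2]),
    ]


@dataclass
class BidirectionalResult:
    """IVW estimates in both directions between two traits."""

    forward: MREstimate | None
    reverse: MREstimate | None
    notes: list[str] = field(default_factory=list)


def bidirectional_check(
    a,
    b,
    ld=None,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.001,
    palindromic_eaf_window: float = 0.08,
    effects_model: str = "random",
) -> BidirectionalResult:
    """Run the select -> clump -> harmonize -> IVW pipeline in both directions.

    A direction with no genome-wide-significant instruments is flagged
    untestable (``None`` estimate plus a note) rather than raising.
    """
    from .instruments import harmonize, ld_clump, select_instruments

    notes: list[str] = []
    results: list[MREstimate | None] = []
    for exp, out in ((a, b), (b, a)):
        inst = select_instruments(exp, p_threshold)
        if len(inst) == 0:
            notes.append(f"{exp.trait_id} -> {out.trait_id}: no instruments, untestable")
            results.append(None)
            continue
        if ld is not None:
            inst = ld_clump(inst, ld, r2_threshold)
        h = harmonize(inst, out, palindromic_eaf_window)
        results.append(ivw(h, effects_model))
    if a.trait_id == b.trait_id:
        notes.append("degenerate self-test: both directions compare a trait with itself")
    return BidirectionalResult(forward=results[0], reverse=results[1], notes=notes)
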