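"""Multivariable MR and the two-step mediation decomposition.

The two-step design quantifies how much of an exposure's effect on a binary
outcome travels through a candidate mediator, using only GWAS summary
statistics:

* **total effect** — univariable IVW of the outcome on the exposure's
  instruments (log-odds per exposure unit);
* **step 1** (``beta1``) — univariable IVW of each mediator on the same
  instruments (mediator SD per exposure unit), screened with a Bonferroni
  threshold across the candidate mediators;
* **step 2** (``beta2``) — multivariable IVW of the outcome on the exposure
  *and* the mediator jointly, giving the mediator's direct log-odds effect
  conditional on the exposure, screened at nominal alpha;
* **indirect effect** — the product ``beta1 * beta2`` with a delta-method
  (Gaussian error-propagation) standard error, and the **proportion
  mediated** ``indirect / total``, again with delta-method uncertainty
  assuming independence of numerator and denominator.

Everything is on the log-odds scale; proportions are reported as
percentages at presentation time.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import IVWEstimator, MREstimate, ivw, run_method_battery
from .instruments import (
    HarmonizedSet,
    MultiHarmonizedSet,
    harmonize,
    harmonize_multi,
    ld_clump,
    make_instrument_set,
    select_instruments,
)
from .sumstats import LDMatrix, SummaryStatSet

logger = logging.getLogger(__name__)

__all__ = [
    "MVMREstimate",
    "MediationResult",
    "ScreeningDecision",
    "MediationConfig",
    "MediationReport",
    "Estimate",
    "mvmr_ivw",
    "propagate_se",
    "mediation_effect",
    "screen_mediators",
    "run_mediation_analysis",
]

_Z95 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class Estimate:
    """A point estimate with its standard error."""

    value: float
    se: float

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("se must be nonnegative")

    @classmethod
    def of(cls, x) -> "Estimate":
        if isinstance(x, Estimate):
            return x
        if isinstance(x, MREstimate):
            return cls(x.beta, x.se)
        value, se = x
        return cls(float(value), float(se))


def propagate_se(op: str, a, b) -> Estimate:
    """First-order Gaussian error propagation for +, -, x, / of two estimates.

    Inputs are independent; each is ``(value, se)`` (or an :class:`Estimate`
    or :class:`~mrmediate.estimators.MREstimate`).

    * add/subtract: ``se = sqrt(se_a^2 + se_b^2)``
    * multiply:     ``se = sqrt(b^2 se_a^2 + a^2 se_b^2)``
    * divide:       ``se = |a/b| sqrt((se_a/a)^2 + (se_b/b)^2)``; the a = 0
      limit is handled as ``se = se_a / |b|``
    """
    a, b = Estimate.of(a), Estimate.of(b)
    if op == "add":
        return Estimate(a.value + b.value, math.hypot(a.se, b.se))
    if op == "subtract":
        return Estimate(a.value - b.value, math.hypot(a.se, b.se))
    if op == "multiply":
        se = math.sqrt(b.value**2 * a.se**2 + a.value**2 * b.se**2)
        return Estimate(a.value * b.value, se)
    if op == "divide":
        if b.value == 0:
            raise ZeroDivisionError("cannot propagate through division by zero")
        if a.value == 0:
            return Estimate(0.0, a.se / abs(b.value))
        ratio = a.value / b.value
        se = abs(ratio) * math.hypot(a.se / a.value, b.se / b.value)
        return Estimate(ratio, se)
    raise ValueError(f"unknown op {op!r}; expected add/subtract/multiply/divide")


@dataclass
class MVMREstimate:
    """Per-exposure direct effects from a multivariable IVW fit."""

    exposure_ids: list[str]
    betas: np.ndarray
    ses: np.ndarray
    pvals: np.ndarray
    n_snp: int
    q: float | None = None
    q_pval: float | None = None
    outcome_type: str = "binary"

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        self.ses = np.asarray(self.ses, dtype=float)
        self.pvals = np.asarray(self.pvals, dtype=float)
        k = len(self.exposure_ids)
        if not (self.betas.shape == self.ses.shape == self.pvals.shape == (k,)):
            raise ValueError("betas/ses/pvals must align with exposure_ids")
        if (self.ses <= 0).any():
            raise ValueError("ses must be strictly positive")

    def for_exposure(self, exposure_id: str) -> Estimate:
        i = self.exposure_ids.index(exposure_id)
        return Estimate(float(self.betas[i]), float(self.ses[i]))

    def pval_for(self, exposure_id: str) -> float:
        return float(self.pvals[self.exposure_ids.index(exposure_id)])

    def to_dict(self) -> dict:
        return {
            "exposure_ids": list(self.exposure_ids),
            "betas": self.betas.tolist(),
            "ses": self.ses.tolist(),
            "pvals": self.pvals.tolist(),
            "n_snp": self.n_snp,
            "q": self.q,
            "q_pval": self.q_pval,
        }


def mvmr_ivw(h: MultiHarmonizedSet, effects_model: str = "random") -> MVMREstimate:
    """Multivariable IVW: outcome betas regressed on the exposure-beta matrix.

    Zero-intercept weighted least squares with weights ``1/se_out^2``;
    per-exposure SEs from the weighted normal-equations covariance with
    multiplicative random-effects scaling (floored at 1).
    """
    k = len(h.exposure_ids)
    if h.n_snp < k + 1:
        raise ValueError(f"{h.n_snp} instruments too few for {k} exposures")
    est = IVWEstimator(effects_model=effects_model).fit(h.beta_exp, h.beta_out, y_se=h.se_out)
    return MVMREstimate(
        exposure_ids=list(h.exposure_ids),
        betas=est.coef_,
        ses=est.se_,
        pvals=est.pval_,
        n_snp=est.n_snp_,
        q=est.q_,
        q_pval=est.q_pval_,
        outcome_type=h.outcome_type,
    )


@dataclass
class MediationResult:
    """Product-of-coefficients decomposition for one mediator.

    All effects are log odds (or mediator SD for step 1); ``proportion`` is
    the indirect effect divided by the *total* effect — every mediator's
    proportion shares the same denominator.  The delta-method SE for the
    proportion assumes indirect and total are independent
    (``independence_assumed``), stated rather than hidden because the two
    share the outcome sample.
    """

    mediator_id: str
    step1_beta: float
    step1_se: float
    step2_beta: float
    step2_se: float
    total_beta: float
    total_se: float
    indirect_beta: float
    indirect_se: float
    proportion: float
    proportion_se: float
    proportion_ci: tuple[float, float]
    indirect_ci: tuple[float, float]
    pval: float
    independence_assumed: bool = True

    @property
    def proportion_pct(self) -> float:
        return 100.0 * self.proportion

    @property
    def indirect_pct(self) -> float:
        """Indirect (mediation) effect x 100, the scale of headline tables."""
        return 100.0 * self.indirect_beta

    def to_dict(self) -> dict:
        return {
            "mediator_id": self.mediator_id,
            "step1_beta": self.step1_beta,
            "step1_se": self.step1_se,
            "step2_beta": self.step2_beta,
            "step2_se": self.step2_se,
            "total_beta": self.total_beta,
            "total_se": self.total_se,
            "indirect_beta": self.indirect_beta,
            "indirect_se": self.indirect_se,
            "indirect_ci": list(self.indirect_ci),
            "proportion": self.proportion,
            "proportion_se": self.proportion_se,
            "proportion_ci": list(self.proportion_ci),
            "pval": self.pval,
            "independence_assumed": self.independence_assumed,
        }


def mediation_effect(step1, step2, total, mediator_id: str = "") -> MediationResult:
    """Indirect effect and proportion mediated from the three fitted effects.

    ``indirect = step1 x step2`` with the multiplication propagation rule;
    ``proportion = indirect / total`` with the division rule (independence
    assumed); 95% CIs are +/- 1.96 SE on each scale and the indirect-effect
    p-value is a two-sided normal z test.
    """
    s1, s2, tot = Estimate.of(step1), Estimate.of(step2), Estimate.of(total)
    if tot.value == 0:
        raise ZeroDivisionError("total effect is zero; proportion undefined")
    indirect = propagate_se("multiply", s1, s2)
    proportion = propagate_se("divide", indirect, tot)
    if indirect.se > 0:
        z = indirect.value / indirect.se
        pval = float(2 * stats.norm.sf(abs(z)))
    else:
        pval = 0.0 if indirect.value != 0 else 1.0
    if not 0.0 <= proportion.value <= 1.0:
        logger.warning(
            "proportion mediated for %s is %.3f (outside [0,1]); reported as computed",
            mediator_id or "<mediator>",
            proportion.value,
        )
    return MediationResult(
        mediator_id=mediator_id,
        step1_beta=s1.value,
        step1_se=s1.se,
        step2_beta=s2.value,
        step2_se=s2.se,
        total_beta=tot.value,
        total_se=tot.se,
        indirect_beta=indirect.value,
        indirect_se=indirect.se,
        proportion=proportion.value,
        proportion_se=proportion.se,
        proportion_ci=(
            proportion.value - _Z95 * proportion.se,
            proportion.value + _Z95 * proportion.se,
        ),
        indirect_ci=(
            indirect.value - _Z95 * indirect.se,
            indirect.value + _Z95 * indirect.se,
        ),
        pval=pval,
    )


@dataclass
class ScreeningDecision:
    """Whether one candidate mediator enters the mediation decomposition.

    Step 1 (exposure -> mediator) is judged against the Bonferroni-corrected
    threshold ``alpha / m``; step 2 (mediator -> outcome given exposure)
    against nominal ``alpha``.  ``included`` is the conjunction.
    """

    mediator_id: str
    step1_p: float
    step1_threshold: float
    step2_p: float
    step2_threshold: float

    @property
    def step1_pass(self) -> bool:
        return self.step1_p < self.step1_threshold

    @property
    def step2_pass(self) -> bool:
        return self.step2_p < self.step2_threshold

    @property
    def included(self) -> bool:
        return self.step1_pass and self.step2_pass

    @property
    def exclusion_reason(self) -> str | None:
        if self.included:
            return None
        reasons = []
        if not self.step1_pass:
            reasons.append(
                f"step1 p={self.step1_p:.3g} >= Bonferroni {self.step1_threshold:.3g}"
            )
        if not self.step2_pass:
            reasons.append(f"step2 p={self.step2_p:.3g} >= alpha {self.step2_threshold:.3g}")
        return "; ".join(reasons)

    def to_dict(self) -> dict:
        return {
            "mediator_id": self.mediator_id,
            "step1_p": self.step1_p,
            "step1_threshold": self.step1_threshold,
            "step1_pass": self.step1_pass,
            "step2_p": self.step2_p,
            "step2_threshold": self.step2_threshold,
            "step2_pass": self.step2_pass,
            "included": self.included,
            "exclusion_reason": self.exclusion_reason,
        }


def screen_mediators(
    step1_pvals: Mapping[str, float],
    step2_pvals: Mapping[str, float],
    alpha: float = 0.05,
    m: int | None = None,
) -> list[ScreeningDecision]:
    """Two-stage mediator screen.

    ``step1_pvals``/``step2_pvals`` map mediator ids to the exposure->mediator
    and adjusted mediator->outcome p-values (p-values may also be given as
    MREstimate/MVMREstimate-bearing floats upstream).  ``m`` defaults to the
    number of candidate mediators.
    """
    if set(step1_pvals) != set(step2_pvals):
        raise ValueError(
            f"mediator ids differ between steps: {sorted(set(step1_pvals) ^ set(step2_pvals))}"
        )
    m = m if m is not None else len(step1_pvals)
    thr1 = alpha / m if m else alpha
    return [
        ScreeningDecision(
            mediator_id=k,
            step1_p=float(step1_pvals[k]),
            step1_threshold=thr1,
            step2_p=float(step2_pvals[k]),
            step2_threshold=alpha,
        )
        for k in step1_pvals
    ]


@dataclass
class MediationConfig:
    """Tuning knobs of the two-step analysis (defaults follow MR convention)."""

    p_threshold: float = 5e-8
    r2_threshold: float = 0.001
    f_threshold: float = 10.0
    palindromic_window: float = 0.08
    alpha: float = 0.05
    bonferroni_m: int | None = None
    effects_model: str = "random"
    run_battery: bool = True
    n_boot: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold <= 1:
            raise ValueError("p_threshold must be in (0,1]")
        if not 0 <= self.r2_threshold <= 1:
            raise ValueError("r2_threshold must be in [0,1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        if self.f_threshold < 0:
            raise ValueError("f_threshold must be nonnegative")
        if not 0 <= self.palindromic_window <= 0.5:
            raise ValueError("palindromic_window must be in [0,0.5]")


@dataclass
class MediationReport:
    """Everything the two-step analysis produced, serializable to JSON/TSV."""

    exposure_id: str
    outcome_id: str
    total: MREstimate
    step1: dict[str, MREstimate]
    step2: dict[str, MVMREstimate]
    screening: list[ScreeningDecision]
    results: list[MediationResult]
    battery: dict[str, list[MREstimate]] = field(default_factory=dict)
    instrument_counts: dict[str, int] = field(default_factory=dict)
    total_pve: float | None = None
    min_f: float | None = None
    config: MediationConfig = field(default_factory=MediationConfig)

    def mediation_table(self) -> pd.DataFrame:
        """Headline table: one row per included mediator, percent scale."""
        rows = []
        for r in self.results:
            rows.append(
                {
                    "mediator": r.mediator_id,
                    "mediation_effect_pct": r.indirect_pct,
                    "proportion_of_total_pct": r.proportion_pct,
                    "proportion_ci_low_pct": 100 * r.proportion_ci[0],
                    "proportion_ci_high_pct": 100 * r.proportion_ci[1],
                    "pval": r.pval,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "mediator",
                "mediation_effect_pct",
                "proportion_of_total_pct",
                "proportion_ci_low_pct",
                "proportion_ci_high_pct",
                "pval",
            ],
        )

    def to_dict(self) -> dict:
        return {
            "exposure": self.exposure_id,
            "outcome": self.outcome_id,
            "config": {
                k: getattr(self.config, k)
                for k in (
                    "p_threshold",
                    "r2_threshold",
                    "f_threshold",
                    "palindromic_window",
                    "alpha",
                    "bonferroni_m",
                    "effects_model",
                    "n_boot",
                    "seed",
                )
            },
            "instrument_counts": self.instrument_counts,
            "total_pve": self.total_pve,
            "min_f": self.min_f,
            "total_effect": self.total.to_dict(),
            "step1": {k: v.to_dict() for k, v in self.step1.items()},
            "step2": {k: v.to_dict() for k, v in self.step2.items()},
            "screening": [s.to_dict() for s in self.screening],
            "mediation": [r.to_dict() for r in self.results],
            "battery": {
                k: [e.to_dict() for e in v] for k, v in self.battery.items()
            },
        }


def run_mediation_analysis(
    exposure: SummaryStatSet,
    mediators: Mapping[str, SummaryStatSet],
    outcome: SummaryStatSet,
    ld: LDMatrix | None = None,
    config: MediationConfig | None = None,
) -> MediationReport:
    """The full two-step, two-sample MR mediation pipeline.

    Select and clump exposure instruments, estimate the total effect
    (exposure -> outcome, IVW), each step-1 effect (exposure -> mediator,
    IVW, Bonferroni screen), each step-2 direct effect (multivariable IVW of
    the outcome on exposure + one mediator at a time over the union of both
    traits' instruments), screen, and decompose for every surviving
    mediator.  Optionally runs the five-method sensitivity battery on the
    total-effect and step-1 sets.
    """
    cfg = config or MediationConfig()
    inst = make_instrument_set(
        exposure,
        p_threshold=cfg.p_threshold,
        ld=ld,
        r2_threshold=cfg.r2_threshold,
        f_threshold=cfg.f_threshold,
    )
    if len(inst.records) == 0:
        raise ValueError(
            f"no instruments for {exposure.trait_id} at p < {cfg.p_threshold:g}"
        )
    counts = dict(inst.counts)

    h_total = harmonize(inst.records, outcome, cfg.palindromic_window)
    total = ivw(h_total, cfg.effects_model)
    counts["total_effect_snps"] = total.n_snp

    step1: dict[str, MREstimate] = {}
    step2: dict[str, MVMREstimate] = {}
    battery: dict[str, list[MREstimate]] = {}
    if cfg.run_battery and h_total.n_snp >= 3:
        battery["total"] = run_method_battery(h_total, seed=cfg.seed, n_boot=cfg.n_boot)

    for name, med in mediators.items():
        h1 = harmonize(inst.records, med, cfg.palindromic_window)
        step1[name] = ivw(h1, cfg.effects_model)
        counts[f"step1_snps_{name}"] = step1[name].n_snp
        if cfg.run_battery and h1.n_snp >= 3:
            battery[f"step1_{name}"] = run_method_battery(
                h1, seed=cfg.seed + 1, n_boot=cfg.n_boot
            )
        # step 2: MVMR over the union of exposure and mediator instruments
        med_inst = select_instruments(med, cfg.p_threshold)
        union_ids = set(inst.records.snp_ids) | set(med_inst.snp_ids)
        exp_union = exposure.subset(union_ids)
        if ld is not None and len(exp_union) > len(inst.records):
            exp_union = ld_clump(exp_union, ld, cfg.r2_threshold)
        h2 = harmonize_multi(
            {exposure.trait_id: exp_union, name: med},
            outcome,
            palindromic_eaf_window=cfg.palindromic_window,
        )
        step2[name] = mvmr_ivw(h2, cfg.effects_model)
        counts[f"step2_snps_{name}"] = step2[name].n_snp

    screening = screen_mediators(
        {k: v.pval for k, v in step1.items()},
        {k: v.pval_for(k) for k, v in step2.items()},
        alpha=cfg.alpha,
        m=cfg.bonferroni_m,
    )
    results = []
    for dec in screening:
        if not dec.included:
            logger.info("mediator %s excluded: %s", dec.mediator_id, dec.exclusion_reason)
            continue
        name = dec.mediator_id
        results.append(
            mediation_effect(
                step1[name],
                step2[name].for_exposure(name),
                total,
                mediator_id=name,
            )
        )
    if not results:
        logger.warning("no mediators survive screening; mediation table is empty")
    return MediationReport(
        exposure_id=exposure.trait_id,
        outcome_id=outcome.trait_id,
        total=total,
        step1=step1,
        step2=step2,
        screening=screening,
        results=results,
        battery=battery,
        instrument_counts=counts,
        total_pve=inst.total_pve if inst.pve else None,
        min_f=inst.min_f,
        config=cfg,
    )
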