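"""Synthetic two-sample GWAS summary statistics with known causal structure.

The generator draws individual-level data from an explicit structural model

* exposure  ``X = G @ gamma + c_x U + eps_x``
* mediators ``M_k = alpha_k X + G @ delta_k + c_m U + eps_k``
* outcome   ``Y ~ Bernoulli(expit(b0 + theta X + sum_k phi_k M_k + c_y U + G @ pi))``

with independent biallelic SNP dosages ``G`` (binomial(2, maf)), a shared
standard-normal confounder ``U``, mediator-specific genetic effects
``delta_k`` and instrument-invalidating direct SNP->outcome effects ``pi``
(drawn at ``pleiotropy_sd``; zero means all instruments are valid).

The SNP panel mirrors real trait architectures: the first ``n_snps``
variants affect the exposure (``gamma``), and each mediator additionally
has ``n_mediator_snps`` variants of its own (``delta_k``), disjoint from
the exposure's.  Mediator-specific variants reach the outcome only through
the mediator (vertical pleiotropy), so they are exactly the instruments
multivariable MR needs to separate the mediator's direct effect from the
exposure's.
Quantitative traits are standardized to unit variance, so ``theta``,
``alpha`` and ``phi`` live on the analysis scale and the ground-truth
mediation quantities follow directly from the configuration::

    total        = theta + sum_k alpha_k phi_k      (log odds)
    indirect_k   = alpha_k phi_k
    proportion_k = indirect_k / total

The outcome model is logistic, matching odds-ratio reporting; because log
odds are non-collapsible these truths are first-order approximations for
large effects, which is recorded as a flag plus a ``truth_tolerance``.

Individuals are split into disjoint cohorts (one per GWAS, plus an LD
reference sample), so the emitted summary statistics genuinely come from
non-overlapping samples, as a two-sample design requires.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats
from scipy.special import expit, logit

from .sumstats import (
    LDMatrix,
    SummaryStatSet,
    VariantAssociation,
    write_ld_matrix,
    write_sumstats,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "simulate_genotypes",
    "simulate_traits",
    "compute_sumstats",
    "simulate_study",
    "ld_from_genotypes",
]

_TINY_P = float(np.nextafter(0.0, 1.0))


@dataclass
class SimulationConfig:
    """Ground-truth parameters for one synthetic two-sample study.

    Defaults mirror the scale of a UK-Biobank-style obesity/gallstone
    analysis at desk size: dozens of independent genome-wide-significant
    instruments, a binary outcome with case fraction ~= 0.0775, a total
    effect of 0.70 log odds (odds ratio ~= 2.0) of which 10% travels through
    a single quantitative mediator, and cohorts of 2 x 10^4.
    """

    n_snps: int = 50
    maf_range: tuple[float, float] = (0.05, 0.5)
    #: cohort sizes: exposure GWAS, each mediator GWAS, outcome GWAS
    n_per_cohort: tuple[int, int, int] = (20_000, 20_000, 20_000)
    #: sd of per-SNP effects on the exposure
    gamma_sd: float = 0.08
    #: exposure -> mediator effect, one entry per mediator (SD units)
    alpha: tuple[float, ...] = (0.25,)
    #: direct exposure -> outcome effect (log odds)
    theta: float = 0.63
    #: mediator -> outcome effect per mediator (log odds)
    phi: tuple[float, ...] = (0.28,)
    #: per-mediator count of mediator-specific SNPs (disjoint from the
    #: exposure's instruments)
    n_mediator_snps: int = 25
    #: sd of mediator-specific SNP effects (the mediator's own genetics)
    delta_sd: float = 0.08
    #: sd of direct SNP -> outcome effects; 0 = all instruments valid
    pleiotropy_sd: float = 0.0
    #: shared-confounder loadings on exposure, mediators, outcome logit
    confounder_strength: tuple[float, float, float] = (0.3, 0.3, 0.2)
    #: outcome intercept on the probability scale
    base_prevalence: float = 0.0775
    #: held-out sample size for estimating the LD matrix
    n_ld: int = 20_000
    #: optional correlated-genotype mode: SNPs in blocks of this size get
    #: AR(1) haplotype correlation ``ld_block_rho`` (None = independent SNPs)
    ld_block_size: int | None = None
    ld_block_rho: float = 0.0
    mediator_names: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if len(self.alpha) != len(self.phi):
            raise ValueError("alpha and phi must have one entry per mediator")
        if any(n <= 0 for n in self.n_per_cohort):
            raise ValueError("cohort sizes must be positive")
        if not 0.0 < self.base_prevalence < 1.0:
            raise ValueError("base_prevalence must be in (0,1)")
        if self.mediator_names is None:
            self.mediator_names = tuple(
                f"mediator_{k + 1}" for k in range(len(self.alpha))
            )
        if len(self.mediator_names) != len(self.alpha):
            raise ValueError("mediator_names must align with alpha/phi")

    @property
    def n_mediators(self) -> int:
        return len(self.alpha)

    @property
    def n_snps_total(self) -> int:
        return self.n_snps + self.n_mediators * self.n_mediator_snps

    def mediator_snp_slice(self, k: int) -> slice:
        """Panel positions of mediator ``k``'s own variants."""
        start = self.n_snps + k * self.n_mediator_snps
        return slice(start, start + self.n_mediator_snps)

    def truth(self) -> dict:
        """Ground-truth mediation quantities implied by the configuration."""
        indirect = {
            name: a * p
            for name, a, p in zip(self.mediator_names, self.alpha, self.phi)
        }
        total = self.theta + sum(indirect.values())
        return {
            "total": total,
            "indirect": indirect,
            "proportion": {
                k: (v / total if total != 0 else float("nan"))
                for k, v in indirect.items()
            },
            "logodds_approximation": True,
            "truth_tolerance": 0.04,
        }


def simulate_genotypes(
    n: int,
    mafs: np.ndarray,
    seed: int | np.random.Generator = 0,
    block_size: int | None = None,
    rho: float = 0.0,
) -> np.ndarray:
    """Biallelic SNP dosages, (n, n_snps) int8.

    Independent ``binomial(2, maf)`` draws by default.  With ``block_size``
    set, haplotypes within each consecutive block are correlated through a
    Gaussian copula with AR(1) correlation ``rho``, producing LD to exercise
    clumping; across blocks SNPs stay independent.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mafs = np.asarray(mafs, dtype=float)
    if ((mafs <= 0) | (mafs > 0.5)).any():
        raise ValueError("mafs must lie in (0, 0.5]")
    m = mafs.size
    if not block_size or rho == 0.0:
        # sum of two Bernoulli haplotypes == binomial(2, maf), but ~2x faster
        g = (rng.random(size=(n, m)) < mafs).view(np.int8)
        g += (rng.random(size=(n, m)) < mafs).view(np.int8)
        return g
    G = np.empty((n, m), dtype=np.int8)
    thresholds = stats.norm.ppf(mafs)
    for start in range(0, m, block_size):
        stop = min(start + block_size, m)
        b = stop - start
        corr = rho ** np.abs(np.subtract.outer(np.arange(b), np.arange(b)))
        chol = np.linalg.cholesky(corr)
        hap = np.zeros((n, b), dtype=np.int8)
        for _ in range(2):
            z = rng.standard_normal(size=(n, b)) @ chol.T
            hap += z < thresholds[start:stop]
        G[:, start:stop] = hap
    return G


def _standardize(x: np.ndarray) -> tuple[np.ndarray, float, float]:
    mu, sd = float(x.mean()), float(x.std())
    return (x - mu) / sd, mu, sd


def simulate_traits(
    G: np.ndarray, config: SimulationConfig, rng: np.random.Generator, mafs: np.ndarray
) -> dict:
    """Per-individual exposure, mediators and binary outcome.

    Residual variances are chosen so each quantitative trait has population
    variance 1 before the (empirical) standardization; the scaling factors
    actually applied are returned so truth parameters remain on the
    analysis scale.
    """
    n, m = G.shape
    if m != config.n_snps_total:
        raise ValueError(
            f"genotype panel has {m} SNPs; config implies {config.n_snps_total}"
        )
    c_x, c_m, c_y = config.confounder_strength
    gamma = np.zeros(m)
    gamma[: config.n_snps] = rng.normal(0.0, config.gamma_sd, size=config.n_snps)
    het = 2.0 * mafs * (1.0 - mafs)
    var_gx = float(np.sum(gamma**2 * het))
    U = rng.standard_normal(n)
    Gf = G.astype(np.float64)
    eps_sd = np.sqrt(max(1.0 - var_gx - c_x**2, 0.05))
    X_raw = Gf @ gamma + c_x * U + rng.normal(0.0, eps_sd, size=n)
    X, x_mu, x_sd = _standardize(X_raw)

    mediators = {}
    deltas = {}
    scalings = {"exposure": (x_mu, x_sd)}
    for k, (name, a) in enumerate(zip(config.mediator_names, config.alpha)):
        delta = np.zeros(m)
        delta[config.mediator_snp_slice(k)] = rng.normal(
            0.0, config.delta_sd, size=config.n_mediator_snps
        )
        var_gm = float(np.sum(delta**2 * het))
        eps_sd_m = np.sqrt(max(1.0 - a**2 - var_gm - c_m**2, 0.05))
        M_raw = a * X + Gf @ delta + c_m * U + rng.normal(0.0, eps_sd_m, size=n)
        M, m_mu, m_sd = _standardize(M_raw)
        mediators[name] = M
        deltas[name] = delta
        scalings[name] = (m_mu, m_sd)

    # direct SNP->outcome effects confined to the exposure's instruments:
    # exactly the variants whose validity the MR assumptions concern
    pi = np.zeros(m)
    if config.pleiotropy_sd > 0:
        pi[: config.n_snps] = rng.normal(0.0, config.pleiotropy_sd, size=config.n_snps)
    eta = logit(config.base_prevalence) + config.theta * X + c_y * U + Gf @ pi
    for name, p in zip(config.mediator_names, config.phi):
        eta += p * mediators[name]
    Y = (rng.random(n) < expit(eta)).astype(np.int8)
    return {
        "exposure": X,
        "mediators": mediators,
        "outcome": Y,
        "gamma": gamma,
        "deltas": deltas,
        "pi": pi,
        "scaling": scalings,
    }


def _linear_gwas(y: np.ndarray, G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form per-SNP simple linear regression (beta, se)."""
    n = y.size
    Gc = G - G.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", Gc, Gc)
    sxy = yc @ Gc
    beta = sxy / sxx
    syy = float(yc @ yc)
    resid_var = (syy - beta * sxy) / (n - 2)
    se = np.sqrt(resid_var / sxx)
    return beta, se


def _logistic_gwas(y: np.ndarray, G: np.ndarray, tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP logistic regression (intercept + dosage), vectorised Newton."""
    n, m = G.shape
    Gf = np.ascontiguousarray(G, dtype=np.float64)
    G2 = Gf * Gf
    ybar = y.mean()
    a = np.full(m, logit(ybar))
    b = np.zeros(m)
    yf = np.asarray(y, dtype=np.float64)[:, None]
    for _ in range(50):
        mu = expit(a + Gf * b)
        w = mu * (1.0 - mu)
        r = yf - mu
        u0 = r.sum(axis=0)
        u1 = np.einsum("ij,ij->j", Gf, r)
        s0 = w.sum(axis=0)
        s1 = np.einsum("ij,ij->j", Gf, w)
        s2 = np.einsum("ij,ij->j", G2, w)
        det = s0 * s2 - s1 * s1
        da = (s2 * u0 - s1 * u1) / det
        db = (s0 * u1 - s1 * u0) / det
        a += da
        b += db
        if max(np.abs(da).max(), np.abs(db).max()) < tol:
            break
    se = np.sqrt(s0 / det)
    return b, se


def compute_sumstats(
    trait: np.ndarray,
    G: np.ndarray,
    trait_type: str,
    trait_id: str,
    snp_ids: list[str] | None = None,
) -> SummaryStatSet:
    """One cohort's GWAS: per-SNP regression of the trait on each dosage.

    Simple linear regression for quantitative traits, maximum-likelihood
    logistic regression for binary traits.  Monomorphic SNPs are dropped
    with a warning; p-values that underflow are clamped to the smallest
    positive float.
    """
    trait = np.asarray(trait, dtype=float).ravel()
    n, m = G.shape
    if trait.size != n:
        raise ValueError("trait and genotype matrix disagree on sample size")
    if snp_ids is None:
        snp_ids = [f"rs{j + 1}" for j in range(m)]
    eaf = G.mean(axis=0) / 2.0
    poly = (eaf > 0) & (eaf < 1)
    if not poly.all():
        dropped = [snp_ids[j] for j in np.flatnonzero(~poly)]
        logger.warning("%s: dropping %d monomorphic SNP(s): %s", trait_id, len(dropped), dropped[:5])
    Gp = np.ascontiguousarray(G[:, poly], dtype=np.float64)
    ids = [s for s, keep in zip(snp_ids, poly) if keep]
    if trait_type == "quantitative":
        beta, se = _linear_gwas(trait, Gp)
        pval = 2.0 * stats.t.sf(np.abs(beta / se), n - 2)
    elif trait_type == "binary":
        beta, se = _logistic_gwas(trait, Gp)
        pval = 2.0 * stats.norm.sf(np.abs(beta / se))
    else:
        raise ValueError(f"unknown trait_type {trait_type!r}")
    pval = np.maximum(pval, _TINY_P)
    eaf = eaf[poly]
    records = [
        VariantAssociation(
            snp_id=ids[j],
            effect_allele="A",
            other_allele="G",
            eaf=float(eaf[j]),
            beta=float(beta[j]),
            se=float(se[j]),
            pval=float(pval[j]),
            n=n,
        )
        for j in range(len(ids))
    ]
    return SummaryStatSet(trait_id=trait_id, trait_type=trait_type, records=records)


def ld_from_genotypes(G: np.ndarray, snp_ids: list[str]) -> LDMatrix:
    """Squared Pearson correlation of dosages; monomorphic columns get r2=0."""
    Gf = G.astype(np.float64)
    sd = Gf.std(axis=0)
    ok = sd > 0
    r2 = np.zeros((Gf.shape[1], Gf.shape[1]))
    if ok.any():
        c = np.corrcoef(Gf[:, ok], rowvar=False)
        r2[np.ix_(ok, ok)] = np.atleast_2d(c) ** 2
    np.fill_diagonal(r2, 1.0)
    r2 = np.clip((r2 + r2.T) / 2.0, 0.0, 1.0)
    return LDMatrix(list(snp_ids), r2)


@dataclass
class SimulatedStudy:
    """A complete synthetic study bundle: truth, per-cohort GWAS, LD."""

    config: SimulationConfig
    truth: dict
    sumstats: dict[str, SummaryStatSet]
    ld: LDMatrix
    cohort_indices: dict[str, np.ndarray]
    scaling: dict[str, tuple[float, float]] = field(default_factory=dict)

    def write_bundle(self, directory: str | Path) -> Path:
        """Write the study as TSVs plus a manifest (config + truth) JSON."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        files = {}
        for name, sset in self.sumstats.items():
            path = directory / f"{name}.tsv"
            write_sumstats(sset, path)
            files[name] = path.name
        write_ld_matrix(self.ld, directory / "ld.tsv")
        manifest = {
            "config": dataclasses.asdict(self.config),
            "truth": self.truth,
            "files": files,
            "ld_file": "ld.tsv",
            "trait_types": {k: v.trait_type for k, v in self.sumstats.items()},
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return directory


def simulate_study(config: SimulationConfig | None = None) -> SimulatedStudy:
    """Generate a full two-sample study with disjoint per-GWAS cohorts.

    One cohort per GWAS (exposure, each mediator, outcome) plus a held-out
    LD reference sample; every downstream number is fixed by
    ``config.seed``.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    n_exp, n_med, n_out = cfg.n_per_cohort
    n_total = n_exp + n_med * cfg.n_mediators + n_out + cfg.n_ld
    mafs = rng.uniform(*cfg.maf_range, size=cfg.n_snps_total)
    snp_ids = [f"rs{j + 1}" for j in range(cfg.n_snps_total)]
    G = simulate_genotypes(
        n_total, mafs, rng, block_size=cfg.ld_block_size, rho=cfg.ld_block_rho
    )
    traits = simulate_traits(G, cfg, rng, mafs)

    cohorts: dict[str, np.ndarray] = {}
    start = 0
    for name, size in [("exposure", n_exp)] + [
        (m, n_med) for m in cfg.mediator_names
    ] + [("outcome", n_out), ("_ld", cfg.n_ld)]:
        cohorts[name] = np.arange(start, start + size)
        start += size

    sumstats = {
        "exposure": compute_sumstats(
            traits["exposure"][cohorts["exposure"]],
            G[cohorts["exposure"]],
            "quantitative",
            "exposure",
            snp_ids,
        )
    }
    for name in cfg.mediator_names:
        sumstats[name] = compute_sumstats(
            traits["mediators"][name][cohorts[name]],
            G[cohorts[name]],
            "quantitative",
            name,
            snp_ids,
        )
    sumstats["outcome"] = compute_sumstats(
        traits["outcome"][cohorts["outcome"]],
        G[cohorts["outcome"]],
        "binary",
        "outcome",
        snp_ids,
    )
    ld = ld_from_genotypes(G[cohorts["_ld"]], snp_ids)
    return SimulatedStudy(
        config=cfg,
        truth=cfg.truth(),
        sumstats=sumstats,
        ld=ld,
        cohort_indices=cohorts,
        scaling=traits["scaling"],
    )
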