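"""Instrument selection, LD clumping, strength diagnostics and harmonization.

Two-sample MR estimates variant-exposure and variant-outcome associations in
non-overlapping cohorts, so the two tables must be aligned to a common effect
allele before any ratio is formed.  This module owns that alignment
(:func:`harmonize`) plus the standard instrument screens: genome-wide
significance (p < 5e-8 by convention), greedy LD clumping at an r^2
threshold, and the per-SNP F statistic (F > 10 is the usual weak-instrument
cut-off).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .sumstats import LDMatrix, SummaryStatSet, SumstatsError, VariantAssociation

logger = logging.getLogger(__name__)

__all__ = [
    "InstrumentSet",
    "HarmonizedSet",
    "HarmonizationError",
    "select_instruments",
    "ld_clump",
    "f_statistic",
    "variance_explained",
    "harmonize",
    "harmonize_multi",
    "MultiHarmonizedSet",
    "make_instrument_set",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class HarmonizationError(SumstatsError):
    """Raised when exposure and outcome sets cannot be aligned at all."""


def f_statistic(record: VariantAssociation) -> float:
    """Per-SNP instrument-strength F statistic, ``(beta/se)^2``."""
    return (record.beta / record.se) ** 2


def variance_explained(record: VariantAssociation) -> float:
    """Proportion of trait variance explained: ``2*eaf*(1-eaf)*beta^2``.

    Assumes a quantitative trait with beta in SD units and Hardy-Weinberg
    allele dosages.  Raises if the record carries no allele frequency.
    """
    if record.eaf is None:
        raise SumstatsError(f"{record.snp_id}: eaf required for variance explained")
    return 2.0 * record.eaf * (1.0 - record.eaf) * record.beta**2


def select_instruments(sset: SummaryStatSet, p_threshold: float = 5e-8) -> SummaryStatSet:
    """Subset to records with ``pval < p_threshold``, preserving order."""
    if not 0.0 < p_threshold <= 1.0:
        raise ValueError(f"p_threshold must be in (0,1], got {p_threshold}")
    kept = [r for r in sset.records if r.pval < p_threshold]
    if not kept:
        logger.warning(
            "no variants in %s pass p < %.3g", sset.trait_id, p_threshold
        )
    return SummaryStatSet(sset.trait_id, sset.trait_type, kept)


def ld_clump(
    sset: SummaryStatSet, ld: LDMatrix, r2_threshold: float = 0.001
) -> SummaryStatSet:
    """Greedy LD clumping.

    Repeatedly take the remaining variant with the smallest p-value (ties
    broken by snp_id, lexicographic), keep it, and discard every remaining
    variant with r^2 >= ``r2_threshold`` to it.  The returned set is mutually
    below the threshold.
    """
    missing = [r.snp_id for r in sset.records if r.snp_id not in ld]
    if missing:
        raise SumstatsError(f"SNP(s) absent from LD matrix: {missing[:10]}")
    order = sorted(sset.records, key=lambda r: (r.pval, r.snp_id))
    sub = ld.submatrix([r.snp_id for r in order])
    alive = np.ones(len(order), dtype=bool)
    kept_ids: set[str] = set()
    for i in range(len(order)):
        if not alive[i]:
            continue
        kept_ids.add(order[i].snp_id)
        alive &= sub.r2[i] < r2_threshold
        alive[i] = False
    return sset.subset(kept_ids)


def make_instrument_set(
    sset: SummaryStatSet,
    p_threshold: float = 5e-8,
    ld: LDMatrix | None = None,
    r2_threshold: float = 0.001,
    f_threshold: float = 10.0,
) -> "InstrumentSet":
    """Full instrument-selection pipeline with strength diagnostics.

    Significance screen, optional greedy clumping, then a per-SNP F filter.
    """
    selected = select_instruments(sset, p_threshold)
    n_sig = len(selected)
    if ld is not None and len(selected):
        selected = ld_clump(selected, ld, r2_threshold)
    n_clumped = len(selected)
    records = [r for r in selected.records if f_statistic(r) >= f_threshold]
    logger.info(
        "%s instruments: %d significant -> %d after clumping -> %d with F >= %g",
        sset.trait_id,
        n_sig,
        n_clumped,
        len(records),
        f_threshold,
    )
    f_stats = {r.snp_id: f_statistic(r) for r in records}
    pve = {}
    for r in records:
        try:
            pve[r.snp_id] = variance_explained(r)
        except SumstatsError:
            pass
    return InstrumentSet(
        exposure_trait=sset.trait_id,
        records=SummaryStatSet(sset.trait_id, sset.trait_type, records),
        f_stats=f_stats,
        pve=pve,
        p_threshold=p_threshold,
        counts={"significant": n_sig, "after_clump": n_clumped, "after_f": len(records)},
    )


@dataclass
class InstrumentSet:
    """Selected instruments for one exposure plus strength diagnostics."""

    exposure_trait: str
    records: SummaryStatSet
    f_stats: dict[str, float]
    pve: dict[str, float]
    p_threshold: float = 5e-8
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_pve(self) -> float:
        """Total proportion of exposure variance explained (sum over SNPs)."""
        return float(sum(self.pve.values()))

    @property
    def min_f(self) -> float:
        return min(self.f_stats.values()) if self.f_stats else float("nan")


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT[a1] == a2


@dataclass
class HarmonizedSet:
    """Instrument-aligned exposure/outcome effects on a common effect allele.

    The numeric arrays carry only kept/flipped SNPs; ``actions`` records the
    fate of every intersected SNP (``kept``, ``flipped``,
    ``dropped_palindromic`` or ``dropped_incompatible``) so nothing is
    silently discarded.
    """

    snp_ids: list[str]
    beta_exp: np.ndarray
    se_exp: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray
    actions: dict[str, str]
    exposure_trait: str = ""
    outcome_trait: str = ""
    outcome_type: str = "binary"

    def __post_init__(self) -> None:
        self.beta_exp = np.asarray(self.beta_exp, dtype=float)
        self.se_exp = np.asarray(self.se_exp, dtype=float)
        self.beta_out = np.asarray(self.beta_out, dtype=float)
        self.se_out = np.asarray(self.se_out, dtype=float)
        k = len(self.snp_ids)
        for name in ("beta_exp", "se_exp", "beta_out", "se_out"):
            arr = getattr(self, name)
            if arr.shape != (k,):
                raise ValueError(f"{name} length {arr.shape} != {k} snp_ids")
        if k and (self.se_exp <= 0).any() or k and (self.se_out <= 0).any():
            raise ValueError("standard errors must be strictly positive")
        kept = {s for s, a in self.actions.items() if a in ("kept", "flipped")}
        if kept != set(self.snp_ids):
            raise ValueError("numeric arrays must contain exactly the kept/flipped SNPs")

    @property
    def n_snp(self) -> int:
        return len(self.snp_ids)

    def subset(self, snp_ids) -> "HarmonizedSet":
        wanted = [s for s in self.snp_ids if s in set(snp_ids)]
        idx = [self.snp_ids.index(s) for s in wanted]
        actions = {s: a for s, a in self.actions.items() if a not in ("kept", "flipped")}
        actions.update({s: self.actions[s] for s in wanted})
        return HarmonizedSet(
            wanted,
            self.beta_exp[idx],
            self.se_exp[idx],
            self.beta_out[idx],
            self.se_out[idx],
            actions,
            self.exposure_trait,
            self.outcome_trait,
            self.outcome_type,
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-SNP table including dropped SNPs and their actions."""
        kept = pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "beta_exp": self.beta_exp,
                "se_exp": self.se_exp,
                "beta_out": self.beta_out,
                "se_out": self.se_out,
            }
        )
        kept["action"] = [self.actions[s] for s in self.snp_ids]
        dropped = [
            {"snp_id": s, "action": a}
            for s, a in self.actions.items()
            if a not in ("kept", "flipped")
        ]
        if dropped:
            kept = pd.concat([kept, pd.DataFrame(dropped)], ignore_index=True)
        return kept

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def harmonize(
    exposure: SummaryStatSet,
    outcome: SummaryStatSet,
    palindromic_eaf_window: float = 0.08,
) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect alleles.

    Variants are intersected on ``snp_id``.  If the outcome file reports the
    swapped allele pair, its beta is negated and eaf complemented
    (``flipped``).  Alleles reported on the opposite strand are complemented
    before matching.  Palindromic variants (A/T or C/G), whose strand cannot
    be resolved from the alleles alone, are kept only when both allele
    frequencies are available, both fall outside
    ``[0.5 - window, 0.5 + window]`` and agree on which allele is the minor
    one; otherwise they are dropped (``dropped_palindromic``).  Irreconcilable
    allele pairs become ``dropped_incompatible``.
    """
    out_by_id = {r.snp_id: r for r in outcome.records}
    shared = [r for r in exposure.records if r.snp_id in out_by_id]
    if not shared:
        raise HarmonizationError(
            f"no shared variants between {exposure.trait_id} and {outcome.trait_id}"
        )
    ids, bx, sx, by, sy = [], [], [], [], []
    actions: dict[str, str] = {}
    w = palindromic_eaf_window
    for e in shared:
        o = out_by_id[e.snp_id]
        ea, oa = e.effect_allele, e.other_allele
        o_ea, o_oa = o.effect_allele, o.other_allele
        palindromic = _is_palindromic(ea, oa)
        if not palindromic and not _is_palindromic(o_ea, o_oa):
            # try direct match, then strand-complemented match
            if {o_ea, o_oa} != {ea, oa}:
                o_ea, o_oa = _COMPLEMENT[o_ea], _COMPLEMENT[o_oa]
            if {o_ea, o_oa} != {ea, oa}:
                actions[e.snp_id] = "dropped_incompatible"
                continue
            flip = o_ea == oa
        elif palindromic and _is_palindromic(o_ea, o_oa) and {o_ea, o_oa} == {ea, oa}:
            # strand is ambiguous: orient by allele frequency
            if e.eaf is None or o.eaf is None:
                actions[e.snp_id] = "dropped_palindromic"
                continue
            flip = o_ea == oa
            o_eaf_aligned = 1.0 - o.eaf if flip else o.eaf
            inside = abs(e.eaf - 0.5) <= w or abs(o_eaf_aligned - 0.5) <= w
            same_side = (e.eaf - 0.5) * (o_eaf_aligned - 0.5) > 0
            if inside or not same_side:
                actions[e.snp_id] = "dropped_palindromic"
                continue
        else:
            actions[e.snp_id] = "dropped_incompatible"
            continue
        actions[e.snp_id] = "flipped" if flip else "kept"
        ids.append(e.snp_id)
        bx.append(e.beta)
        sx.append(e.se)
        by.append(-o.beta if flip else o.beta)
        sy.append(o.se)
    n_dropped = sum(a.startswith("dropped") for a in actions.values())
    if n_dropped:
        logger.info(
            "harmonize %s ~ %s: %d kept, %d dropped",
            exposure.trait_id,
            outcome.trait_id,
            len(ids),
            n_dropped,
        )
    return HarmonizedSet(
        ids,
        np.array(bx),
        np.array(sx),
        np.array(by),
        np.array(sy),
        actions,
        exposure_trait=exposure.trait_id,
        outcome_trait=outcome.trait_id,
        outcome_type=outcome.trait_type,
    )


@dataclass
class MultiHarmonizedSet:
    """Several exposures and one outcome aligned on a common SNP panel.

    ``beta_exp`` is (n_snp, n_exposure); column order follows
    ``exposure_ids``.  All effects are oriented to the first (primary)
    exposure's effect alleles.
    """

    snp_ids: list[str]
    exposure_ids: list[str]
    beta_exp: np.ndarray
    se_exp: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray
    outcome_trait: str = ""
    outcome_type: str = "binary"

    @property
    def n_snp(self) -> int:
        return len(self.snp_ids)


def harmonize_multi(
    exposures: dict[str, SummaryStatSet],
    outcome: SummaryStatSet,
    snp_ids=None,
    palindromic_eaf_window: float = 0.08,
) -> MultiHarmonizedSet:
    """Harmonize several exposure sets and one outcome to a shared panel.

    The first exposure is the allele-orientation reference: the outcome and
    every further exposure are harmonized against it, and only SNPs kept in
    every pairwise harmonization (optionally restricted to ``snp_ids``)
    enter the panel.
    """
    names = list(exposures)
    if not names:
        raise ValueError("need at least one exposure")
    primary = exposures[names[0]]
    if snp_ids is not None:
        primary = primary.subset(snp_ids)
    h_out = harmonize(primary, outcome, palindromic_eaf_window)
    panels = {names[0]: None, "_outcome": h_out}
    for name in names[1:]:
        panels[name] = harmonize(primary, exposures[name], palindromic_eaf_window)
    common = [s for s in h_out.snp_ids]
    for name in names[1:]:
        keep = set(panels[name].snp_ids)
        common = [s for s in common if s in keep]
    if not common:
        raise HarmonizationError("no SNPs survive multi-exposure harmonization")
    h_out = h_out.subset(common)
    beta_cols = [h_out.beta_exp]
    se_cols = [h_out.se_exp]
    for name in names[1:]:
        h = panels[name].subset(common)
        # in harmonize(primary, mediator) the mediator plays the outcome role
        beta_cols.append(h.beta_out)
        se_cols.append(h.se_out)
    return MultiHarmonizedSet(
        snp_ids=common,
        exposure_ids=names,
        beta_exp=np.column_stack(beta_cols),
        se_exp=np.column_stack(se_cols),
        beta_out=h_out.beta_out,
        se_out=h_out.se_out,
        outcome_trait=outcome.trait_id,
        outcome_type=outcome.trait_type,
    )
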