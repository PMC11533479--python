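"""Data model, validation and file I/O for GWAS summary statistics and LD matrices.

A GWAS summary-statistic file carries one row per variant: the per-allele
association of that variant with a trait (``beta``), its standard error,
p-value, effect/other allele, effect-allele frequency and sample size.  For
quantitative traits ``beta`` is on the trait-SD scale; for binary traits it
is a log-odds ratio.  The canonical on-disk dialect is a tab-separated table
with the columns::

    snp_id  effect_allele  other_allele  eaf  beta  se  pval  n

Files using other column names (e.g. IEU OpenGWAS exports with ``SNP``,
``pval.exposure`` ...) are handled through a column map and a built-in alias
table.  Gzipped files are read and written transparently.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VariantAssociation",
    "SummaryStatSet",
    "LDMatrix",
    "SumstatsError",
    "ValidationError",
    "read_sumstats",
    "write_sumstats",
    "read_ld_matrix",
    "write_ld_matrix",
]

VALID_BASES = frozenset("ACGT")

CANONICAL_COLUMNS = ("snp_id", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n")

# Common column spellings in the wild (IEU exports, PLINK, GWAS catalog dumps).
_COLUMN_ALIASES: dict[str, str] = {
    "snp": "snp_id",
    "rsid": "snp_id",
    "variant_id": "snp_id",
    "markername": "snp_id",
    "ea": "effect_allele",
    "a1": "effect_allele",
    "allele1": "effect_allele",
    "oa": "other_allele",
    "nea": "other_allele",
    "a2": "other_allele",
    "allele0": "other_allele",
    "allele2": "other_allele",
    "eaf": "eaf",
    "af": "eaf",
    "freq": "eaf",
    "effect_allele_frequency": "eaf",
    "b": "beta",
    "beta": "beta",
    "effect": "beta",
    "se": "se",
    "standard_error": "se",
    "stderr": "se",
    "p": "pval",
    "pval": "pval",
    "p_value": "pval",
    "pvalue": "pval",
    "n": "n",
    "samplesize": "n",
    "sample_size": "n",
}


class SumstatsError(Exception):
    """Base error for summary-statistic I/O and validation."""


class ValidationError(SumstatsError):
    """One or more rows violate a field invariant.

    ``issues`` is a list of ``(row_index, message)`` pairs, 0-based over data
    rows (header excluded).
    """

    def __init__(self, issues: Sequence[tuple[int, str]]):
        self.issues = list(issues)
        lines = "; ".join(f"row {i}: {msg}" for i, msg in self.issues[:20])
        extra = "" if len(self.issues) <= 20 else f" (+{len(self.issues) - 20} more)"
        super().__init__(f"{len(self.issues)} invalid row(s): {lines}{extra}")


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's per-allele effect on one trait.

    ``beta`` is in trait-SD units for quantitative traits and log-odds for
    binary traits.  ``eaf`` may be ``None`` when the source file omits
    effect-allele frequencies.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    n: float
    eaf: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "effect_allele", str(self.effect_allele).upper())
        object.__setattr__(self, "other_allele", str(self.other_allele).upper())
        problems = _check_record(
            self.effect_allele, self.other_allele, self.eaf, self.beta, self.se, self.pval, self.n
        )
        if problems:
            raise ValidationError([(0, f"{self.snp_id}: {p}") for p in problems])

    @property
    def f_stat(self) -> float:
        """Single-SNP instrument-strength F statistic, (beta/se)^2."""
        return (self.beta / self.se) ** 2


def _check_record(ea, oa, eaf, beta, se, pval, n) -> list[str]:
    problems = []
    if ea not in VALID_BASES or oa not in VALID_BASES:
        problems.append(f"alleles must be single bases A/C/G/T, got {ea!r}/{oa!r}")
    elif ea == oa:
        problems.append(f"effect and other allele identical ({ea})")
    if eaf is not None and not (math.isnan(eaf) if isinstance(eaf, float) else False):
        if not 0.0 <= eaf <= 1.0:
            problems.append(f"eaf {eaf} outside [0,1]")
    if not math.isfinite(beta):
        problems.append(f"non-finite beta {beta}")
    if not (math.isfinite(se) and se > 0):
        problems.append(f"se must be finite and > 0, got {se}")
    if not (0.0 < pval <= 1.0):
        problems.append(f"pval {pval} outside (0,1]")
    if not n > 0:
        problems.append(f"sample size {n} must be > 0")
    return problems


@dataclass
class SummaryStatSet:
    """A full set of per-variant associations for one trait.

    ``trait_type`` is ``"quantitative"`` or ``"binary"``; ``snp_id`` values
    are unique within the set.
    """

    trait_id: str
    trait_type: str
    records: list[VariantAssociation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise SumstatsError(
                f"trait_type must be 'quantitative' or 'binary', got {self.trait_type!r}"
            )
        ids = [r.snp_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SumstatsError(f"duplicate snp_id in {self.trait_id}: {dupes[:10]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]

    def get(self, snp_id: str) -> VariantAssociation:
        try:
            return self._index[snp_id]
        except AttributeError:
            self._index = {r.snp_id: r for r in self.records}
            return self._index[snp_id]

    def subset(self, snp_ids: Iterable[str]) -> "SummaryStatSet":
        """Records restricted to ``snp_ids``, preserving this set's order."""
        wanted = set(snp_ids)
        return SummaryStatSet(
            trait_id=self.trait_id,
            trait_type=self.trait_type,
            records=[r for r in self.records if r.snp_id in wanted],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": [r.snp_id for r in self.records],
                "effect_allele": [r.effect_allele for r in self.records],
                "other_allele": [r.other_allele for r in self.records],
                "eaf": [np.nan if r.eaf is None else r.eaf for r in self.records],
                "beta": [r.beta for r in self.records],
                "se": [r.se for r in self.records],
                "pval": [r.pval for r in self.records],
                "n": [r.n for r in self.records],
            }
        )

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, trait_id: str, trait_type: str
    ) -> "SummaryStatSet":
        """Validate a canonical-column DataFrame into a SummaryStatSet.

        Every offending row is reported (with its 0-based index) rather than
        silently dropped; p-values of exactly 0 are clamped to the smallest
        positive float with a warning, since some GWAS exports truncate.
        """
        missing = [c for c in CANONICAL_COLUMNS if c not in df.columns and c != "eaf"]
        if missing:
            raise SumstatsError(f"missing required column(s): {missing}")
        issues: list[tuple[int, str]] = []
        records: list[VariantAssociation] = []
        has_eaf = "eaf" in df.columns
        n_clamped = 0
        for i, row in enumerate(df.itertuples(index=False)):
            d = row._asdict()
            try:
                beta = float(d["beta"])
                se = float(d["se"])
                pval = float(d["pval"])
                n = float(d["n"])
            except (TypeError, ValueError) as exc:
                issues.append((i, f"non-numeric field: {exc}"))
                continue
            if pval == 0.0:
                pval = np.nextafter(0.0, 1.0)
                n_clamped += 1
            eaf = None
            if has_eaf:
                raw = d["eaf"]
                if raw is not None and not (isinstance(raw, float) and math.isnan(raw)) and raw != "":
                    try:
                        eaf = float(raw)
                    except (TypeError, ValueError):
                        issues.append((i, f"non-numeric eaf {raw!r}"))
                        continue
            ea = str(d["effect_allele"]).upper()
            oa = str(d["other_allele"]).upper()
            problems = _check_record(ea, oa, eaf, beta, se, pval, n)
            if problems:
                issues.append((i, f"{d['snp_id']}: " + "; ".join(problems)))
                continue
            records.append(
                VariantAssociation(
                    snp_id=str(d["snp_id"]),
                    effect_allele=ea,
                    other_allele=oa,
                    eaf=eaf,
                    beta=beta,
                    se=se,
                    pval=pval,
                    n=n,
                )
            )
        if n_clamped:
            logger.warning(
                "%d p-value(s) of exactly 0 clamped to %.3g in %s",
                n_clamped,
                float(np.nextafter(0.0, 1.0)),
                trait_id,
            )
        if issues:
            raise ValidationError(issues)
        return cls(trait_id=trait_id, trait_type=trait_type, records=records)


def read_sumstats(
    path: str | Path,
    trait_id: str | None = None,
    trait_type: str = "quantitative",
    column_map: Mapping[str, str] | None = None,
    sep: str = "\t",
) -> SummaryStatSet:
    """Read a delimited summary-statistic file into a validated set.

    Parameters
    ----------
    path
        Delimited text file with a header row; ``.gz`` handled transparently.
    trait_id
        Defaults to the file stem.
    trait_type
        ``"quantitative"`` or ``"binary"`` (log-odds betas).
    column_map
        Maps canonical names to the file's column names, e.g.
        ``{"snp_id": "SNP", "pval": "p.value"}``.  Unmapped canonical columns
        fall back to the built-in alias table.
    """
    path = Path(path)
    if not path.exists():
        raise SumstatsError(f"no such file: {path}")
    df = pd.read_csv(path, sep=sep, dtype={0: str}, float_precision="round_trip")
    rename: dict[str, str] = {}
    explicit = dict(column_map or {})
    lower_cols = {c.lower(): c for c in df.columns}
    for canonical in CANONICAL_COLUMNS:
        if canonical in explicit:
            src = explicit[canonical]
            if src not in df.columns:
                raise SumstatsError(f"mapped column {src!r} (for {canonical}) not in file")
            rename[src] = canonical
            continue
        for alias, target in _COLUMN_ALIASES.items():
            if target == canonical and alias in lower_cols:
                rename[lower_cols[alias]] = canonical
                break
    df = df.rename(columns=rename)
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns and c != "eaf"]
    if missing:
        raise SumstatsError(f"{path}: could not locate column(s) {missing}; pass column_map")
    if df["snp_id"].duplicated().any():
        dupes = df.loc[df["snp_id"].duplicated(), "snp_id"].unique().tolist()
        raise SumstatsError(f"{path}: duplicate snp_id values {dupes[:10]}")
    return SummaryStatSet.from_frame(
        df, trait_id=trait_id or path.stem.removesuffix(".tsv"), trait_type=trait_type
    )


def write_sumstats(sset: SummaryStatSet, path: str | Path) -> None:
    """Write the canonical tab-separated dialect, full float precision.

    Missing ``eaf`` is an empty field.  ``.gz`` suffix triggers gzip.
    """
    df = sset.to_frame()
    # %.17g guarantees exact binary round trip of every float
    df.to_csv(path, sep="\t", index=False, na_rep="", float_format="%.17g")


@dataclass
class LDMatrix:
    """Pairwise squared-correlation (r^2) matrix over an ordered SNP panel."""

    snp_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.snp_ids)
        if self.r2.shape != (k, k):
            raise SumstatsError(
                f"LD matrix shape {self.r2.shape} does not match {k} snp_ids"
            )
        if len(set(self.snp_ids)) != k:
            raise SumstatsError("duplicate snp_id in LD matrix")
        if not np.allclose(self.r2, self.r2.T, atol=1e-12, rtol=0.0):
            raise SumstatsError("LD matrix not symmetric within 1e-12")
        if k and not np.allclose(np.diag(self.r2), 1.0, atol=1e-8):
            raise SumstatsError("LD matrix diagonal entries must equal 1")
        if ((self.r2 < -1e-12) | (self.r2 > 1.0 + 1e-8)).any():
            bad = float(self.r2.min()) if self.r2.min() < 0 else float(self.r2.max())
            raise SumstatsError(f"LD r2 entries must lie in [0,1]; found {bad}")
        self.r2 = np.clip(self.r2, 0.0, 1.0)
        self._pos = {s: i for i, s in enumerate(self.snp_ids)}

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._pos

    def lookup(self, a: str, b: str) -> float:
        return float(self.r2[self._pos[a], self._pos[b]])

    def submatrix(self, snp_ids: Sequence[str]) -> "LDMatrix":
        missing = [s for s in snp_ids if s not in self._pos]
        if missing:
            raise SumstatsError(f"SNP(s) absent from LD matrix: {missing[:10]}")
        idx = [self._pos[s] for s in snp_ids]
        return LDMatrix(list(snp_ids), self.r2[np.ix_(idx, idx)])


def read_ld_matrix(path: str | Path) -> LDMatrix:
    """Read a TSV LD matrix whose first row and column are snp_ids."""
    path = Path(path)
    if not path.exists():
        raise SumstatsError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    row_ids = [str(s) for s in df.index]
    col_ids = [str(s) for s in df.columns]
    if row_ids != col_ids:
        raise SumstatsError(f"{path}: row and column snp_ids differ")
    return LDMatrix(row_ids, df.to_numpy(dtype=float))


def write_ld_matrix(ld: LDMatrix, path: str | Path) -> None:
    pd.DataFrame(ld.r2, index=ld.snp_ids, columns=ld.snp_ids).to_csv(path, sep="\t")
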