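"""GWAS summary-statistic I/O, instrument selection, and allele harmonization.

Summary statistics travel as delimited text (tab or comma, sniffed from the
header line) with one row per variant. Harmonization aligns exposure and
outcome records onto the exposure's effect allele, following standard
two-sample MR practice: matching alleles are copied, swapped alleles flip the
outcome sign, strand-complement codings are resolved, and palindromic (A/T,
C/G) variants are kept only when both allele frequencies identify the strand
unambiguously.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    HarmonizationError,
    NoInstrumentsError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: one standard deviation of circulating GDF-15, in pg/ml
GDF15_SD_PGML = 625.0

#: genome-wide significance, the default instrument-selection threshold
GENOME_WIDE_P = 5e-8

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: standard field -> default column name in delimited files
DEFAULT_COLUMNS: Mapping[str, str] = {
    "variant_id": "SNP",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pvalue": "pval",
    "n": "n",
    "chrom": "chrom",
    "pos": "pos",
}

MANDATORY_FIELDS = ("variant_id", "effect_allele", "other_allele", "beta", "se", "pvalue")


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's summary association with one trait.

    ``beta`` is the effect per copy of ``effect_allele``: SD units for a
    continuous trait, log-odds for a binary one.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: float | None = None
    n: float | None = None
    chrom: str | None = None
    pos: int | None = None

    def __post_init__(self) -> None:
        ea = str(self.effect_allele).upper()
        oa = str(self.other_allele).upper()
        object.__setattr__(self, "effect_allele", ea)
        object.__setattr__(self, "other_allele", oa)
        if ea not in COMPLEMENT or oa not in COMPLEMENT:
            raise ValidationError(
                f"{self.variant_id}: alleles must be single nucleotides, got {ea}/{oa}"
            )
        if ea == oa:
            raise ValidationError(f"{self.variant_id}: effect and other allele are identical")
        if not (self.se > 0) or not math.isfinite(self.se):
            raise ValidationError(f"{self.variant_id}: standard error must be > 0")
        if not math.isfinite(self.beta):
            raise ValidationError(f"{self.variant_id}: beta is not finite")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValidationError(f"{self.variant_id}: p-value must be in (0, 1]")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise ValidationError(f"{self.variant_id}: EAF must be in [0, 1]")

    @property
    def is_palindromic(self) -> bool:
        return self.other_allele == COMPLEMENT[self.effect_allele]


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure and outcome effects for one instrument on a common effect allele.

    ``x``/``sx`` are the exposure association and its SE, ``y``/``sy`` the
    outcome association after alignment. Dropped variants carry a
    ``dropped_reason`` and no outcome values.
    """

    variant_id: str
    x: float
    sx: float
    y: float | None = None
    sy: float | None = None
    flipped: bool = False
    dropped_reason: str | None = None

    def __post_init__(self) -> None:
        if not (self.sx > 0):
            raise ValidationError(f"{self.variant_id}: exposure SE must be > 0")
        if self.dropped_reason is None:
            if self.y is None or self.sy is None or not (self.sy > 0):
                raise ValidationError(
                    f"{self.variant_id}: retained pair needs outcome beta and SE > 0"
                )


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pairwise LD correlations (r values) between instruments."""

    variant_ids: tuple[str, ...]
    r: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "variant_ids", tuple(self.variant_ids))
        k = len(self.variant_ids)
        if r.shape != (k, k):
            raise ValidationError(f"correlation matrix shape {r.shape} != ({k}, {k})")
        if not np.allclose(r, r.T, atol=1e-8):
            raise ValidationError("correlation matrix is not symmetric")
        if np.any(np.abs(np.diag(r) - 1.0) > 1e-6):
            raise ValidationError("correlation matrix diagonal must be 1")
        if np.any(np.abs(r) > 1.0 + 1e-8):
            raise ValidationError("correlations must lie in [-1, 1]")
        w = np.linalg.eigvalsh((r + r.T) / 2.0)
        if w.min() < -1e-8 * max(1.0, w.max()):
            raise ValidationError("correlation matrix is not positive semi-definite")

    def subset(self, ids: Sequence[str]) -> "CorrelationMatrix":
        """Restrict (and reorder) to ``ids``."""
        index = {v: i for i, v in enumerate(self.variant_ids)}
        missing = [v for v in ids if v not in index]
        if missing:
            raise ValidationError(f"correlation matrix is missing ids: {missing}")
        idx = np.array([index[v] for v in ids], dtype=int)
        return CorrelationMatrix(tuple(ids), self.r[np.ix_(idx, idx)])

    @classmethod
    def identity(cls, ids: Sequence[str]) -> "CorrelationMatrix":
        return cls(tuple(ids), np.eye(len(ids)))


@dataclass
class InstrumentSet:
    """Harmonized instruments for one exposure-outcome pair."""

    exposure_name: str
    outcome_name: str
    pairs: list[HarmonizedPair]
    dropped: list[HarmonizedPair] = field(default_factory=list)
    correlation: CorrelationMatrix | None = None

    def __post_init__(self) -> None:
        if not self.pairs:
            raise HarmonizationError(
                f"no overlapping instruments for {self.exposure_name} -> {self.outcome_name}"
            )
        if self.correlation is not None:
            ids = tuple(p.variant_id for p in self.pairs)
            if self.correlation.variant_ids != ids:
                raise ValidationError("correlation matrix order does not match pairs")

    def with_correlation(self, corr: CorrelationMatrix) -> "InstrumentSet":
        sub = corr.subset([p.variant_id for p in self.pairs])
        return InstrumentSet(
            self.exposure_name, self.outcome_name, self.pairs, self.dropped, sub
        )


def _sniff_sep(path: Path) -> str:
    header = Path(path).open().readline()
    return "\t" if "\t" in header else ","


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[VariantAssociation]:
    """Read per-variant summary statistics from a delimited text table.

    ``column_map`` maps standard field names (``variant_id``, ``beta`` ...)
    to the file's column names; unmapped optional fields are taken from the
    defaults when present in the file and skipped otherwise. Rows whose beta,
    SE, or p-value cannot be parsed or violate invariants are rejected and
    counted in the log.
    """
    path = Path(path)
    cmap = dict(DEFAULT_COLUMNS)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep=_sniff_sep(path), float_precision="round_trip")

    for fld in MANDATORY_FIELDS:
        if cmap[fld] not in df.columns:
            raise ConfigurationError(
                f"{path.name}: mandatory column {cmap[fld]!r} (field {fld!r}) is missing"
            )
    optional = {f: cmap[f] for f in ("eaf", "n", "chrom", "pos") if cmap[f] in df.columns}

    records: list[VariantAssociation] = []
    n_rejected = 0
    for _, row in df.iterrows():
        try:
            kwargs = dict(
                variant_id=str(row[cmap["variant_id"]]),
                effect_allele=str(row[cmap["effect_allele"]]),
                other_allele=str(row[cmap["other_allele"]]),
                beta=float(row[cmap["beta"]]),
                se=float(row[cmap["se"]]),
                pvalue=float(row[cmap["pvalue"]]),
            )
            for fld, col in optional.items():
                val = row[col]
                if pd.isna(val):
                    continue
                if fld == "pos":
                    kwargs[fld] = int(val)
                elif fld == "chrom":
                    kwargs[fld] = str(val)
                else:
                    kwargs[fld] = float(val)
            records.append(VariantAssociation(**kwargs))
        except (ValueError, TypeError, ValidationError) as exc:
            n_rejected += 1
            logger.warning("%s: rejected row (%s)", path.name, exc)
    logger.info(
        "%s: read %d rows, retained %d, rejected %d",
        path.name, len(df), len(records), n_rejected,
    )
    return records


def write_sumstats(
    assocs: Sequence[VariantAssociation],
    path: str | Path,
    sep: str = "\t",
) -> None:
    """Write associations back to a delimited table using the default columns."""
    rows = []
    for a in assocs:
        rows.append({
            "SNP": a.variant_id,
            "chrom": a.chrom,
            "pos": a.pos,
            "effect_allele": a.effect_allele,
            "other_allele": a.other_allele,
            "eaf": a.eaf,
            "beta": a.beta,
            "se": a.se,
            "pval": a.pvalue,
            "n": a.n,
        })
    # 17 significant digits so floats survive a write/read round trip exactly
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False, float_format="%.17g")


def select_instruments(
    assocs: Sequence[VariantAssociation],
    p_threshold: float = GENOME_WIDE_P,
    inclusive: bool = False,
) -> list[VariantAssociation]:
    """Keep variants reaching the significance threshold, preserving order.

    The comparison is strict (``p < threshold``) by default; ``inclusive``
    switches to ``<=``.
    """
    if not (0.0 < p_threshold < 1.0):
        raise ConfigurationError("p_threshold must be in (0, 1)")
    if inclusive:
        kept = [a for a in assocs if a.pvalue <= p_threshold]
    else:
        kept = [a for a in assocs if a.pvalue < p_threshold]
    if not kept:
        raise NoInstrumentsError(p_threshold)
    logger.info("selected %d/%d instruments at p %s %g",
                len(kept), len(assocs), "<=" if inclusive else "<", p_threshold)
    return kept


def _same_side(f1: float, f2: float) -> bool:
    return (f1 - 0.5) * (f2 - 0.5) > 0


def harmonize(
    exposure: Sequence[VariantAssociation],
    outcome: Sequence[VariantAssociation],
    palindrome_eaf_limit: float = 0.42,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
) -> InstrumentSet:
    """Align outcome associations onto each exposure variant's effect allele.

    Matching is by rsID. Non-palindromic variants are aligned by allele
    labels, resolving strand complements; palindromic variants are retained
    only when both reported EAFs fall on the same side of 0.5 and outside
    ``[limit, 1 - limit]``, and are otherwise dropped as ambiguous.
    """
    if not (0.0 < palindrome_eaf_limit < 0.5):
        raise ConfigurationError("palindrome_eaf_limit must be in (0, 0.5)")
    by_id = {o.variant_id: o for o in outcome}

    retained: list[HarmonizedPair] = []
    dropped: list[HarmonizedPair] = []

    def drop(exp: VariantAssociation, reason: str) -> None:
        dropped.append(HarmonizedPair(exp.variant_id, exp.beta, exp.se,
                                      dropped_reason=reason))

    for exp in exposure:
        out = by_id.get(exp.variant_id)
        if out is None:
            drop(exp, "missing_in_outcome")
            continue

        if exp.is_palindromic:
            # Strand cannot be resolved from allele labels alone: align by
            # labels, then demand that the allele frequencies agree for the
            # aligned effect allele and sit well away from 0.5.
            if exp.eaf is None or out.eaf is None:
                drop(exp, "palindromic_ambiguous")
                continue
            if (out.effect_allele, out.other_allele) == (exp.effect_allele, exp.other_allele):
                flipped = False
                aligned_eaf = out.eaf
            elif (out.other_allele, out.effect_allele) == (exp.effect_allele, exp.other_allele):
                flipped = True
                aligned_eaf = 1.0 - out.eaf
            else:
                drop(exp, "allele_mismatch")
                continue
            lo, hi = palindrome_eaf_limit, 1.0 - palindrome_eaf_limit
            if (not _same_side(exp.eaf, aligned_eaf)
                    or lo <= exp.eaf <= hi or lo <= aligned_eaf <= hi):
                drop(exp, "palindromic_ambiguous")
                continue
            y = -out.beta if flipped else out.beta
            retained.append(HarmonizedPair(
                exp.variant_id, exp.beta, exp.se, y, out.se, flipped=flipped
            ))
            continue

        ea, oa = out.effect_allele, out.other_allele
        if (ea, oa) == (exp.effect_allele, exp.other_allele):
            flipped = False
        elif (oa, ea) == (exp.effect_allele, exp.other_allele):
            flipped = True
        else:
            cea, coa = COMPLEMENT[ea], COMPLEMENT[oa]
            if (cea, coa) == (exp.effect_allele, exp.other_allele):
                flipped = False
            elif (coa, cea) == (exp.effect_allele, exp.other_allele):
                flipped = True
            else:
                drop(exp, "allele_mismatch")
                continue

        y = -out.beta if flipped else out.beta
        retained.append(HarmonizedPair(
            exp.variant_id, exp.beta, exp.se, y, out.se, flipped=flipped
        ))

    logger.info("harmonized %s -> %s: retained %d, dropped %d",
                exposure_name, outcome_name, len(retained), len(dropped))
    if not retained:
        raise HarmonizationError(
            f"no overlapping instruments for {exposure_name} -> {outcome_name} "
            f"({len(dropped)} dropped)"
        )
    return InstrumentSet(exposure_name, outcome_name, retained, dropped)


def read_correlation_matrix(path: str | Path, ids: Sequence[str]) -> CorrelationMatrix:
    """Read a square LD r-matrix (id header row and column), reordered to ``ids``.

    Asymmetries below 1e-6 are averaged away; anything larger, or a diagonal
    off unity by more than 1e-6, is a validation error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0,
                     float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.shape[0] != df.shape[1]:
        raise ValidationError(f"{path.name}: correlation table is not square")
    missing = [v for v in ids if v not in df.index or v not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: ids missing from correlation table: {missing}")
    sub = df.loc[list(ids), list(ids)].to_numpy(dtype=float)
    if np.max(np.abs(sub - sub.T)) >= 1e-6:
        raise ValidationError(f"{path.name}: correlation table asymmetry exceeds 1e-6")
    sub = (sub + sub.T) / 2.0
    if np.any(np.abs(np.diag(sub) - 1.0) > 1e-6):
        raise ValidationError(f"{path.name}: correlation diagonal deviates from 1")
    return CorrelationMatrix(tuple(ids), sub)


def write_correlation_matrix(corr: CorrelationMatrix, path: str | Path, sep: str = "\t") -> None:
    pd.DataFrame(corr.r, index=list(corr.variant_ids),
                 columns=list(corr.variant_ids)).to_csv(path, sep=sep,
                                                        float_format="%.17g")


def sd_to_pgml(x_sd: float) -> float:
    """Convert a GDF-15 effect in SD units to pg/ml (1 SD = 625.0 pg/ml)."""
    return x_sd * GDF15_SD_PGML


def reorient(pair: HarmonizedPair) -> HarmonizedPair:
    """Jointly negate x and y; the implied causal ratio is unchanged."""
    return replace(pair, x=-pair.x, y=None if pair.y is None else -pair.y)
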