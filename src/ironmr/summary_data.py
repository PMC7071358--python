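"""Data model and I/O for summary-level GWAS association statistics.

Two-sample Mendelian randomization works entirely from per-variant summary
associations: an effect size (``beta``), its standard error, the effect
allele it is expressed against, and optionally the effect-allele frequency
(EAF), p-value and sample size.  Continuous exposures are conventionally in
standard-deviation units per effect allele; binary outcomes are on the
log-odds scale.

This module provides

* :class:`VariantAssociation`, :class:`InstrumentTable` -- one trait's
  per-variant associations, read from TSV/CSV files;
* :func:`select_instruments` -- p-value and LD (r-squared) filtering;
* :func:`harmonize` -- effect-allele alignment between an exposure and an
  outcome table, including strand-complement matching and palindromic
  (A/T, C/G) variant policies;
* :func:`backfill_from_ratio` -- recovery of a per-variant outcome
  association from a published per-variant odds ratio and 95% CI, given
  the exposure beta (the inverse of the first-order Wald ratio).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("ironmr")

#: Normal 97.5% quantile; used for every 95% confidence interval in the package.
Z_95 = 1.959964

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC_SETS = ({"A", "T"}, {"C", "G"})

#: Smallest positive float; p-values below double precision (as occur for
#: very strong GWAS hits) are clamped here instead of underflowing to zero.
_TINY_P = 5e-324


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


def _complement(allele: str) -> str | None:
    return _COMPLEMENT.get(allele)


def is_palindromic(a1: str | None, a2: str | None) -> bool:
    """True for A/T and C/G variants, whose strand is ambiguous."""
    if a1 is None or a2 is None:
        return False
    return {a1, a2} in _PALINDROMIC_SETS


@dataclass(frozen=True)
class VariantAssociation:
    """A single variant's association with a single trait.

    ``beta`` is in SD units of the trait for continuous exposures and
    log-odds per effect allele for binary outcomes.
    """

    variant_id: str
    trait_id: str
    beta: float
    se: float
    effect_allele: str | None = None
    other_allele: str | None = None
    eaf: float | None = None
    pvalue: float | None = None
    gene_label: str | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if not self.variant_id:
            raise ValidationError("variant_id must be non-empty")
        if not math.isfinite(self.beta):
            raise ValidationError(f"{self.variant_id}: beta must be finite")
        if not (math.isfinite(self.se) and self.se > 0):
            raise ValidationError(f"{self.variant_id}: se must be > 0, got {self.se}")
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            raise ValidationError(f"{self.variant_id}: eaf must lie in (0, 1), got {self.eaf}")
        if self.pvalue is not None and not (0.0 < self.pvalue <= 1.0):
            raise ValidationError(f"{self.variant_id}: pvalue must lie in (0, 1], got {self.pvalue}")

    @property
    def z(self) -> float:
        return self.beta / self.se


@dataclass(frozen=True)
class InstrumentTable:
    """Ordered per-variant associations for one trait.

    ``variance_explained`` is the fraction of trait variance jointly
    explained by the instruments, when known (used for power calculations).
    """

    trait_id: str
    records: tuple[VariantAssociation, ...]
    variance_explained: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        seen: set[str] = set()
        for rec in self.records:
            if rec.trait_id != self.trait_id:
                raise ValidationError(
                    f"record {rec.variant_id} has trait {rec.trait_id!r}, table is {self.trait_id!r}"
                )
            if rec.variant_id in seen:
                raise ValidationError(f"duplicate variant {rec.variant_id} in table {self.trait_id!r}")
            seen.add(rec.variant_id)
        if self.variance_explained is not None and not (0.0 <= self.variance_explained <= 1.0):
            raise ValidationError("variance_explained must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VariantAssociation]:
        return iter(self.records)

    @property
    def variant_ids(self) -> tuple[str, ...]:
        return tuple(rec.variant_id for rec in self.records)

    def get(self, variant_id: str) -> VariantAssociation:
        for rec in self.records:
            if rec.variant_id == variant_id:
                return rec
        raise KeyError(variant_id)

    def subset(self, variant_ids: Sequence[str]) -> "InstrumentTable":
        """Table restricted to ``variant_ids``, preserving this table's order."""
        wanted = set(variant_ids)
        missing = wanted - set(self.variant_ids)
        if missing:
            raise KeyError(f"variants not in table {self.trait_id!r}: {sorted(missing)}")
        return replace(self, records=tuple(r for r in self.records if r.variant_id in wanted))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": [r.variant_id for r in self.records],
                "effect_allele": [r.effect_allele for r in self.records],
                "other_allele": [r.other_allele for r in self.records],
                "eaf": [r.eaf for r in self.records],
                "beta": [r.beta for r in self.records],
                "se": [r.se for r in self.records],
                "pvalue": [r.pvalue for r in self.records],
                "trait": self.trait_id,
                "n": [r.n for r in self.records],
            }
        )


@dataclass(frozen=True)
class HarmonizedPair:
    """An allele-aligned exposure/outcome association pair for one variant.

    ``beta_exposure`` is in SD units per allele, ``beta_outcome`` in
    log-odds per allele, both expressed against the same effect allele.
    ``flipped`` records that the outcome association was sign-inverted
    relative to its source orientation.
    """

    variant_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    flipped: bool = False
    palindromic: bool = False

    def __post_init__(self) -> None:
        if self.se_exposure <= 0 or self.se_outcome <= 0:
            raise ValidationError(f"{self.variant_id}: standard errors must be > 0")


@dataclass(frozen=True)
class HarmonizedSet:
    """Aligned exposure/outcome pairs for one MR analysis.

    May be empty (e.g. after palindromic exclusions); each estimator
    enforces its own minimum variant count.
    """

    exposure_id: str
    outcome_id: str
    pairs: tuple[HarmonizedPair, ...]
    instrument_set_label: str = "custom"

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", tuple(self.pairs))
        ids = [p.variant_id for p in self.pairs]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate variant_ids in HarmonizedSet")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[HarmonizedPair]:
        return iter(self.pairs)

    @property
    def variant_ids(self) -> tuple[str, ...]:
        return tuple(p.variant_id for p in self.pairs)

    def drop(self, variant_ids: Sequence[str]) -> "HarmonizedSet":
        """Set with the named variants removed (for exclusion sensitivity runs)."""
        dropped = set(variant_ids)
        kept = tuple(p for p in self.pairs if p.variant_id not in dropped)
        if not kept:
            raise ValidationError("exclusion would remove every variant")
        return replace(self, pairs=kept)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": [p.variant_id for p in self.pairs],
                "beta_exposure": [p.beta_exposure for p in self.pairs],
                "se_exposure": [p.se_exposure for p in self.pairs],
                "beta_outcome": [p.beta_outcome for p in self.pairs],
                "se_outcome": [p.se_outcome for p in self.pairs],
                "flipped": [p.flipped for p in self.pairs],
            }
        )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

DEFAULT_COLUMNS = {
    "variant_id": "variant_id",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pvalue": "pvalue",
    "trait": "trait",
    "n": "n",
    "gene": "gene",
}

_MANDATORY = ("variant_id", "beta", "se")


def _parse_float(text: object, what: str, row: int) -> float | None:
    if text is None or (isinstance(text, float) and math.isnan(text)):
        return None
    s = str(text).strip()
    if s in ("", "NA", "NaN", "nan", "."):
        return None
    try:
        return float(s)  # locale-independent: always decimal point
    except ValueError:
        raise ValidationError(f"row {row}: non-numeric {what}: {s!r}") from None


def _parse_p(text: object, row: int) -> float | None:
    value = _parse_float(text, "pvalue", row)
    if value is None:
        return None
    if value == 0.0:
        s = str(text).strip().lower()
        # a syntactically positive literal that underflowed double precision
        if not s.startswith("-") and not s.startswith("0e") and s not in ("0", "0.0"):
            return _TINY_P
    return value


def read_association_table(
    path: str | Path,
    trait_id: str | None = None,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
    permissive: bool = False,
    variance_explained: float | None = None,
) -> InstrumentTable:
    """Read one trait's associations from a delimited text file.

    Parameters
    ----------
    path
        Tab-separated file with a header row; pass ``sep=","`` for CSV
        (``.csv`` suffixes switch automatically).
    trait_id
        Trait to extract.  Required when the file has no trait column or
        contains several traits; defaults to the single trait found.
    column_map
        Mapping from the canonical names (``variant_id``, ``beta``, ``se``,
        ...) to the column names actually present in the file.
    permissive
        Drop (with a log entry) rows with missing beta or se instead of
        raising.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    columns = dict(DEFAULT_COLUMNS)
    if column_map:
        columns.update(column_map)

    frame = pd.read_csv(path, sep=sep, dtype=str)
    for key in _MANDATORY:
        if columns[key] not in frame.columns:
            raise ValidationError(f"mandatory column {columns[key]!r} ({key}) not found in {path.name}")

    def col(key: str) -> pd.Series | None:
        name = columns[key]
        return frame[name] if name in frame.columns else None

    trait_col = col("trait")
    if trait_col is not None:
        traits = sorted(trait_col.dropna().unique())
        if trait_id is None:
            if len(traits) > 1:
                raise ValidationError(f"{path.name} contains several traits {traits}; pass trait_id")
            trait_id = traits[0] if traits else "trait"
        mask = trait_col == trait_id
        frame = frame[mask]
    elif trait_id is None:
        raise ValidationError("trait_id is required when the file has no trait column")

    records: list[VariantAssociation] = []
    for idx, row in frame.iterrows():
        rownum = int(idx) + 2  # 1-based with header
        variant = str(row[columns["variant_id"]]).strip()
        beta = _parse_float(row.get(columns["beta"]), "beta", rownum)
        se = _parse_float(row.get(columns["se"]), "se", rownum)
        if beta is None or se is None:
            if permissive:
                logger.warning("%s row %d (%s): missing beta/se, dropped", path.name, rownum, variant)
                continue
            raise ValidationError(f"row {rownum} ({variant}): missing beta or se")
        kwargs = {}
        for key in ("eaf",):
            series = col(key)
            if series is not None:
                kwargs[key] = _parse_float(row.get(columns[key]), key, rownum)
        pser = col("pvalue")
        pvalue = _parse_p(row.get(columns["pvalue"]), rownum) if pser is not None else None
        nser = col("n")
        n_raw = _parse_float(row.get(columns["n"]), "n", rownum) if nser is not None else None
        ea = row.get(columns["effect_allele"]) if col("effect_allele") is not None else None
        oa = row.get(columns["other_allele"]) if col("other_allele") is not None else None
        gene = row.get(columns["gene"]) if col("gene") is not None else None
        try:
            records.append(
                VariantAssociation(
                    variant_id=variant,
                    trait_id=trait_id,
                    beta=beta,
                    se=se,
                    effect_allele=None if pd.isna(ea) else str(ea).strip().upper() or None,
                    other_allele=None if pd.isna(oa) else str(oa).strip().upper() or None,
                    eaf=kwargs.get("eaf"),
                    pvalue=pvalue,
                    gene_label=None if pd.isna(gene) else str(gene).strip(),
                    n=None if n_raw is None else int(n_raw),
                )
            )
        except ValidationError as err:
            raise ValidationError(f"row {rownum}: {err}") from None
    try:
        return InstrumentTable(trait_id=trait_id, records=tuple(records), variance_explained=variance_explained)
    except ValidationError as err:
        raise ValidationError(f"{path.name}: {err}") from None


def write_association_table(table: InstrumentTable, path: str | Path, sep: str = "\t") -> None:
    table.to_frame().to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Instrument selection
# ---------------------------------------------------------------------------


def _pair_r2(correlations, a: str, b: str) -> float | None:
    if correlations is None:
        return None
    if isinstance(correlations, pd.DataFrame):
        if a in correlations.index and b in correlations.columns:
            return float(correlations.loc[a, b])
        return None
    for key in ((a, b), (b, a)):
        if key in correlations:
            return float(correlations[key])
    return None


def select_instruments(
    table: InstrumentTable,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.01,
    correlations: Mapping[tuple[str, str], float] | pd.DataFrame | None = None,
) -> InstrumentTable:
    """Keep genome-wide-significant, mutually independent variants.

    Variants with ``p < p_threshold`` are retained; among each pair with
    ``r**2 >= r2_threshold`` only the variant with the smaller p-value is
    kept (ties broken by smaller SE, then lexicographic ID).  When no
    correlation matrix is supplied all variants are assumed independent.
    """
    if not (0.0 < p_threshold < 1.0):
        raise ValidationError("p_threshold must lie in (0, 1)")

    significant = []
    for rec in table:
        if rec.pvalue is None:
            logger.warning("%s: no p-value, excluded from selection", rec.variant_id)
            continue
        if rec.pvalue < p_threshold:
            significant.append(rec)

    if correlations is None:
        if len(significant) > 1:
            logger.warning(
                "no correlation matrix supplied for %s; assuming the %d variants are independent",
                table.trait_id,
                len(significant),
            )
        kept = significant
    else:
        order = sorted(significant, key=lambda r: (r.pvalue, r.se, r.variant_id))
        kept_ids: list[str] = []
        for rec in order:
            clash = False
            for other in kept_ids:
                r2 = _pair_r2(correlations, rec.variant_id, other)
                if r2 is None:
                    raise ValidationError(
                        f"correlation matrix lacks pair ({rec.variant_id}, {other})"
                    )
                if r2 >= r2_threshold:
                    clash = True
                    break
            if not clash:
                kept_ids.append(rec.variant_id)
        keep = set(kept_ids)
        kept = [rec for rec in significant if rec.variant_id in keep]

    keep_ids = {rec.variant_id for rec in kept}
    return replace(table, records=tuple(r for r in table.records if r.variant_id in keep_ids))


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------


def _try_align(e_ea: str, e_oa: str | None, o_ea: str, o_oa: str | None) -> bool | None:
    """Alignment of one strand reading: False=as-is, True=flip, None=no match."""
    if o_ea == e_ea and (o_oa is None or e_oa is None or o_oa == e_oa):
        return False
    if e_oa is not None and o_ea == e_oa and (o_oa is None or o_oa == e_ea):
        return True
    if e_oa is None and o_oa is not None and o_oa == e_ea and o_ea != e_ea:
        return True
    return None


def _match_orientation(exp: VariantAssociation, out: VariantAssociation) -> bool:
    """Return True if the outcome association must be sign-flipped.

    The direct strand reading is tried first, then the complementary
    strand (summary files from different consortia differ in strand
    convention).  Missing other-allele codes restrict matching to the
    effect alleles alone.
    """
    e_ea, e_oa = exp.effect_allele, exp.other_allele
    o_ea, o_oa = out.effect_allele, out.other_allele
    if e_ea is None or o_ea is None:
        raise ValidationError(f"{exp.variant_id}: effect alleles required for harmonization")
    readings = [(o_ea, o_oa)]
    c_ea = _complement(o_ea)
    if c_ea is not None:
        readings.append((c_ea, _complement(o_oa) if o_oa else None))
    for ea, oa in readings:
        result = _try_align(e_ea, e_oa, ea, oa)
        if result is not None:
            return result
    raise ValidationError(
        f"{exp.variant_id}: alleles incompatible under any strand "
        f"(exposure {e_ea}/{e_oa}, outcome {o_ea}/{o_oa})"
    )


def harmonize(
    exposure: InstrumentTable,
    outcome: InstrumentTable,
    palindromic_policy: str = "eaf",
    eaf_window: float = 0.08,
    instrument_set_label: str = "custom",
) -> HarmonizedSet:
    """Align outcome effect alleles to the exposure orientation.

    Only variants present in both tables are kept, in exposure-table order.
    When the outcome effect allele matches the exposure's other allele
    (directly or as a strand complement) the outcome beta sign is flipped.

    Palindromic (A/T, C/G) variants are handled per ``palindromic_policy``:

    ``strict``
        raise :class:`ValidationError`;
    ``drop``
        exclude with a log entry;
    ``eaf``
        align by effect-allele-frequency side when both EAFs lie outside
        ``[0.5 - eaf_window, 0.5 + eaf_window]``, else exclude.
    """
    if palindromic_policy not in ("strict", "eaf", "drop"):
        raise ValidationError(f"unknown palindromic policy {palindromic_policy!r}")

    outcome_by_id = {rec.variant_id: rec for rec in outcome}
    pairs: list[HarmonizedPair] = []
    for exp in exposure:
        out = outcome_by_id.get(exp.variant_id)
        if out is None:
            continue
        palindromic = is_palindromic(exp.effect_allele, exp.other_allele) or is_palindromic(
            out.effect_allele, out.other_allele
        )
        if palindromic:
            if palindromic_policy == "strict":
                raise ValidationError(f"{exp.variant_id}: palindromic variant under strict policy")
            if palindromic_policy == "drop":
                logger.info("%s: palindromic variant dropped", exp.variant_id)
                continue
            flipped = _palindromic_flip_by_eaf(exp, out, eaf_window)
            if flipped is None:
                logger.info("%s: palindromic variant with uninformative EAF, excluded", exp.variant_id)
                continue
        else:
            flipped = _match_orientation(exp, out)
        gamma = -out.beta if flipped else out.beta
        pairs.append(
            HarmonizedPair(
                variant_id=exp.variant_id,
                beta_exposure=exp.beta,
                se_exposure=exp.se,
                beta_outcome=gamma,
                se_outcome=out.se,
                flipped=flipped,
                palindromic=palindromic,
            )
        )
    return HarmonizedSet(
        exposure_id=exposure.trait_id,
        outcome_id=outcome.trait_id,
        pairs=tuple(pairs),
        instrument_set_label=instrument_set_label,
    )


def _palindromic_flip_by_eaf(
    exp: VariantAssociation, out: VariantAssociation, eaf_window: float
) -> bool | None:
    """EAF-side matching for palindromic variants; None means undecidable."""
    if exp.eaf is None or out.eaf is None:
        return None
    lo, hi = 0.5 - eaf_window, 0.5 + eaf_window
    if lo <= exp.eaf <= hi or lo <= out.eaf <= hi:
        return None
    return (exp.eaf < 0.5) != (out.eaf < 0.5)


# ---------------------------------------------------------------------------
# Back-derivation from published odds ratios
# ---------------------------------------------------------------------------


def backfill_from_ratio(
    or_point: float, ci_low: float, ci_high: float, beta_exposure: float
) -> tuple[float, float]:
    """Recover a per-variant outcome association from an OR and 95% CI.

    A published per-variant odds ratio per SD of exposure is the
    exponentiated first-order Wald ratio ``theta = gamma / beta``.  Given
    the exposure beta, the outcome log-odds association and its SE are::

        theta    = ln(or_point)
        se_theta = (ln(ci_high) - ln(ci_low)) / (2 * 1.959964)
        gamma    = theta * beta_exposure
        se_gamma = se_theta * |beta_exposure|

    The CI is assumed to be a symmetric 95% normal interval on the log
    scale (as produced by standard MR software).
    """
    if not (0.0 < ci_low <= or_point <= ci_high):
        raise ValidationError(
            f"invalid OR/CI ordering: need 0 < {ci_low} <= {or_point} <= {ci_high}"
        )
    if ci_low == ci_high:
        raise ValidationError("zero-width confidence interval gives se = 0")
    if beta_exposure == 0.0:
        raise ValidationError("beta_exposure must be nonzero")
    theta = math.log(or_point)
    se_theta = (math.log(ci_high) - math.log(ci_low)) / (2.0 * Z_95)
    return theta * beta_exposure, se_theta * abs(beta_exposure)
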