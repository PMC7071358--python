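"""Bundled case study: iron-status instruments and liver/brain cancer outcomes.

The package ships a small, fully text-based dataset for a two-sample MR
analysis of systemic iron status and cancer risk:

* ``iron_instruments.tsv`` -- genome-wide-significant instruments for four
  iron-status biomarkers (serum iron, transferrin saturation, log10
  ferritin, serum transferrin) from a European-ancestry GWAS of 48,972
  individuals, in SD units per effect allele.  Three variants --
  rs1800562 and rs1799945 in *HFE* and rs855791 in *TMPRSS6* -- are the
  primary instruments; they are mutually independent (r-squared < 0.01)
  and carry most of the instrumented variance.
* ``cancer_per_variant_or.tsv`` -- published per-variant odds ratios
  (with 95% CIs) of liver and brain cancer per SD of each biomarker,
  estimated in a cohort of 367,643 European-descent participants
  (324 liver and 810 brain cancer cases).  Per-variant outcome log-odds
  associations are back-derived from these rows with
  :func:`ironmr.summary_data.backfill_from_ratio`.
* ``cancer_reference_estimates.tsv`` -- the published pooled estimates
  (IVW random effects, weighted median, MR-Egger, heterogeneity,
  pleiotropy intercept) used by :func:`ironmr.pipeline.reproduce_tables`
  as comparison references.

Note: the biomarker labelled ``transferrin`` is serum transferrin (g/L);
its betas are negative for the three primary variants because high iron
status suppresses transferrin production.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .summary_data import (
    HarmonizedPair,
    HarmonizedSet,
    InstrumentTable,
    backfill_from_ratio,
    read_association_table,
)

#: The three primary instruments for all four iron-status biomarkers.
PRIMARY_VARIANTS = ("rs1800562", "rs1799945", "rs855791")

EXPOSURES = ("serum_iron", "transferrin_saturation", "log10_ferritin", "transferrin")
OUTCOMES = ("liver_cancer", "brain_cancer")

#: Fraction of biomarker variance explained by all its instruments.
VARIANCE_EXPLAINED = {
    "serum_iron": 0.034,
    "transferrin_saturation": 0.069,
    "log10_ferritin": 0.009,
    "transferrin": 0.072,
}

#: Outcome-cohort design constants for the case study.
EXPOSURE_GWAS_N = 48_972
OUTCOME_COHORT_N = 367_643
CASE_COUNTS = {"liver_cancer": 324, "brain_cancer": 810, "overall_cancer": 75_037}


def _data_path(name: str) -> Path:
    return Path(resources.files("ironmr").joinpath("data", name))


def exposure_tables() -> dict[str, InstrumentTable]:
    """All four iron-biomarker instrument tables, keyed by trait id."""
    path = _data_path("iron_instruments.tsv")
    return {
        trait: read_association_table(
            path, trait_id=trait, variance_explained=VARIANCE_EXPLAINED[trait]
        )
        for trait in EXPOSURES
    }


def outcome_ratios() -> pd.DataFrame:
    """Published per-variant OR/CI rows for liver and brain cancer."""
    return pd.read_csv(_data_path("cancer_per_variant_or.tsv"), sep="\t")


def reference_estimates() -> pd.DataFrame:
    """Published pooled estimates used as comparison references."""
    return pd.read_csv(_data_path("cancer_reference_estimates.tsv"), sep="\t")


def harmonized_sets(instrument_set_label: str = "primary-3snp") -> dict[tuple[str, str], HarmonizedSet]:
    """Aligned exposure/outcome pairs for every biomarker x cancer analysis.

    Outcome associations are back-derived from the per-variant OR rows, so
    each set carries the three primary variants.  Keys are
    ``(exposure_id, outcome_id)`` tuples.
    """
    exposures = exposure_tables()
    ratios = outcome_ratios()
    sets: dict[tuple[str, str], HarmonizedSet] = {}
    for (outcome, exposure), block in ratios.groupby(["outcome", "exposure"], sort=False):
        table = exposures[exposure]
        rows = {r.variant_id: r for r in block.itertuples()}
        pairs = []
        for variant_id in PRIMARY_VARIANTS:
            row = rows[variant_id]
            exp = table.get(variant_id)
            gamma, se_gamma = backfill_from_ratio(row.or_point, row.ci_low, row.ci_high, exp.beta)
            pairs.append(
                HarmonizedPair(
                    variant_id=variant_id,
                    beta_exposure=exp.beta,
                    se_exposure=exp.se,
                    beta_outcome=gamma,
                    se_outcome=se_gamma,
                )
            )
        sets[(exposure, outcome)] = HarmonizedSet(
            exposure_id=exposure,
            outcome_id=outcome,
            pairs=tuple(pairs),
            instrument_set_label=instrument_set_label,
        )
    return sets
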