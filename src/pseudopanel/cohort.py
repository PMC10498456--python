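"""Cohort tables and summary statistics.

Ships the nine-proband cohort (clinical-feature statuses, demographics,
per-family allele labels) as editable TSV fixtures and computes the summary
numbers with N/A-aware denominators: a feature's denominator counts only
patients whose status is known.  Percentages round half-up at one decimal.

Qualified entries are coded by their leading sign — "- (only fingers and
elbows)" is negative, "+(shoulder)" positive — with the qualifier retained
as free text.  Composite gastrointestinal categories (perforation,
diverticulitis, gallstones, ...) are prose in the source table, so they are
derived by an explicit, user-editable keyword mapping.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "CohortTable",
    "load_cohort",
    "feature_frequency",
    "cohort_demographics",
    "tnxa_derived_family_fraction",
    "percent_of_normal",
    "composite_feature_counts",
    "round_half_up",
]

_TNXA_CLASSES = {"fusion_type1", "fusion_type2", "conversion_type1", "conversion_type2"}


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (22.12 -> 22.1, 36.28 -> 36.3)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CohortTable:
    features: pd.DataFrame      # one row per patient; feature columns hold status|detail
    alleles: pd.DataFrame       # family_id, allele_1, allele_2

    def feature_names(self) -> list[str]:
        skip = {"patient_id", "sex", "age", "deceased", "ethnicity"}
        return [c for c in self.features.columns if c not in skip]


def _data_path(name: str) -> Path:
    return Path(str(resources.files("pseudopanel").joinpath("data", name)))


def load_cohort(features_path: str | Path | None = None,
                alleles_path: str | Path | None = None) -> CohortTable:
    features = pd.read_csv(features_path or _data_path("cohort_features.tsv"),
                           sep="\t", dtype=str)
    alleles = pd.read_csv(alleles_path or _data_path("cohort_alleles.tsv"),
                          sep="\t", dtype=str)
    allowed = {"+", "-", "na"}
    for col in [c for c in features.columns
                if c not in {"patient_id", "sex", "age", "deceased", "ethnicity"}]:
        statuses = features[col].map(_status)
        bad = set(statuses) - allowed
        if bad:
            raise ValueError(f"column {col!r} has unknown statuses {bad}")
    return CohortTable(features, alleles)


def _status(cell: str) -> str:
    """Leading status code of a cell like '+|shoulder' or '-|only fingers'."""
    if cell is None or pd.isna(cell):
        return "na"
    return str(cell).split("|", 1)[0].strip()


def feature_frequency(table: CohortTable, feature: str) -> tuple[int, int, float | None]:
    """(numerator, denominator, percent) with an N/A-aware denominator.

    Returns percent None (undefined) when every status is unknown.
    """
    if feature not in table.features.columns:
        raise KeyError(f"unknown feature {feature!r}; available: "
                       f"{table.feature_names()}")
    statuses = table.features[feature].map(_status)
    num = int((statuses == "+").sum())
    den = int((statuses != "na").sum())
    if den == 0:
        return 0, 0, None
    return num, den, round_half_up(100.0 * num / den)


def cohort_demographics(table: CohortTable) -> tuple[float, float]:
    """(percent female to one decimal, median age at last observation).

    Deceased patients contribute their age at death.
    """
    ages = table.features["age"].astype(float)
    if ages.isna().any():
        raise ValueError("ages must be present for all patients")
    n = len(table.features)
    n_female = int((table.features["sex"].str.lower() == "female").sum())
    return round_half_up(100.0 * n_female / n), float(ages.median())


def tnxa_derived_family_fraction(table: CohortTable) -> tuple[int, int, float]:
    """Families with at least one pseudogene-derived (fusion or conversion)
    allele, over all families."""
    def family_has(row) -> bool:
        return any(str(row[c]).split("(", 1)[0] in _TNXA_CLASSES
                   for c in ("allele_1", "allele_2"))

    with_tnxa = int(table.alleles.apply(family_has, axis=1).sum())
    total = len(table.alleles)
    pct = round_half_up(100.0 * with_tnxa / total) if total else 0.0
    return with_tnxa, total, pct


def percent_of_normal(mean_conc: float, control_conc: float) -> float:
    """Serum-protein concentration as a percent of the normal control,
    rounded half-up at one decimal."""
    if control_conc <= 0:
        raise ValueError("control concentration must be > 0")
    return round_half_up(100.0 * mean_conc / control_conc)


def composite_feature_counts(table: CohortTable,
                             mapping_path: str | Path | None = None,
                             columns: tuple[str, ...] = ("gastrointestinal", "hematoma"),
                             ) -> dict[str, int]:
    """Count patients matching each keyword-defined composite category.

    The mapping ships as an editable YAML file because the source table
    stores these categories as prose; which entries count toward e.g.
    'diverticulitis' is an editorial choice the user can revise.
    """
    with open(mapping_path or _data_path("composite_keywords.yaml")) as fh:
        mapping = yaml.safe_load(fh)
    counts = {cat: 0 for cat in mapping}
    for _, row in table.features.iterrows():
        texts = {c: str(row.get(c, "") or "").lower() for c in columns}
        for cat, rule in mapping.items():
            keywords = rule["keywords"] if isinstance(rule, dict) else rule
            cols = rule.get("columns", list(columns)) if isinstance(rule, dict) else columns
            text = " ".join(texts.get(c, "") for c in cols)
            if any(kw.lower() in text for kw in keywords):
                counts[cat] += 1
    return counts
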