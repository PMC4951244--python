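"""Somatic SNV catalog: functional-class filter, burden and recurrence summaries.

Works on annotated SNV tables with one row per somatic variant carrying a
tumor identifier, a gene symbol and a SeattleSeq-style functional class.
Missense rows additionally carry a 1-based protein position and the reference
and alternate amino acids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: The ten annotation classes considered potentially functional.
FUNCTIONAL_CLASSES: frozenset[str] = frozenset(
    {
        "coding-synonymous-near-splice",
        "missense",
        "missense-near-splice",
        "splice-3",
        "splice-5",
        "stop-gained",
        "stop-gained-near-splice",
        "stop-lost",
        "utr-3",
        "utr-5",
    }
)

#: Classes accepted in input tables but removed by the functional filter.
NONFUNCTIONAL_CLASSES: frozenset[str] = frozenset(
    {
        "intron",
        "coding-synonymous",
        "intergenic",
        "near-gene-3",
        "near-gene-5",
        "non-coding-exon",
    }
)

KNOWN_CLASSES: frozenset[str] = FUNCTIONAL_CLASSES | NONFUNCTIONAL_CLASSES

MUTATION_COLUMNS = ["tumor_id", "gene", "class", "protein_pos", "ref_aa", "alt_aa"]


def filter_functional(records: pd.DataFrame) -> pd.DataFrame:
    """Keep only potentially functional SNVs.

    Retains exactly the ten functional annotation classes, preserving row
    order. Rows with a class string outside the known vocabulary are dropped
    with a warning rather than treated as functional.
    """
    if records.empty:
        return records.copy()
    cls = records["class"]
    unknown = sorted(set(cls) - KNOWN_CLASSES)
    if unknown:
        logger.warning(
            "dropping %d records with unknown functional class(es): %s",
            int(cls.isin(unknown).sum()),
            ", ".join(unknown),
        )
    return records[cls.isin(FUNCTIONAL_CLASSES)].copy()


@dataclass(frozen=True)
class BurdenSummary:
    """Per-group burden of functional SNVs (or of distinct mutated genes)."""

    level: str  # "snv" or "gene"
    per_tumor: pd.Series  # tumor_id -> count
    totals: dict[str, int]
    medians: dict[str, float]
    ranges: dict[str, tuple[int, int]]
    median_difference: float
    p_value: float


def _mann_whitney(x, y) -> float:
    """Two-sided Mann-Whitney p: exact when both groups have <= 8 values,
    tie-corrected normal approximation otherwise."""
    import numpy as np

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):  # every observation tied: no evidence
        return 1.0
    method = "exact" if (len(x) <= 8 and len(y) <= 8) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def per_tumor_counts(
    records: pd.DataFrame, clinical: pd.DataFrame, level: str = "snv"
) -> pd.Series:
    """Functional SNVs (``level='snv'``) or distinct mutated genes
    (``level='gene'``) per tumor; tumors without records count 0."""
    if level == "snv":
        counts = records.groupby("tumor_id").size()
    elif level == "gene":
        counts = records.groupby("tumor_id")["gene"].nunique()
    else:
        raise ValueError(f"unknown level {level!r}")
    return counts.reindex(clinical["patient_id"], fill_value=0).astype(int)


def burden_by_group(
    records: pd.DataFrame, clinical: pd.DataFrame, level: str = "snv"
) -> BurdenSummary:
    """Compare per-tumor mutation burden between prognosis groups.

    ``clinical`` must carry ``patient_id`` and ``group`` (good/poor) columns
    and must cover every tumor_id present in ``records``.
    """
    known = set(clinical["patient_id"])
    stray = set(records["tumor_id"]) - known
    if stray:
        raise ValueError(f"tumors absent from clinical table: {sorted(stray)}")
    counts = per_tumor_counts(records, clinical, level=level)
    groups = clinical.set_index("patient_id")["group"]
    by_group = {g: counts[groups == g] for g in ("good", "poor")}
    for g, vals in by_group.items():
        if len(vals) < 1:
            raise ValueError(f"group {g!r} has no tumors")
    medians = {g: float(v.median()) for g, v in by_group.items()}
    return BurdenSummary(
        level=level,
        per_tumor=counts,
        totals={g: int(v.sum()) for g, v in by_group.items()},
        medians=medians,
        ranges={g: (int(v.min()), int(v.max())) for g, v in by_group.items()},
        median_difference=medians["good"] - medians["poor"],
        p_value=_mann_whitney(by_group["good"], by_group["poor"]),
    )


@dataclass(frozen=True)
class RecurrenceSummary:
    """Recurrently mutated genes and SNVs, split by group exclusivity."""

    recurrent_shared: list[str]
    good_exclusive: list[str]
    poor_exclusive: list[str]
    recurrent_snvs: pd.DataFrame  # gene, protein_pos, ref_aa, alt_aa, n_tumors
    min_tumors: int


def recurrence_exclusivity(
    records: pd.DataFrame,
    clinical: pd.DataFrame,
    min_tumors: int = 3,
    min_recurrence: int = 2,
) -> RecurrenceSummary:
    """Group-exclusive recurrently mutated genes and recurrent SNVs.

    A gene is group-exclusive at threshold ``min_tumors`` (k) if it is
    mutated in >= k tumors of one group and in none of the other; genes
    recurrently mutated (>= k tumors overall) in both groups are "shared".
    A SNV (gene + protein position + amino-acid change) is recurrent if seen
    in >= ``min_recurrence`` tumors.
    """
    if min_tumors < 2:
        raise ValueError("min_tumors must be >= 2")
    groups = clinical.set_index("patient_id")["group"]
    recs = records.assign(group=records["tumor_id"].map(groups))
    # distinct tumors per gene per group
    per_gene = (
        recs.drop_duplicates(["tumor_id", "gene"])
        .groupby(["gene", "group"])["tumor_id"]
        .nunique()
        .unstack(fill_value=0)
        .reindex(columns=["good", "poor"], fill_value=0)
    )
    total = per_gene["good"] + per_gene["poor"]
    good_excl = per_gene[(per_gene["good"] >= min_tumors) & (per_gene["poor"] == 0)]
    poor_excl = per_gene[(per_gene["poor"] >= min_tumors) & (per_gene["good"] == 0)]
    shared = per_gene[
        (total >= min_tumors) & (per_gene["good"] > 0) & (per_gene["poor"] > 0)
    ]

    missense = recs.dropna(subset=["protein_pos", "ref_aa", "alt_aa"])
    snv_counts = (
        missense.drop_duplicates(["tumor_id", "gene", "protein_pos", "ref_aa", "alt_aa"])
        .groupby(["gene", "protein_pos", "ref_aa", "alt_aa"])
        .size()
        .rename("n_tumors")
        .reset_index()
    )
    recurrent_snvs = snv_counts[snv_counts["n_tumors"] >= min_recurrence].reset_index(
        drop=True
    )
    return RecurrenceSummary(
        recurrent_shared=sorted(shared.index),
        good_exclusive=sorted(good_excl.index),
        poor_exclusive=sorted(poor_excl.index),
        recurrent_snvs=recurrent_snvs,
        min_tumors=min_tumors,
    )


def read_mutations(path) -> pd.DataFrame:
    """Read a mutations.tsv table (tumor_id, gene, class, protein_pos, ref_aa, alt_aa)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"tumor_id": str, "gene": str})
    missing = set(MUTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"mutations table missing columns: {sorted(missing)}")
    return df


def read_clinical(path) -> pd.DataFrame:
    """Read a clinical.tsv table (patient_id, event, time_months, group, cms_label)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"patient_id": str})
    missing = {"patient_id", "event", "time_months", "group"} - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    return df
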