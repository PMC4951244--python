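"""Gene-set mutation-burden scores with a permuted-label significance test.

For every tumor and gene set, the burden score is the number of that tumor's
functional SNVs falling in set genes divided by the set size. Group scores
(good vs poor prognosis) are aggregated over the group's tumors and compared
with a label-permutation test sized so the smallest attainable p-value clears
a Bonferroni correction over all sets tested.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_MIN_PERMUTATIONS = 999
#: Exhaustive enumeration is used when the number of distinct label
#: assignments does not exceed this bound.
EXHAUSTIVE_LIMIT = 20_000


@dataclass(frozen=True)
class GeneSet:
    name: str
    source: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass(frozen=True)
class PathwayScoreResult:
    name: str
    source: str
    score_good: float
    score_poor: float
    dif_score: float
    p_value: float
    n_permutations: int


class GMTParseError(ValueError):
    pass


def load_gmt(path) -> list[GeneSet]:
    """Parse a GMT file (name<TAB>description<TAB>gene...), one set per line.

    Duplicate genes within a line are collapsed; duplicate set names are an
    error. The description field is kept as the set's source label.
    """
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTParseError(
                    f"{path}: line {lineno} has {len(fields)} fields, expected >= 3"
                )
            name, source = fields[0], fields[1]
            if name in seen:
                raise GMTParseError(f"{path}: duplicate gene set name {name!r}")
            seen.add(name)
            genes = frozenset(g for g in fields[2:] if g)
            sets.append(GeneSet(name=name, source=source, genes=genes))
    return sets


def tumor_set_score(tumor_genes: Sequence[str], gene_set: GeneSet) -> float:
    """Mutation-burden score of one tumor for one gene set.

    ``tumor_genes`` is the list of genes hit by the tumor's functional SNVs,
    one entry per SNV: multiple mutations in the same set gene all count.
    """
    hits = sum(1 for g in tumor_genes if g in gene_set.genes)
    return hits / len(gene_set.genes)


def group_scores(
    per_tumor_scores: pd.Series,
    clinical: pd.DataFrame,
    aggregator: str = "sum",
) -> tuple[float, float, float]:
    """Aggregate per-tumor scores into (score_good, score_poor, dif_score).

    ``dif_score = score_poor - score_good``; the aggregator is a sum over the
    group's tumors by default (a group's total in-set mutations divided by the
    set size), with a per-tumor mean as the alternative.
    """
    groups = clinical.set_index("patient_id")["group"]
    vals = {g: per_tumor_scores[groups[groups == g].index] for g in ("good", "poor")}
    for g, v in vals.items():
        if len(v) == 0:
            raise ValueError(f"group {g!r} is empty")
    if aggregator == "sum":
        sg, sp = float(vals["good"].sum()), float(vals["poor"].sum())
    elif aggregator == "mean":
        sg, sp = float(vals["good"].mean()), float(vals["poor"].mean())
    else:
        raise ValueError(f"unknown aggregator {aggregator!r}")
    return sg, sp, sp - sg


def required_permutations(n_sets: int, alpha: float = 0.05) -> int:
    """Smallest n such that the minimum attainable add-one p-value 1/(n+1)
    clears the Bonferroni threshold alpha / n_sets."""
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    return math.ceil(n_sets / alpha) - 1


def _group_stat(scores: np.ndarray, is_poor: np.ndarray, aggregator: str) -> float:
    if aggregator == "sum":
        return float(scores[is_poor].sum() - scores[~is_poor].sum())
    return float(scores[is_poor].mean() - scores[~is_poor].mean())


def permutation_test(
    per_tumor_scores: Sequence[float],
    labels: Sequence[str],
    n_sets: int = 1,
    alpha: float = 0.05,
    seed: int | None = 0,
    aggregator: str = "sum",
    min_permutations: int = DEFAULT_MIN_PERMUTATIONS,
    mode: str = "auto",
) -> tuple[float, int]:
    """Two-sided permuted-label p-value for the group score difference.

    Permutations shuffle the good/poor labels while preserving group sizes.
    On small cohorts (number of distinct assignments <= ``EXHAUSTIVE_LIMIT``)
    all assignments are enumerated and the p-value is the exact fraction with
    ``|dif*| >= |dif_observed|``. Otherwise Monte Carlo sampling is used with
    the add-one convention ``p = (1 + #extreme) / (n_permutations + 1)`` and
    ``n_permutations = max(min_permutations, ceil(n_sets / alpha) - 1)`` so
    that the smallest attainable p-value survives a Bonferroni correction
    over ``n_sets`` tests at level ``alpha``.
    """
    scores = np.asarray(per_tumor_scores, dtype=float)
    labels = np.asarray(labels)
    is_poor = labels == "poor"
    n = len(scores)
    n_poor = int(is_poor.sum())
    if n_poor < 2 or (n - n_poor) < 2:
        raise ValueError("need at least 2 tumors in each group")

    if mode not in ("auto", "exhaustive", "monte-carlo"):
        raise ValueError(f"unknown mode {mode!r}")
    observed = abs(_group_stat(scores, is_poor, aggregator))
    n_assignments = math.comb(n, n_poor)
    if mode == "exhaustive" or (mode == "auto" and n_assignments <= EXHAUSTIVE_LIMIT):
        extreme = 0
        for idx in combinations(range(n), n_poor):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            if abs(_group_stat(scores, mask, aggregator)) >= observed - 1e-12:
                extreme += 1
        return extreme / n_assignments, n_assignments

    n_perm = max(min_permutations, required_permutations(n_sets, alpha))
    rng = np.random.default_rng(seed)
    extreme = 0
    # permute in blocks to bound memory
    block = 4096
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        perm = np.argsort(rng.random((b, n)), axis=1)[:, :n_poor]
        mask = np.zeros((b, n), dtype=bool)
        np.put_along_axis(mask, perm, True, axis=1)
        if aggregator == "sum":
            stat = (scores * mask).sum(axis=1) - (scores * ~mask).sum(axis=1)
        else:
            stat = (scores * mask).sum(axis=1) / n_poor - (scores * ~mask).sum(
                axis=1
            ) / (n - n_poor)
        extreme += int((np.abs(stat) >= observed - 1e-12).sum())
        done += b
    return (1 + extreme) / (n_perm + 1), n_perm


def score_gene_sets(
    records: pd.DataFrame,
    clinical: pd.DataFrame,
    gene_sets: Sequence[GeneSet],
    alpha: float = 0.05,
    seed: int = 0,
    aggregator: str = "sum",
) -> pd.DataFrame:
    """Score every gene set and test group differences; returns a table with
    columns function, source, score_good, score_poor, dif_score, p_val."""
    tumor_genes = {
        t: list(g) for t, g in records.groupby("tumor_id")["gene"]
    }
    patients = list(clinical["patient_id"])
    labels = clinical.set_index("patient_id")["group"].loc[patients].to_numpy()
    rows = []
    for i, gs in enumerate(gene_sets):
        scores = pd.Series(
            [tumor_set_score(tumor_genes.get(p, []), gs) for p in patients],
            index=patients,
            dtype=float,
        )
        sg, sp, dif = group_scores(scores, clinical, aggregator=aggregator)
        p, n_perm = permutation_test(
            scores.to_numpy(),
            labels,
            n_sets=len(gene_sets),
            alpha=alpha,
            seed=None if seed is None else seed + i,
            aggregator=aggregator,
        )
        rows.append(
            PathwayScoreResult(gs.name, gs.source, sg, sp, dif, p, n_perm)
        )
    return pd.DataFrame(
        {
            "function": [r.name for r in rows],
            "source": [r.source for r in rows],
            "score_good": [r.score_good for r in rows],
            "score_poor": [r.score_poor for r in rows],
            "dif_score": [r.dif_score for r in rows],
            "p_val": [r.p_value for r in rows],
            "n_permutations": [r.n_permutations for r in rows],
        }
    )
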