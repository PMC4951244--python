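"""Confidence-filtered protein-protein interaction network and centrality.

Mutated genes are mapped onto a PPI network built from a HIPPIE-style edge
list (interactor A, interactor B, confidence score); only high-confidence
edges (score strictly above the threshold) are retained. Degree, betweenness,
closeness and eccentricity are computed per gene within its connected
component, and per-measure group differences are assessed with a two-sided
Mann-Whitney test on per-tumor mean centralities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .catalog import _mann_whitney

logger = logging.getLogger(__name__)

CENTRALITY_MEASURES = ("degree", "betweenness", "closeness", "eccentricity")


class PPIParseError(ValueError):
    pass


def load_ppi(path, min_score: float = 0.72) -> nx.Graph:
    """Build an undirected PPI graph keeping edges with score > ``min_score``.

    Duplicate edges keep the maximum score; self-loops are dropped. The input
    is a TSV whose first two columns are gene symbols and whose third column
    is a numeric confidence in [0, 1]; a leading header line is tolerated.
    """
    graph = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise PPIParseError(f"{path}: line {lineno}: expected >= 3 columns")
            a, b, raw = fields[0], fields[1], fields[2]
            try:
                score = float(raw)
            except ValueError:
                if lineno == 1:  # header
                    continue
                raise PPIParseError(
                    f"{path}: line {lineno}: non-numeric score {raw!r}"
                ) from None
            if a == b:
                continue
            if score > min_score:
                if graph.has_edge(a, b):
                    graph[a][b]["score"] = max(graph[a][b]["score"], score)
                else:
                    graph.add_edge(a, b, score=score)
    return graph


@dataclass(frozen=True)
class CentralityProfile:
    gene: str
    degree: int
    betweenness: float
    closeness: float
    eccentricity: int


def centrality(
    graph: nx.Graph, genes=None
) -> tuple[pd.DataFrame, list[str]]:
    """Shortest-path centralities for the requested genes.

    Betweenness is unnormalized; closeness and eccentricity are computed
    within each gene's connected component (closeness = (n_c - 1) / sum of
    distances to the component's other nodes). Genes absent from the network
    are returned in the unmapped list, never zero-filled.

    Returns (profiles table indexed by gene, unmapped gene list).
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("network is empty")
    requested = list(genes) if genes is not None else list(graph.nodes)
    mapped = [g for g in requested if g in graph]
    unmapped = [g for g in requested if g not in graph]

    betweenness = nx.betweenness_centrality(graph, normalized=False)
    closeness: dict[str, float] = {}
    eccentricity: dict[str, int] = {}
    for comp in nx.connected_components(graph):
        sub = graph.subgraph(comp)
        closeness.update(nx.closeness_centrality(sub, wf_improved=False))
        if len(comp) > 1:
            eccentricity.update(nx.eccentricity(sub))

    rows = []
    for g in mapped:
        rows.append(
            {
                "gene": g,
                "degree": graph.degree[g],
                "betweenness": betweenness[g],
                "closeness": closeness[g],
                "eccentricity": eccentricity.get(g),
            }
        )
    profiles = pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame(
        columns=["degree", "betweenness", "closeness", "eccentricity"]
    )
    return profiles, unmapped


def compare_group_centrality(
    profiles: pd.DataFrame,
    records: pd.DataFrame,
    clinical: pd.DataFrame,
    aggregation: str = "per-tumor-mean",
) -> pd.DataFrame:
    """Per-measure two-sided Mann-Whitney p-values between prognosis groups.

    Default aggregation summarizes each tumor by the mean centrality of its
    mapped mutated genes; ``aggregation='pooled'`` instead pools one value
    per (tumor, gene) pair. Tumors with no mapped genes are excluded and
    logged.
    """
    groups = clinical.set_index("patient_id")["group"]
    mapped = records[records["gene"].isin(profiles.index)]
    if aggregation == "per-tumor-mean":
        per_tumor = {
            measure: mapped.drop_duplicates(["tumor_id", "gene"])
            .groupby("tumor_id")["gene"]
            .apply(lambda gs: profiles.loc[list(gs), measure].mean())
            for measure in CENTRALITY_MEASURES
        }
        excluded = set(clinical["patient_id"]) - set(
            per_tumor["degree"].index
        )
        if excluded:
            logger.info(
                "excluding %d tumors with no network-mapped mutated genes",
                len(excluded),
            )
        rows = []
        for measure, vals in per_tumor.items():
            vals = vals.dropna()
            g = vals[vals.index.map(groups) == "good"]
            p = vals[vals.index.map(groups) == "poor"]
            if len(g) < 2 or len(p) < 2:
                raise ValueError("need at least 2 tumors per group")
            rows.append({"measure": measure, "p_value": _mann_whitney(g, p)})
        return pd.DataFrame(rows)
    if aggregation == "pooled":
        pairs = mapped.drop_duplicates(["tumor_id", "gene"]).assign(
            group=lambda d: d["tumor_id"].map(groups)
        )
        rows = []
        for measure in CENTRALITY_MEASURES:
            vals = profiles.loc[pairs["gene"], measure].to_numpy()
            good = vals[(pairs["group"] == "good").to_numpy()]
            poor = vals[(pairs["group"] == "poor").to_numpy()]
            rows.append(
                {"measure": measure, "p_value": _mann_whitney(good, poor)}
            )
        return pd.DataFrame(rows)
    raise ValueError(f"unknown aggregation {aggregation!r}")
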