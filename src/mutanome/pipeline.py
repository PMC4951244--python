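"""End-to-end orchestration: simulate (or load) a cohort, then run the
mutation catalog, pathway burden, interactome, neoantigen and immune
survival stages, writing per-stage TSVs and a machine-readable summary."""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd

from . import catalog, network, pathways, synthetic
from . import neoantigen as neo
from . import survival as surv
from .config import CohortConfig, PipelineConfig

logger = logging.getLogger(__name__)


def _provenance_write(df: pd.DataFrame, path: Path, config_hash: str, index=False):
    with open(path, "w") as fh:
        fh.write(f"# pipeline_config={config_hash}\n")
        df.to_csv(fh, sep="\t", index=index)


def run_all(
    config: PipelineConfig | None = None,
    outdir="results/pipeline",
    gene_sets: list[pathways.GeneSet] | None = None,
    ppi_edges: pd.DataFrame | None = None,
    predictor: neo.AffinityPredictor | None = None,
) -> dict:
    """Run every stage on a synthetic cohort and return the summary dict.

    Identical config (and seed) reproduces the output bundle byte for byte.
    External inputs can replace the synthetic gene sets, PPI edge list or
    affinity predictor; the cohort itself comes from the embedded simulator.
    """
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()

    logger.info("simulating cohort (%d patients)", config.cohort.n_patients)
    cohort = synthetic.generate_cohort(config.cohort)
    synthetic.write_cohort(cohort, outdir)
    clinical = cohort.clinical
    patients = cohort.patients

    # --- mutation catalog ---------------------------------------------------
    functional = catalog.filter_functional(cohort.mutations)
    burden_snv = catalog.burden_by_group(functional, clinical, level="snv")
    burden_gene = catalog.burden_by_group(functional, clinical, level="gene")
    recurrence = catalog.recurrence_exclusivity(
        functional, clinical, min_tumors=config.exclusivity_k,
        min_recurrence=config.min_recurrence,
    )
    burden_rows = []
    for b in (burden_snv, burden_gene):
        for g in ("good", "poor"):
            burden_rows.append(
                {
                    "level": b.level,
                    "group": g,
                    "total": b.totals[g],
                    "median": b.medians[g],
                    "min": b.ranges[g][0],
                    "max": b.ranges[g][1],
                    "mannwhitney_p": b.p_value,
                }
            )
    _provenance_write(pd.DataFrame(burden_rows), outdir / "burden_summary.tsv", chash)
    gene_lists = pd.DataFrame(
        [
            {"list": "recurrent_shared", "gene": g}
            for g in recurrence.recurrent_shared
        ]
        + [{"list": "good_exclusive", "gene": g} for g in recurrence.good_exclusive]
        + [{"list": "poor_exclusive", "gene": g} for g in recurrence.poor_exclusive],
        columns=["list", "gene"],
    )
    _provenance_write(gene_lists, outdir / "gene_lists.tsv", chash)

    # --- pathway burden -----------------------------------------------------
    if gene_sets is None:
        gene_sets = synthetic.generate_gene_sets(config.cohort)
        synthetic.write_gmt(gene_sets, outdir / "gene_sets.gmt")
    pathway_scores = pathways.score_gene_sets(
        functional, clinical, gene_sets, alpha=config.alpha, seed=config.seed,
        aggregator=config.score_aggregator,
    )
    _provenance_write(pathway_scores, outdir / "pathway_scores.tsv", chash)

    # --- interactome --------------------------------------------------------
    if ppi_edges is None:
        ppi_edges = synthetic.generate_ppi(config.cohort)
        synthetic.write_ppi(ppi_edges, outdir / "ppi_edges.tsv")
        graph = network.load_ppi(outdir / "ppi_edges.tsv", config.min_ppi_score)
    else:
        import tempfile

        with tempfile.NamedTemporaryFile("w", suffix=".tsv", delete=False) as fh:
            ppi_edges.to_csv(fh, sep="\t", index=False)
            graph = network.load_ppi(fh.name, config.min_ppi_score)
    mutated_genes = sorted(functional["gene"].unique())
    profiles, unmapped = network.centrality(graph, mutated_genes)
    _provenance_write(profiles, outdir / "centrality.tsv", chash, index=True)
    group_comparison = network.compare_group_centrality(profiles, functional, clinical)
    _provenance_write(group_comparison, outdir / "group_comparison.tsv", chash)

    # --- neoantigens --------------------------------------------------------
    predictor = predictor or neo.ToyAffinityPredictor()
    epitopes, counts = neo.call_cohort_epitopes(
        cohort.mutations,
        cohort.proteome,
        cohort.hla,
        predictor,
        k_range=config.kmer_range,
        ic50_mut_max=config.ic50_mut_max,
        ic50_wt_min=config.ic50_wt_min,
    )
    counts = counts.reindex(patients, fill_value=0)
    _provenance_write(
        epitopes[epitopes["immunogenic"]], outdir / "epitopes.tsv", chash
    )
    expr_counts = neo.expression_aware_counts(epitopes, cohort.expression).reindex(
        patients, fill_value=0
    )
    counts_df = pd.DataFrame(
        {
            "patient_id": patients,
            "neoantigens": counts.to_numpy(),
            "neoantigens_expressed": expr_counts.to_numpy(),
        }
    )
    _provenance_write(counts_df, outdir / "neoantigen_counts.tsv", chash)
    extremes = neo.extremes_summary(
        counts, clinical, low=0, high=config.neoantigen_high_cut
    )
    groups = clinical.set_index("patient_id")["group"]
    counts_mw_p = catalog._mann_whitney(
        counts[groups[groups == "good"].index], counts[groups[groups == "poor"].index]
    )

    # --- immune survival ----------------------------------------------------
    expression = cohort.expression
    surv_rows = []
    for gene in surv.PRESENTATION_GENES + surv.CLASS_II_GENES:
        res = surv.survival_by_quartiles(expression, gene, clinical)
        surv_rows.append(
            {
                "gene": gene,
                "stratum": "all",
                "n": res["n"],
                "logrank_p": res["logrank_p"],
                "cox_coef": res["cox_coef"],
                "cox_p": res["cox_p"],
            }
        )
    cd8a_labels = surv.cd8a_stratify(expression, patients, rule=config.cd8a_rule)
    cd8a_strat = surv.stratified_survival(
        expression, clinical, cd8a_labels, min_n=config.cms_min_n
    )
    cd8a_strat = cd8a_strat.assign(stratum="CD8A_" + cd8a_strat["stratum"].astype(str))
    cms_strat = surv.cms_stratified_analysis(
        expression, clinical, min_n=config.cms_min_n
    )
    parts = [
        df for df in (pd.DataFrame(surv_rows), cd8a_strat, cms_strat) if not df.empty
    ]
    surv_table = pd.concat(parts, ignore_index=True)[
        ["gene", "stratum", "n", "logrank_p", "cox_coef", "cox_p"]
    ]
    _provenance_write(surv_table, outdir / "survival_results.tsv", chash)

    paired = {
        gene: surv.paired_tumor_normal_test(expression, gene)
        for gene in surv.PRESENTATION_GENES + ("CD8A",)
    }
    cd8a_vals = surv.tumor_values(expression, "CD8A", patients)
    cd8a_t, cd8a_p = surv.welch_group_test(cd8a_vals, clinical)

    features = pd.DataFrame(
        {"neoantigen_count": counts.astype(float)}, index=patients
    )
    for gene in surv.IMMUNE_PANEL:
        features[gene] = surv.tumor_values(expression, gene, patients)
    coords, evr, loadings = surv.pca_immune(features)
    _provenance_write(
        coords.rename_axis("patient_id"), outdir / "pca_coords.tsv", chash, index=True
    )

    # Cox on the planted immune covariates (parameter recovery at cohort scale)
    covars = pd.DataFrame(
        {
            "presentation_score": synthetic.presentation_score(expression, patients),
            "neoantigen_count": counts.astype(float),
        }
    )
    cox = surv.cox_fit(
        covars.reset_index(drop=True),
        clinical.set_index("patient_id").loc[patients, "time_months"],
        clinical.set_index("patient_id").loc[patients, "event"],
    )

    summary = {
        "config_hash": chash,
        "n_patients": len(patients),
        "n_relapse": int(clinical["event"].sum()),
        "snv": {
            "total_functional": int(len(functional)),
            "median_good": burden_snv.medians["good"],
            "median_poor": burden_snv.medians["poor"],
            "range_good": list(burden_snv.ranges["good"]),
            "range_poor": list(burden_snv.ranges["poor"]),
            "mannwhitney_p": burden_snv.p_value,
        },
        "genes": {
            "median_good": burden_gene.medians["good"],
            "median_poor": burden_gene.medians["poor"],
            "mannwhitney_p": burden_gene.p_value,
        },
        "recurrence": {
            "n_recurrent_snvs": int(len(recurrence.recurrent_snvs)),
            "n_good_exclusive": len(recurrence.good_exclusive),
            "n_poor_exclusive": len(recurrence.poor_exclusive),
            "n_recurrent_shared": len(recurrence.recurrent_shared),
        },
        "pathways": {
            "n_sets": len(gene_sets),
            "n_permutations": int(pathway_scores["n_permutations"].iloc[0]),
            "min_p": float(pathway_scores["p_val"].min()),
            "max_abs_dif_score": float(pathway_scores["dif_score"].abs().max()),
        },
        "interactome": {
            "n_nodes": graph.number_of_nodes(),
            "n_edges": graph.number_of_edges(),
            "n_unmapped_genes": len(unmapped),
            "centrality_p": {
                r["measure"]: r["p_value"] for _, r in group_comparison.iterrows()
            },
        },
        "neoantigens": {
            "total": int(counts.sum()),
            "median": float(counts.median()),
            "max": int(counts.max()),
            "mannwhitney_p_by_group": counts_mw_p,
            "extremes": extremes.to_dict(orient="records"),
        },
        "survival": {
            "cox_presentation_coef": float(cox.loc["presentation_score", "coef"]),
            "cox_presentation_p": float(cox.loc["presentation_score", "p"]),
            "cox_neoantigen_coef": float(cox.loc["neoantigen_count", "coef"]),
            "cox_neoantigen_p": float(cox.loc["neoantigen_count", "p"]),
            "cd8a_welch_t": cd8a_t,
            "cd8a_welch_p": cd8a_p,
            "paired_tumor_normal": {
                g: {"mean_diff": d, "p": p} for g, (d, p) in paired.items()
            },
            "pca_var_explained_pc1": float(evr[0]),
            "pca_var_explained_pc2": float(evr[1]),
        },
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(outdir / "config.json", "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=2, sort_keys=True, default=list)
        fh.write("\n")
    return summary


def config_from_yaml(path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file; unknown keys are an error."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cohort_raw = raw.pop("cohort", {})
    if "protein_length_range" in cohort_raw:
        cohort_raw["protein_length_range"] = tuple(cohort_raw["protein_length_range"])
    if "hla_allele_pool" in cohort_raw:
        cohort_raw["hla_allele_pool"] = tuple(cohort_raw["hla_allele_pool"])
    if "kmer_range" in raw:
        raw["kmer_range"] = tuple(raw["kmer_range"])
    cohort = CohortConfig(**cohort_raw)
    return PipelineConfig(cohort=cohort, **raw)
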