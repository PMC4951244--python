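#!/usr/bin/env python
"""Immune-gene expression, T-cell infiltration and outcome.

Quartile Kaplan-Meier / log-rank and Cox analyses of the antigen-presentation
panel (HLA-A/B/C, TAP1, TAP2) and HLA class II genes; CD8A-based high/low
stratification; consensus-molecular-subtype stratified reanalysis; paired
tumor-vs-mucosa tests; PCA over the immune feature block."""

from pathlib import Path

import pandas as pd

from mutanome import catalog
from mutanome import survival as surv
from mutanome.synthetic import read_expression

COHORT = Path("results/cohort")
OUT = Path("results")


def main() -> None:
    expression = read_expression(COHORT / "expression.tsv")
    clinical = catalog.read_clinical(COHORT / "clinical.tsv")
    patients = list(clinical["patient_id"])
    counts = pd.read_csv(OUT / "neoantigen_counts.tsv", sep="\t").set_index("patient_id")

    rows = []
    for gene in surv.PRESENTATION_GENES + surv.CLASS_II_GENES:
        res = surv.survival_by_quartiles(expression, gene, clinical)
        rows.append({"gene": gene, "stratum": "all", "n": res["n"],
                     "logrank_p": res["logrank_p"], "cox_coef": res["cox_coef"],
                     "cox_p": res["cox_p"]})
        print(f"{gene}: quartile log-rank p = {res['logrank_p']:.3f}, "
              f"Cox coef = {res['cox_coef']:+.2f} (p = {res['cox_p']:.3f})")

    cd8a = surv.cd8a_stratify(expression, patients, rule="upper-quartile")
    print(f"CD8A upper-quartile split: {int((cd8a == 'high').sum())} high, "
          f"{int((cd8a == 'low').sum())} low")
    strat = surv.stratified_survival(expression, clinical, cd8a)
    strat = strat.assign(stratum="CD8A_" + strat["stratum"].astype(str))
    cms = surv.cms_stratified_analysis(expression, clinical)
    table = pd.concat([pd.DataFrame(rows)] + [d for d in (strat, cms) if not d.empty],
                      ignore_index=True)
    table.to_csv(OUT / "survival_results.tsv", sep="\t", index=False)

    print("paired tumor vs adjacent mucosa (mean log2 difference, p):")
    for gene in surv.PRESENTATION_GENES + ("CD8A",):
        diff, p = surv.paired_tumor_normal_test(expression, gene)
        print(f"  {gene}: {diff:+.2f} (p = {p:.2e})")

    features = pd.DataFrame(
        {"neoantigen_count": counts.loc[patients, "neoantigens"].astype(float)},
        index=patients,
    )
    for gene in surv.IMMUNE_PANEL:
        features[gene] = surv.tumor_values(expression, gene, patients)
    coords, evr, _ = surv.pca_immune(features)
    coords.rename_axis("patient_id").to_csv(OUT / "pca_coords.tsv", sep="\t")
    print(f"PCA: PC1 {evr[0]:.0%}, PC2 {evr[1]:.0%} of variance")


if __name__ == "__main__":
    main()
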