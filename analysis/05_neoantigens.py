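#!/usr/bin/env python
"""HLA-restricted neoantigen calling with the differential-affinity filter.

Expands every missense mutation into a 21-mer window, scores all 8-11-mers
overlapping the mutation against the patient's HLA-A/B alleles, and calls a
peptide immunogenic when the mutant binds strongly (IC50 < 50 nM) while the
wild type does not (IC50 > 500 nM) on the same allele. Tabulates relapse at
the extremes of the per-tumor neoantigen count."""

from pathlib import Path

import pandas as pd

from mutanome import catalog
from mutanome import neoantigen as neo
from mutanome.synthetic import read_expression, read_proteome_fasta

COHORT = Path("results/cohort")
OUT = Path("results")


def main() -> None:
    mutations = catalog.read_mutations(COHORT / "mutations.tsv")
    clinical = catalog.read_clinical(COHORT / "clinical.tsv")
    proteome = read_proteome_fasta(COHORT / "proteome.fasta")
    genotypes = neo.parse_hla(COHORT / "hla.tsv")

    predictor = neo.ToyAffinityPredictor()
    epitopes, counts = neo.call_cohort_epitopes(mutations, proteome, genotypes, predictor)
    counts = counts.reindex(clinical["patient_id"], fill_value=0)
    epitopes[epitopes["immunogenic"]].to_csv(OUT / "epitopes.tsv", sep="\t", index=False)

    expression = read_expression(COHORT / "expression.tsv")
    expressed = neo.expression_aware_counts(epitopes, expression).reindex(
        clinical["patient_id"], fill_value=0
    )
    pd.DataFrame(
        {"patient_id": clinical["patient_id"], "neoantigens": counts.to_numpy(),
         "neoantigens_expressed": expressed.to_numpy()}
    ).to_csv(OUT / "neoantigen_counts.tsv", sep="\t", index=False)

    print(f"predicted neoantigens per tumor: median {counts.median():.0f}, "
          f"max {counts.max()}")
    groups = clinical.set_index("patient_id")["group"]
    mw_p = catalog._mann_whitney(
        counts[groups[groups == "good"].index], counts[groups[groups == "poor"].index]
    )
    print(f"good vs poor neoantigen count: Mann-Whitney p = {mw_p:.2f}")

    extremes = neo.extremes_summary(counts, clinical, low=0, high=8)
    extremes.to_csv(OUT / "neoantigen_extremes.tsv", sep="\t", index=False)
    for row in extremes.itertuples():
        print(f"{row.stratum}: {row.n_relapsed}/{row.n_tumors} relapsed")


if __name__ == "__main__":
    main()
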