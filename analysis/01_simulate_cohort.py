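#!/usr/bin/env python
"""Simulate the study cohort: 42 microsatellite-stable stage II colon tumors
(21 relapse / 21 no relapse expected), ~90 functional somatic SNVs per tumor,
HLA-A/B genotypes, paired tumor/normal immune-gene expression and relapse
outcomes driven by planted immune covariates. Writes every downstream input
under results/cohort/."""

from pathlib import Path

from mutanome.config import CohortConfig
from mutanome import synthetic

OUT = Path("results/cohort")


def main(seed: int = 1) -> None:
    cohort = synthetic.generate_cohort(CohortConfig(seed=seed))
    paths = synthetic.write_cohort(cohort, OUT)
    synthetic.write_gmt(synthetic.generate_gene_sets(cohort.config), OUT / "gene_sets.gmt")
    synthetic.write_ppi(synthetic.generate_ppi(cohort.config), OUT / "ppi_edges.tsv")

    from mutanome.catalog import filter_functional

    clin = cohort.clinical
    print(f"cohort: {len(clin)} patients, {int(clin['event'].sum())} relapsed")
    per_tumor = filter_functional(cohort.mutations).groupby("tumor_id").size()
    print(
        "functional SNVs per tumor: "
        f"median {per_tumor.median():.0f}, range {per_tumor.min()}-{per_tumor.max()}"
    )
    print(
        "neoantigen load: median "
        f"{cohort.neoantigen_counts.median():.0f}, max {cohort.neoantigen_counts.max()}"
    )
    print("wrote:", ", ".join(str(p) for p in paths.values()))


if __name__ == "__main__":
    main()
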