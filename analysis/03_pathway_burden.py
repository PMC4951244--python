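#!/usr/bin/env python
"""Gene-set mutation-burden scores with a permuted-label null.

Per tumor and gene set: in-set functional SNVs divided by set size; group
scores are sums over the good / poor tumors and their difference is tested by
permuting tumor labels, with the permutation count sized for a Bonferroni
correction over all sets."""

from pathlib import Path

from mutanome import catalog, pathways

COHORT = Path("results/cohort")
OUT = Path("results")


def main(seed: int = 1) -> None:
    records = catalog.filter_functional(catalog.read_mutations(COHORT / "mutations.tsv"))
    clinical = catalog.read_clinical(COHORT / "clinical.tsv")
    gene_sets = pathways.load_gmt(COHORT / "gene_sets.gmt")

    scores = pathways.score_gene_sets(records, clinical, gene_sets, seed=seed)
    scores.to_csv(OUT / "pathway_scores.tsv", sep="\t", index=False)

    print(f"{len(gene_sets)} gene sets, {scores['n_permutations'].iloc[0]} permutations each")
    top = scores.reindex(scores["dif_score"].abs().sort_values(ascending=False).index)
    print("largest group differences:")
    print(
        top.head(5)[["function", "score_good", "score_poor", "dif_score", "p_val"]]
        .round(3)
        .to_string(index=False)
    )
    n_sig = int((scores["p_val"] < 0.05 / len(gene_sets)).sum())
    print(f"{n_sig} sets pass the Bonferroni threshold at alpha 0.05")


if __name__ == "__main__":
    main()
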