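#!/usr/bin/env python
"""Functional SNV burden by prognosis group, recurrence and exclusivity.

Applies the ten-class functional filter, compares per-tumor SNV and mutated-
gene counts between good- and poor-prognosis tumors (Mann-Whitney), and lists
recurrently and group-exclusively mutated genes."""

from pathlib import Path

import pandas as pd

from mutanome import catalog

COHORT = Path("results/cohort")
OUT = Path("results")


def main() -> None:
    records = catalog.filter_functional(catalog.read_mutations(COHORT / "mutations.tsv"))
    clinical = catalog.read_clinical(COHORT / "clinical.tsv")

    rows = []
    for level in ("snv", "gene"):
        b = catalog.burden_by_group(records, clinical, level=level)
        print(
            f"{level}-level burden: good median {b.medians['good']:.0f} "
            f"(range {b.ranges['good'][0]}-{b.ranges['good'][1]}), "
            f"poor median {b.medians['poor']:.0f} "
            f"(range {b.ranges['poor'][0]}-{b.ranges['poor'][1]}), "
            f"Mann-Whitney p = {b.p_value:.2f}"
        )
        for g in ("good", "poor"):
            rows.append(
                {"level": level, "group": g, "total": b.totals[g],
                 "median": b.medians[g], "min": b.ranges[g][0], "max": b.ranges[g][1],
                 "mannwhitney_p": b.p_value}
            )
    pd.DataFrame(rows).to_csv(OUT / "burden_summary.tsv", sep="\t", index=False)

    rec = catalog.recurrence_exclusivity(records, clinical, min_tumors=3)
    print(
        f"recurrent SNVs (>=2 tumors): {len(rec.recurrent_snvs)}; "
        f"good-exclusive genes (k=3): {len(rec.good_exclusive)}; "
        f"poor-exclusive: {len(rec.poor_exclusive)}"
    )
    lists = pd.DataFrame(
        [{"list": "recurrent_shared", "gene": g} for g in rec.recurrent_shared]
        + [{"list": "good_exclusive", "gene": g} for g in rec.good_exclusive]
        + [{"list": "poor_exclusive", "gene": g} for g in rec.poor_exclusive],
        columns=["list", "gene"],
    )
    lists.to_csv(OUT / "gene_lists.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
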