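"""Self-consistent synthetic tumor cohort generator.

Emulates a stage II microsatellite-stable colon-cancer study end to end:
a canonical-isoform proteome, per-tumor somatic SNV tables (functional and
non-functional annotation classes), HLA-A/B genotypes, paired tumor/normal
log-expression with planted tumor under-expression of HLA class I and CD8A,
gene sets and a confidence-scored interaction network, and relapse outcomes
drawn from an exponential proportional-hazards model whose log hazard ratios
on antigen-presentation expression and predicted neoantigen load are
configurable. Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .catalog import FUNCTIONAL_CLASSES, NONFUNCTIONAL_CLASSES
from .config import CohortConfig, ConfigurationError
from .neoantigen import HLAGenotype, ToyAffinityPredictor, call_cohort_epitopes
from .pathways import GeneSet
from .survival import CLASS_II_GENES, IMMUNE_PANEL, PRESENTATION_GENES

logger = logging.getLogger(__name__)

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: Relative frequencies of the functional annotation classes among somatic
#: exome SNVs; missense dominates, UTR classes follow, splice/stop are rare.
FUNCTIONAL_CLASS_PROBS: dict[str, float] = {
    "missense": 0.55,
    "missense-near-splice": 0.02,
    "coding-synonymous-near-splice": 0.02,
    "splice-3": 0.01,
    "splice-5": 0.01,
    "stop-gained": 0.04,
    "stop-gained-near-splice": 0.005,
    "stop-lost": 0.005,
    "utr-3": 0.20,
    "utr-5": 0.14,
}
assert set(FUNCTIONAL_CLASS_PROBS) == set(FUNCTIONAL_CLASSES)
assert abs(sum(FUNCTIONAL_CLASS_PROBS.values()) - 1.0) < 1e-9

#: Strength of the shared per-patient immune-activity factor on the tumor
#: expression of presentation genes and CD8A (log2 units).
IMMUNE_FACTOR_LOADING = 0.5
#: Genes carrying the planted tumor-vs-normal under-expression shift.
SHIFTED_GENES = ("HLA-A", "HLA-B", "HLA-C", "CD8A")

CMS_PROBS = {"CMS1": 0.15, "CMS2": 0.35, "CMS3": 0.20, "CMS4": 0.30}


@dataclass
class SyntheticCohort:
    """A complete synthetic study, ready for every downstream stage."""

    config: CohortConfig
    proteome: dict[str, str]
    mutations: pd.DataFrame
    hla: dict[str, HLAGenotype]
    expression: pd.DataFrame
    clinical: pd.DataFrame
    neoantigen_counts: pd.Series = field(default=None)
    epitopes: pd.DataFrame = field(default=None)

    @property
    def patients(self) -> list[str]:
        return list(self.clinical["patient_id"])


def _patient_ids(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"P{i + 1:0{width}d}" for i in range(n)]


def generate_proteome(config: CohortConfig) -> dict[str, str]:
    """One canonical protein sequence per synthetic gene symbol."""
    lo, hi = config.protein_length_range
    rng = np.random.default_rng([config.seed, 1])
    genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    proteome = {}
    for g in genes:
        length = int(rng.integers(lo, hi + 1))
        proteome[g] = "".join(rng.choice(AMINO_ACIDS, size=length))
    return proteome


def proteome_to_fasta(proteome: dict[str, str]) -> str:
    buf = io.StringIO()
    records = [
        SeqRecord(Seq(seq), id=gene, description="synthetic canonical isoform")
        for gene, seq in proteome.items()
    ]
    SeqIO.write(records, buf, "fasta")
    return buf.getvalue()


def read_proteome_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def generate_mutations(proteome: dict[str, str], config: CohortConfig) -> pd.DataFrame:
    """Somatic SNV table over the cohort.

    Per-tumor functional SNV counts are Poisson around
    ``per_tumor_mutation_rate``; genes are hit proportionally to protein
    length, positions uniformly along the protein, and the alternate amino
    acid uniformly over the 19 non-reference residues. A second Poisson
    stream of non-functional records (intron, intergenic, ...) exercises the
    downstream functional filter.
    """
    if not proteome:
        raise ValueError("proteome is empty")
    rng = np.random.default_rng([config.seed, 2])
    genes = np.array(list(proteome))
    lengths = np.array([len(proteome[g]) for g in genes], dtype=float)
    weights = lengths / lengths.sum()
    func_classes = np.array(list(FUNCTIONAL_CLASS_PROBS))
    func_probs = np.array(list(FUNCTIONAL_CLASS_PROBS.values()))
    nonfunc_classes = np.array(sorted(NONFUNCTIONAL_CLASSES))

    rows = []
    for pid in _patient_ids(config.n_patients):
        n_func = rng.poisson(config.per_tumor_mutation_rate)
        hit_genes = rng.choice(genes, size=n_func, p=weights)
        classes = rng.choice(func_classes, size=n_func, p=func_probs)
        for gene, cls in zip(hit_genes, classes):
            row = {
                "tumor_id": pid,
                "gene": gene,
                "class": cls,
                "protein_pos": np.nan,
                "ref_aa": None,
                "alt_aa": None,
            }
            if cls.startswith("missense"):
                seq = proteome[gene]
                pos = int(rng.integers(1, len(seq) + 1))
                ref = seq[pos - 1]
                alt = str(rng.choice(AMINO_ACIDS[AMINO_ACIDS != ref]))
                row.update(protein_pos=float(pos), ref_aa=ref, alt_aa=alt)
            rows.append(row)
        n_nonfunc = rng.poisson(
            config.per_tumor_mutation_rate * config.nonfunctional_fraction
        )
        for gene, cls in zip(
            rng.choice(genes, size=n_nonfunc, p=weights),
            rng.choice(nonfunc_classes, size=n_nonfunc),
        ):
            rows.append(
                {
                    "tumor_id": pid,
                    "gene": gene,
                    "class": cls,
                    "protein_pos": np.nan,
                    "ref_aa": None,
                    "alt_aa": None,
                }
            )
    return pd.DataFrame(
        rows, columns=["tumor_id", "gene", "class", "protein_pos", "ref_aa", "alt_aa"]
    )


def generate_hla(config: CohortConfig) -> dict[str, HLAGenotype]:
    """Two HLA-A and two HLA-B alleles per patient, drawn with replacement
    from the configured pool; duplicated draws are kept once and flagged
    homozygous."""
    rng = np.random.default_rng([config.seed, 3])
    pool_a = [a for a in config.hla_allele_pool if a.startswith("HLA-A")]
    pool_b = [a for a in config.hla_allele_pool if a.startswith("HLA-B")]
    if not pool_a or not pool_b:
        raise ConfigurationError("hla_allele_pool needs HLA-A and HLA-B alleles")
    genotypes = {}
    for pid in _patient_ids(config.n_patients):
        draws = list(rng.choice(pool_a, size=2)) + list(rng.choice(pool_b, size=2))
        alleles, homo = [], set()
        for a in draws:
            if a in alleles:
                homo.add(a)
            else:
                alleles.append(a)
        genotypes[pid] = HLAGenotype(pid, tuple(alleles), frozenset(homo))
    return genotypes


def generate_expression(config: CohortConfig) -> pd.DataFrame:
    """Paired tumor/normal log2 expression for the immune panel plus all
    synthetic genes.

    A per-patient immune-activity factor loads on the tumor expression of the
    presentation genes and CD8A, coupling antigen presentation and T-cell
    infiltration. HLA-A/B/C and CD8A tumor columns carry the planted
    under-expression shift; TAP1/TAP2 do not.
    """
    rng = np.random.default_rng([config.seed, 4])
    patients = _patient_ids(config.n_patients)
    genes = list(IMMUNE_PANEL) + [f"G{i + 1:04d}" for i in range(config.n_genes)]
    base = pd.Series(rng.normal(8.0, 1.5, size=len(genes)), index=genes)
    base[list(IMMUNE_PANEL)] = rng.normal(10.0, 0.5, size=len(IMMUNE_PANEL))
    patient_effect = rng.normal(0.0, 0.2, size=len(patients))
    immune_factor = rng.normal(0.0, 1.0, size=len(patients))

    data = {}
    immune_loaded = set(PRESENTATION_GENES) | {"CD8A"}
    for j, pid in enumerate(patients):
        noise_t = rng.normal(0.0, config.expression_sd, size=len(genes))
        noise_n = rng.normal(0.0, config.expression_sd, size=len(genes))
        tumor = base.to_numpy() + patient_effect[j] + noise_t
        normal = base.to_numpy() + patient_effect[j] + noise_n
        for i, g in enumerate(genes):
            if g in immune_loaded:
                tumor[i] += IMMUNE_FACTOR_LOADING * immune_factor[j]
            if g in SHIFTED_GENES:
                tumor[i] += config.tumor_shift
        data[f"{pid}_T"] = tumor
        data[f"{pid}_N"] = normal
    return pd.DataFrame(data, index=genes)


def presentation_score(expression: pd.DataFrame, patients) -> pd.Series:
    """Standardized per-patient antigen-presentation expression summary:
    mean of per-gene z-scores of tumor HLA-A/B/C, TAP1, TAP2 expression."""
    cols = [f"{p}_T" for p in patients]
    block = expression.loc[list(PRESENTATION_GENES), cols].astype(float)
    z = block.sub(block.mean(axis=1), axis=0).div(block.std(axis=1, ddof=0), axis=0)
    score = z.mean(axis=0)
    score = (score - score.mean()) / score.std(ddof=0)
    score.index = list(patients)
    return score


def generate_outcomes(covariates: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Relapse outcomes from an exponential proportional-hazards model.

    ``covariates`` is indexed by patient and must carry ``neoantigen_count``
    and ``presentation_score`` columns. The linear predictor applies the
    configured log hazard ratios to the presentation score (per SD) and the
    centered neoantigen count (per neoantigen); the baseline hazard is set so
    the marginal event fraction before administrative censoring at
    ``censoring_time`` months approximates ``relapse_fraction``. The
    prognosis group label is the observed outcome: relapse = poor.
    """
    for col in ("neoantigen_count", "presentation_score"):
        if col not in covariates.columns:
            raise ConfigurationError(f"covariates missing column {col!r}")
    rng = np.random.default_rng([config.seed, 5])
    patients = list(covariates.index)
    counts = covariates["neoantigen_count"].to_numpy(dtype=float)
    score = covariates["presentation_score"].to_numpy(dtype=float)
    lp = config.presentation_effect * score + config.neoantigen_effect * (
        counts - counts.mean()
    )
    if config.censoring_time <= 0:
        clinical = pd.DataFrame(
            {
                "patient_id": patients,
                "event": 0,
                "time_months": 0.0,
                "group": "good",
                "cms_label": _draw_cms(rng, len(patients)),
            }
        )
        return clinical
    frac = min(max(config.relapse_fraction, 1e-6), 1 - 1e-6)
    h0 = -np.log1p(-frac) / config.censoring_time
    t_event = rng.exponential(1.0 / (h0 * np.exp(lp)))
    event = (t_event <= config.censoring_time).astype(int)
    time = np.minimum(t_event, config.censoring_time)
    return pd.DataFrame(
        {
            "patient_id": patients,
            "event": event,
            "time_months": time,
            "group": np.where(event == 1, "poor", "good"),
            "cms_label": _draw_cms(rng, len(patients)),
        }
    )


def _draw_cms(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.choice(list(CMS_PROBS), size=n, p=list(CMS_PROBS.values()))


def generate_gene_sets(
    config: CohortConfig, n_sets: int = 25, size_range: tuple[int, int] = (10, 60)
) -> list[GeneSet]:
    """Random gene sets over the synthetic gene symbols (MSigDB-like)."""
    rng = np.random.default_rng([config.seed, 6])
    genes = np.array([f"G{i + 1:04d}" for i in range(config.n_genes)])
    sources = ["KEGG", "GO", "REACTOME", "BIOCARTA"]
    sets = []
    for i in range(n_sets):
        size = int(rng.integers(size_range[0], min(size_range[1], len(genes)) + 1))
        members = rng.choice(genes, size=size, replace=False)
        sets.append(
            GeneSet(
                name=f"PATHWAY_{i + 1:03d}",
                source=sources[i % len(sources)],
                genes=frozenset(members),
            )
        )
    return sets


def generate_ppi(
    config: CohortConfig, mean_degree: float = 6.0
) -> pd.DataFrame:
    """Random confidence-scored PPI edge list over the synthetic genes.

    Erdos-Renyi topology with confidence scores uniform on [0.4, 1.0], so a
    0.72 threshold removes roughly half the edges.
    """
    rng = np.random.default_rng([config.seed, 7])
    genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    n = len(genes)
    p = min(mean_degree / max(n - 1, 1), 1.0)
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                rows.append(
                    {
                        "interactor_a": genes[i],
                        "interactor_b": genes[j],
                        "score": round(float(rng.uniform(0.4, 1.0)), 3),
                    }
                )
    return pd.DataFrame(rows, columns=["interactor_a", "interactor_b", "score"])


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Generate the full self-consistent cohort.

    The planted outcome model needs each patient's predicted neoantigen load,
    so the epitope pipeline (deterministic toy affinity predictor) runs here
    on the generated mutations and genotypes before outcomes are drawn —
    downstream reanalysis of the cohort reproduces exactly the covariates the
    hazards were built from.
    """
    config = config or CohortConfig()
    proteome = generate_proteome(config)
    mutations = generate_mutations(proteome, config)
    hla = generate_hla(config)
    expression = generate_expression(config)
    predictor = ToyAffinityPredictor()
    epitopes, counts = call_cohort_epitopes(mutations, proteome, hla, predictor)
    patients = _patient_ids(config.n_patients)
    covariates = pd.DataFrame(
        {
            "neoantigen_count": counts.reindex(patients, fill_value=0),
            "presentation_score": presentation_score(expression, patients),
        },
        index=patients,
    )
    clinical = generate_outcomes(covariates, config)
    return SyntheticCohort(
        config=config,
        proteome=proteome,
        mutations=mutations,
        hla=hla,
        expression=expression,
        clinical=clinical,
        neoantigen_counts=covariates["neoantigen_count"],
        epitopes=epitopes,
    )


def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, Path]:
    """Write the cohort to TSV/FASTA files consumed by downstream stages."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["proteome"] = outdir / "proteome.fasta"
    paths["proteome"].write_text(proteome_to_fasta(cohort.proteome))

    header = f"# cohort_config={cohort.config.config_hash()}\n"

    paths["mutations"] = outdir / "mutations.tsv"
    with open(paths["mutations"], "w") as fh:
        fh.write(header)
        cohort.mutations.to_csv(fh, sep="\t", index=False)

    paths["hla"] = outdir / "hla.tsv"
    with open(paths["hla"], "w") as fh:
        fh.write(header)
        fh.write("patient_id\tallele\n")
        for pid, gt in cohort.hla.items():
            for allele in gt.alleles:
                reps = 2 if allele in gt.homozygous else 1
                for _ in range(reps):
                    fh.write(f"{pid}\t{allele}\n")

    paths["expression"] = outdir / "expression.tsv"
    with open(paths["expression"], "w") as fh:
        fh.write(header)
        cohort.expression.rename_axis("gene").to_csv(fh, sep="\t")

    paths["clinical"] = outdir / "clinical.tsv"
    with open(paths["clinical"], "w") as fh:
        fh.write(header)
        cohort.clinical.to_csv(fh, sep="\t", index=False)
    return paths


def write_gmt(gene_sets, path) -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            genes = "\t".join(sorted(gs.genes))
            fh.write(f"{gs.name}\t{gs.source}\t{genes}\n")


def write_ppi(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)
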