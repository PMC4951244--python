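"""Neoantigen calling from missense mutations and HLA class I genotypes.

Each missense mutation is expanded into a 21-residue window centered on the
altered amino acid (truncated at protein termini), paired with its wild-type
counterpart. All 8-11-mers overlapping the mutated residue are scored for
MHC class I binding through a pluggable affinity predictor, and a mutant
peptide is called immunogenic for an allele when it binds strongly
(IC50 < 50 nM) while its wild-type counterpart does not (IC50 > 500 nM) on
the same allele. Per-tumor neoantigen load is the number of distinct
immunogenic mutant peptides.
"""

from __future__ import annotations

import hashlib
import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Protocol, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtri

logger = logging.getLogger(__name__)

IC50_MUT_MAX = 50.0  # nM, strong binder threshold for the mutant peptide
IC50_WT_MIN = 500.0  # nM, weak binder threshold for the wild-type peptide
KMER_RANGE = (8, 11)
WINDOW_FLANK = 10  # 21-mer window: 10 residues either side of the mutation


class RefMismatchError(ValueError):
    """Proteome residue does not match the annotated reference amino acid.

    Signals an isoform or annotation inconsistency; callers skip and log the
    offending record rather than repairing it.
    """


class AlleleParseError(ValueError):
    pass


_ALLELE_RE = re.compile(
    r"^(?:HLA-)?([A-Z]+\d*)\*?(\d{2,3}):?(\d{2,3})(?::\d+)*[A-Z]?$"
)


def normalize_allele(token: str) -> str:
    """Normalize an HLA class I allele token to 4-digit form, e.g.
    ``A0201`` / ``A*02:01`` / ``HLA-A*02:01:01P`` -> ``HLA-A*02:01``."""
    token = token.strip()
    m = _ALLELE_RE.match(token)
    if m is None:
        raise AlleleParseError(f"cannot parse HLA allele token {token!r}")
    locus, group, protein = m.groups()
    return f"HLA-{locus}*{int(group):02d}:{int(protein):02d}"


@dataclass(frozen=True)
class HLAGenotype:
    patient_id: str
    alleles: tuple[str, ...]
    homozygous: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.alleles:
            raise ValueError(f"patient {self.patient_id}: no HLA alleles")


def _collapse(patient_id: str, raw_alleles: Iterable[str]) -> HLAGenotype:
    seen: list[str] = []
    homo: set[str] = set()
    for a in raw_alleles:
        if a in seen:
            homo.add(a)
        else:
            seen.append(a)
    return HLAGenotype(patient_id, tuple(seen), frozenset(homo))


def parse_hla(path) -> dict[str, HLAGenotype]:
    """Parse HLA genotypes from a plain two-column TSV (patient_id, allele).

    Allele names are normalized to 4-digit form; duplicated alleles collapse
    to one entry flagged homozygous. A header line is tolerated.
    """
    per_patient: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise AlleleParseError(f"{path}: line {lineno}: expected 2 columns")
            pid, token = fields[0], fields[1]
            if token.lower() in {"allele", "hla_allele"}:  # header line
                continue
            per_patient.setdefault(pid, []).append(normalize_allele(token))
    return {p: _collapse(p, alleles) for p, alleles in per_patient.items()}


def parse_hlaminer(path, patient_id: str) -> HLAGenotype:
    """Parse a single-sample HLAminer summary (HPTASR-style) into a genotype.

    Keeps the top-ranked allele of each numbered prediction group under each
    ``HLA-<locus>`` heading, truncated to 4-digit resolution.
    """
    alleles: list[str] = []
    in_group = False
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if re.match(r"^HLA-\w+$", stripped):
                in_group = False
                continue
            if re.match(r"^\d+\.$", stripped):
                in_group = True
                continue
            if in_group and stripped:
                token = stripped.split(",")[0].strip()
                alleles.append(normalize_allele(token))
                in_group = False
    if not alleles:
        raise AlleleParseError(f"{path}: no allele predictions found")
    return _collapse(patient_id, alleles)


@dataclass(frozen=True)
class PeptideWindow:
    """A mutant/wild-type peptide window around one missense mutation."""

    mutant_seq: str
    wildtype_seq: str
    mutated_index: int  # 0-based offset of the altered residue
    gene: str = ""
    protein_pos: int = 0

    def __post_init__(self) -> None:
        if len(self.mutant_seq) != len(self.wildtype_seq):
            raise ValueError("mutant and wild-type windows differ in length")
        diffs = [
            i
            for i, (a, b) in enumerate(zip(self.mutant_seq, self.wildtype_seq))
            if a != b
        ]
        if diffs != [self.mutated_index]:
            raise ValueError(
                "window sequences must differ exactly at mutated_index"
            )


def build_window(
    protein_seq: str,
    pos_1based: int,
    ref_aa: str,
    alt_aa: str,
    gene: str = "",
    flank: int = WINDOW_FLANK,
) -> PeptideWindow:
    """21-residue window centered on the mutation (truncated at termini)."""
    if not 1 <= pos_1based <= len(protein_seq):
        raise ValueError(
            f"position {pos_1based} outside protein of length {len(protein_seq)}"
        )
    found = protein_seq[pos_1based - 1]
    if found != ref_aa:
        raise RefMismatchError(
            f"{gene or 'protein'} position {pos_1based}: proteome has "
            f"{found!r}, annotation says {ref_aa!r}"
        )
    start = max(1, pos_1based - flank)
    end = min(len(protein_seq), pos_1based + flank)
    wt = protein_seq[start - 1 : end]
    idx = pos_1based - start
    mut = wt[:idx] + alt_aa + wt[idx + 1 :]
    return PeptideWindow(mut, wt, idx, gene=gene, protein_pos=pos_1based)


def enumerate_kmer_pairs(
    window: PeptideWindow, k_range: tuple[int, int] = KMER_RANGE
) -> list[tuple[str, str]]:
    """All (mutant k-mer, wild-type k-mer) pairs overlapping the mutation.

    For each k in ``k_range`` every k-window of the peptide that covers the
    mutated residue yields one pair; identical pairs arising from repeated
    sequence are deduplicated, order of first occurrence preserved.
    """
    lo, hi = k_range
    n = len(window.mutant_seq)
    idx = window.mutated_index
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for k in range(lo, hi + 1):
        if k > n:
            continue
        for s in range(max(0, idx - k + 1), min(idx, n - k) + 1):
            pair = (window.mutant_seq[s : s + k], window.wildtype_seq[s : s + k])
            if pair not in seen:
                seen.add(pair)
                pairs.append(pair)
    return pairs


class AffinityPredictor(Protocol):
    """Contract for MHC class I binding predictors: strictly positive IC50
    in nM, deterministic for fixed (peptide, allele)."""

    def predict(self, peptide: str, allele: str) -> float: ...


class PredictorError(RuntimeError):
    def __init__(self, peptide: str, allele: str, reason: str):
        super().__init__(f"prediction failed for {peptide}/{allele}: {reason}")
        self.peptide = peptide
        self.allele = allele


class ToyAffinityPredictor:
    """Deterministic hash-to-lognormal IC50 map with allele-specific anchors.

    An explicit test double, NOT a binding model: each (peptide, allele) pair
    is hashed to a uniform deviate which is mapped through a log-normal IC50
    distribution (median ~5 uM, log-sd 1.4), so that a small fraction of
    random peptides are strong binders for a given allele — of the order of
    real class I predictors on random peptides. Each allele carries a
    deterministic anchor shifting its log-median by up to ``anchor_spread``,
    making some alleles far more permissive than others (and per-patient
    neoantigen loads realistically overdispersed). Bit-reproducible across
    runs and platforms.
    """

    def __init__(
        self,
        mu: float = 8.6,
        sigma: float = 1.4,
        anchor_spread: float = 0.7,
        salt: int = 0,
    ):
        self.mu = mu
        self.sigma = sigma
        self.anchor_spread = anchor_spread
        self.salt = salt
        self._anchors: dict[str, float] = {}

    @staticmethod
    def _hash_uniform(key: str) -> float:
        digest = hashlib.blake2b(key.encode(), digest_size=8).digest()
        u = int.from_bytes(digest, "big") / 2**64
        return min(max(u, 1e-12), 1 - 1e-12)

    def _allele_mu(self, allele: str) -> float:
        anchor = self._anchors.get(allele)
        if anchor is None:
            u = self._hash_uniform(f"{self.salt}|anchor|{allele}")
            anchor = self.mu + self.anchor_spread * (2.0 * u - 1.0)
            self._anchors[allele] = anchor
        return anchor

    def _uniform(self, peptide: str, allele: str) -> float:
        return self._hash_uniform(f"{self.salt}|{allele}|{peptide}")

    def predict(self, peptide: str, allele: str) -> float:
        u = self._uniform(peptide, allele)
        return float(math.exp(self._allele_mu(allele) + self.sigma * ndtri(u)))

    def predict_many(self, peptides: Sequence[str], alleles: Sequence[str]) -> np.ndarray:
        u = np.array([self._uniform(p, a) for p, a in zip(peptides, alleles)])
        mus = np.array([self._allele_mu(a) for a in alleles])
        return np.exp(mus + self.sigma * ndtri(u))


class TabularPredictor:
    """Adapter over NetMHCpan-style tabular output.

    Reads a TSV with columns peptide, allele, ic50 (nM) and serves lookups;
    missing pairs raise :class:`PredictorError`.
    """

    def __init__(self, path):
        df = pd.read_csv(path, sep="\t")
        missing = {"peptide", "allele", "ic50"} - set(df.columns)
        if missing:
            raise ValueError(f"predictor table missing columns: {sorted(missing)}")
        if (df["ic50"] <= 0).any():
            raise ValueError("IC50 values must be strictly positive")
        self._table = {
            (r.peptide, normalize_allele(r.allele)): float(r.ic50)
            for r in df.itertuples()
        }

    def predict(self, peptide: str, allele: str) -> float:
        try:
            return self._table[(peptide, allele)]
        except KeyError:
            raise PredictorError(peptide, allele, "pair absent from table") from None


def write_batch_file(pairs: Sequence[tuple[str, str]], alleles: Sequence[str], path) -> None:
    """Write the (peptide, allele) query list an external predictor consumes."""
    with open(path, "w") as fh:
        fh.write("peptide\tallele\n")
        for mut, wt in pairs:
            for allele in alleles:
                fh.write(f"{mut}\t{allele}\n")
                fh.write(f"{wt}\t{allele}\n")


EPITOPE_COLUMNS = [
    "tumor_id",
    "gene",
    "protein_change",
    "peptide_mut",
    "peptide_wt",
    "allele",
    "ic50_mut",
    "ic50_wt",
    "immunogenic",
]


def call_epitopes(
    pairs: Sequence[tuple[str, str]],
    genotype: HLAGenotype,
    predictor: AffinityPredictor,
    ic50_mut_max: float = IC50_MUT_MAX,
    ic50_wt_min: float = IC50_WT_MIN,
    same_allele: bool = True,
) -> pd.DataFrame:
    """Score every (pair, allele) combination and flag immunogenic calls.

    Default (same-allele) rule: a call is immunogenic iff the mutant peptide
    binds strongly (IC50 < ``ic50_mut_max``) and the wild-type counterpart
    weakly (IC50 > ``ic50_wt_min``) on the SAME allele. With
    ``same_allele=False`` a peptide is immunogenic when its best mutant IC50
    over the patient's alleles is strong while the wild type is weak on every
    allele; the flag is then set on all calls of that peptide.
    """
    rows = []
    for mut, wt in pairs:
        for allele in genotype.alleles:
            try:
                ic_mut = predictor.predict(mut, allele)
                ic_wt = predictor.predict(wt, allele)
            except PredictorError:
                raise
            except Exception as exc:  # pragma: no cover - adapter failures
                raise PredictorError(mut, allele, str(exc)) from exc
            rows.append(
                {
                    "peptide_mut": mut,
                    "peptide_wt": wt,
                    "allele": allele,
                    "ic50_mut": ic_mut,
                    "ic50_wt": ic_wt,
                }
            )
    calls = pd.DataFrame(
        rows, columns=["peptide_mut", "peptide_wt", "allele", "ic50_mut", "ic50_wt"]
    )
    if calls.empty:
        calls["immunogenic"] = pd.Series(dtype=bool)
        return calls
    if same_allele:
        calls["immunogenic"] = (calls["ic50_mut"] < ic50_mut_max) & (
            calls["ic50_wt"] > ic50_wt_min
        )
    else:
        best = calls.groupby("peptide_mut").agg(
            mut_min=("ic50_mut", "min"), wt_min=("ic50_wt", "min")
        )
        flagged = set(
            best[(best["mut_min"] < ic50_mut_max) & (best["wt_min"] > ic50_wt_min)].index
        )
        calls["immunogenic"] = calls["peptide_mut"].isin(flagged)
    return calls


def count_neoantigens(calls: pd.DataFrame, mode: str = "peptide") -> int:
    """Neoantigen count from one tumor's epitope calls.

    Modes: ``peptide`` (distinct immunogenic mutant peptides, default),
    ``event`` (immunogenic peptide x allele calls), ``mutation`` (distinct
    source mutations with >= 1 immunogenic peptide; requires gene and
    protein_change columns).
    """
    hits = calls[calls["immunogenic"]]
    if mode == "peptide":
        return int(hits["peptide_mut"].nunique())
    if mode == "event":
        return int(len(hits))
    if mode == "mutation":
        return int(hits.drop_duplicates(["gene", "protein_change"]).shape[0])
    raise ValueError(f"unknown count mode {mode!r}")


def call_cohort_epitopes(
    mutations: pd.DataFrame,
    proteome: dict[str, str],
    genotypes: dict[str, HLAGenotype],
    predictor: AffinityPredictor,
    k_range: tuple[int, int] = KMER_RANGE,
    ic50_mut_max: float = IC50_MUT_MAX,
    ic50_wt_min: float = IC50_WT_MIN,
    count_mode: str = "peptide",
) -> tuple[pd.DataFrame, pd.Series]:
    """Run the full epitope pipeline over a cohort's missense mutations.

    Returns (epitope call table, per-tumor neoantigen counts). Records whose
    reference residue disagrees with the proteome are skipped and logged;
    tumors without missense mutations (or without a genotype) count 0.
    """
    missense = mutations[mutations["class"].str.startswith("missense")].dropna(
        subset=["protein_pos", "ref_aa", "alt_aa"]
    )
    all_calls: list[pd.DataFrame] = []
    counts: dict[str, int] = {t: 0 for t in genotypes}
    skipped = 0
    for tumor_id, tumor_muts in missense.groupby("tumor_id"):
        genotype = genotypes.get(str(tumor_id))
        if genotype is None:
            logger.warning("tumor %s has no HLA genotype; skipped", tumor_id)
            continue
        tumor_calls = []
        for rec in tumor_muts.itertuples():
            seq = proteome.get(rec.gene)
            if seq is None:
                logger.warning("gene %s absent from proteome; record skipped", rec.gene)
                continue
            try:
                window = build_window(
                    seq, int(rec.protein_pos), rec.ref_aa, rec.alt_aa, gene=rec.gene
                )
            except RefMismatchError as exc:
                skipped += 1
                logger.warning("reference mismatch skipped: %s", exc)
                continue
            pairs = enumerate_kmer_pairs(window, k_range)
            calls = call_epitopes(
                pairs, genotype, predictor, ic50_mut_max, ic50_wt_min
            )
            calls.insert(0, "tumor_id", tumor_id)
            calls.insert(1, "gene", rec.gene)
            calls.insert(
                2, "protein_change", f"{rec.ref_aa}{int(rec.protein_pos)}{rec.alt_aa}"
            )
            tumor_calls.append(calls)
        if tumor_calls:
            merged = pd.concat(tumor_calls, ignore_index=True)
            all_calls.append(merged)
            counts[str(tumor_id)] = count_neoantigens(merged, mode=count_mode)
    if skipped:
        logger.info("%d records skipped for reference mismatches", skipped)
    epitopes = (
        pd.concat(all_calls, ignore_index=True)
        if all_calls
        else pd.DataFrame(columns=EPITOPE_COLUMNS)
    )
    per_tumor = pd.Series(counts, dtype=int).sort_index()
    per_tumor.index.name = "tumor_id"
    return epitopes, per_tumor


def expression_aware_counts(
    epitopes: pd.DataFrame,
    expression: pd.DataFrame,
    tumor_suffix: str = "_T",
    threshold: pd.Series | None = None,
    count_mode: str = "peptide",
) -> pd.Series:
    """Per-tumor neoantigen counts restricted to expressed source genes.

    A source gene counts as expressed in a tumor when its value in the
    tumor's expression column exceeds the threshold for that gene (default:
    the cohort median across tumor columns). Genes absent from the matrix
    retain their epitopes, logged.
    """
    tumor_cols = [c for c in expression.columns if c.endswith(tumor_suffix)]
    if threshold is None:
        threshold = expression[tumor_cols].median(axis=1)
    counts: dict[str, int] = {}
    for tumor_id, calls in epitopes.groupby("tumor_id"):
        col = f"{tumor_id}{tumor_suffix}"
        if col not in expression.columns:
            raise KeyError(f"expression matrix lacks column {col!r}")
        keep = []
        for gene in calls["gene"].unique():
            if gene not in expression.index:
                logger.info("gene %s absent from expression matrix; epitopes kept", gene)
                keep.append(gene)
            elif expression.at[gene, col] > threshold[gene]:
                keep.append(gene)
        counts[str(tumor_id)] = count_neoantigens(
            calls[calls["gene"].isin(keep)], mode=count_mode
        )
    out = pd.Series(counts, dtype=int).sort_index()
    out.index.name = "tumor_id"
    return out


def extremes_summary(
    per_tumor_counts: pd.Series,
    clinical: pd.DataFrame,
    low: int = 0,
    high: int = 8,
) -> pd.DataFrame:
    """Relapse tabulated at the extremes of the neoantigen-count distribution.

    Returns one row per stratum — tumors with exactly ``low`` predicted
    neoantigens and tumors with more than ``high`` — with the number of
    tumors and the number relapsed.
    """
    events = clinical.set_index("patient_id")["event"]
    aligned = per_tumor_counts.reindex(events.index)
    rows = []
    for name, mask in (
        (f"count=={low}", aligned == low),
        (f"count>{high}", aligned > high),
    ):
        sel = events[mask.fillna(False)]
        rows.append(
            {
                "stratum": name,
                "n_tumors": int(len(sel)),
                "n_relapsed": int(sel.sum()),
                "relapse_fraction": float(sel.mean()) if len(sel) else float("nan"),
            }
        )
    return pd.DataFrame(rows)
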