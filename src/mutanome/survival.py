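"""Immune-gene expression, neoantigen load and outcome.

Kaplan-Meier / log-rank analyses over expression quartiles, Cox
proportional-hazards fits, CD8A-based stratification (CD8A expression as a
T-cell infiltration surrogate), paired tumor-vs-mucosa tests, PCA over the
immune feature block, and consensus-molecular-subtype stratified reanalysis.

Partial-likelihood fitting and the log-rank statistic delegate to lifelines
(Efron ties); quartile construction and stratification policies live here.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger(__name__)

#: MHC class I antigen-presentation genes (heavy chains + peptide transporters).
PRESENTATION_GENES = ("HLA-A", "HLA-B", "HLA-C", "TAP1", "TAP2")
#: HLA class II genes carried along for completeness.
CLASS_II_GENES = ("HLA-DPA1", "HLA-DPB1", "HLA-DQA1", "HLA-DQB1")
#: Full immune panel expected in every expression matrix.
IMMUNE_PANEL = PRESENTATION_GENES + CLASS_II_GENES + ("CD8A",)


def km_estimate(times, events) -> pd.DataFrame:
    """Product-limit survival estimate; returns a (time, survival) table.

    The step function starts at S(0) = 1 and is non-increasing; censored
    subjects leave the risk set without a drop.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) < 1:
        raise ValueError("need at least one subject")
    if (times < 0).any():
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    return pd.DataFrame(
        {"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()}
    )


def logrank_test(groups: dict) -> tuple[float, float, int]:
    """k-sample log-rank test over shared risk sets.

    ``groups`` maps a label to a (times, events) pair; returns
    (chi-square statistic, p-value, degrees of freedom = k - 1).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    times, events, labels = [], [], []
    for name, (t, e) in groups.items():
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=int)
        if len(t) == 0:
            raise ValueError(f"group {name!r} is empty")
        times.append(t)
        events.append(e)
        labels.extend([name] * len(t))
    res = multivariate_logrank_test(
        np.concatenate(times), np.array(labels), np.concatenate(events)
    )
    return float(res.test_statistic), float(res.p_value), len(groups) - 1


def quartile_stratify(values) -> pd.Series:
    """Quartile label (Q1-Q4) per sample by empirical quartiles.

    Ties are broken by stable sample order so the four groups differ in size
    by at most one. A constant input collapses to a single stratum with a
    warning.
    """
    values = pd.Series(values)
    n = len(values)
    if n < 4:
        raise ValueError("need at least 4 samples for quartiles")
    if values.nunique() == 1:
        logger.warning("constant expression: single stratum")
        return pd.Series(["Q1"] * n, index=values.index)
    order = np.argsort(values.to_numpy(), kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    labels = [f"Q{r * 4 // n + 1}" for r in ranks]
    return pd.Series(labels, index=values.index)


def equal_width_stratify(values, k: int = 4) -> pd.Series:
    """Alternative policy: equal-width bins over the value range."""
    values = pd.Series(values)
    edges = np.linspace(values.min(), values.max(), k + 1)
    idx = np.clip(np.searchsorted(edges, values.to_numpy(), side="right") - 1, 0, k - 1)
    return pd.Series([f"Q{i + 1}" for i in idx], index=values.index)


class CoxConvergenceError(RuntimeError):
    pass


def cox_fit(covariate, times, events) -> pd.DataFrame:
    """Cox proportional-hazards fit (Efron ties, Wald p per covariate).

    ``covariate`` is a Series (univariate) or DataFrame (multivariable).
    Returns a table with coef, hazard_ratio, se, p per covariate.
    """
    X = pd.DataFrame(covariate).reset_index(drop=True)
    if len(X) < 10:
        raise ValueError("need at least 10 subjects for a Cox fit")
    for col in X.columns:
        if X[col].nunique() <= 1:
            raise ValueError(f"covariate {col!r} is constant")
    df = X.copy()
    df["time"] = np.asarray(times, dtype=float)
    df["event"] = np.asarray(events, dtype=int)
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:
        raise CoxConvergenceError(f"Cox fit failed: {exc}") from exc
    out = cph.summary[["coef", "exp(coef)", "se(coef)", "p"]].copy()
    out.columns = ["coef", "hazard_ratio", "se", "p"]
    return out


def tumor_values(expression: pd.DataFrame, gene: str, patients, suffix: str = "_T") -> pd.Series:
    """Expression of ``gene`` in each patient's tumor column, indexed by patient."""
    cols = [f"{p}{suffix}" for p in patients]
    missing = [c for c in cols if c not in expression.columns]
    if missing:
        raise KeyError(f"expression matrix lacks columns: {missing[:5]}")
    vals = expression.loc[gene, cols]
    vals.index = list(patients)
    return vals.astype(float)


def survival_by_quartiles(
    expression: pd.DataFrame, gene: str, clinical: pd.DataFrame
) -> dict:
    """Quartile KM/log-rank plus univariate Cox for one gene's tumor expression."""
    patients = list(clinical["patient_id"])
    vals = tumor_values(expression, gene, patients)
    labels = quartile_stratify(vals)
    clin = clinical.set_index("patient_id")
    groups = {
        q: (
            clin.loc[labels[labels == q].index, "time_months"],
            clin.loc[labels[labels == q].index, "event"],
        )
        for q in sorted(labels.unique())
    }
    if len(groups) >= 2:
        stat, logrank_p, dof = logrank_test(groups)
    else:
        stat, logrank_p, dof = float("nan"), float("nan"), 0
    cox = cox_fit(
        vals.rename(gene).reset_index(drop=True),
        clin.loc[patients, "time_months"],
        clin.loc[patients, "event"],
    )
    return {
        "gene": gene,
        "n": len(patients),
        "logrank_stat": stat,
        "logrank_p": logrank_p,
        "logrank_df": dof,
        "cox_coef": float(cox.loc[gene, "coef"]),
        "cox_p": float(cox.loc[gene, "p"]),
        "quartiles": labels,
    }


def cd8a_stratify(
    expression: pd.DataFrame,
    patients,
    rule: str | float = "upper-quartile",
) -> pd.Series:
    """High/low T-cell infiltration labels from tumor CD8A expression.

    ``rule``: 'median', 'upper-quartile', or a float quantile in (0, 1) —
    patients with CD8A expression strictly above the cut are 'high'.
    """
    vals = tumor_values(expression, "CD8A", patients)
    if rule == "median":
        cut = float(vals.quantile(0.5))
    elif rule == "upper-quartile":
        cut = float(vals.quantile(0.75))
    elif isinstance(rule, (int, float)):
        cut = float(vals.quantile(float(rule)))
    else:
        raise ValueError(f"unknown CD8A rule {rule!r}")
    return pd.Series(np.where(vals > cut, "high", "low"), index=vals.index)


def stratified_survival(
    expression: pd.DataFrame,
    clinical: pd.DataFrame,
    strata: pd.Series,
    genes=PRESENTATION_GENES,
    min_n: int = 10,
) -> pd.DataFrame:
    """Repeat the per-gene quartile/log-rank/Cox analysis within each stratum.

    Strata smaller than ``min_n`` are skipped with a logged reason. Returns
    one row per (stratum, gene).
    """
    rows = []
    for stratum in sorted(strata.dropna().unique()):
        ids = strata[strata == stratum].index
        sub = clinical[clinical["patient_id"].isin(ids)]
        if len(sub) < min_n:
            logger.info(
                "stratum %s skipped: %d patients < minimum %d", stratum, len(sub), min_n
            )
            continue
        for gene in genes:
            res = survival_by_quartiles(expression, gene, sub)
            rows.append(
                {
                    "stratum": stratum,
                    "gene": gene,
                    "n": res["n"],
                    "logrank_p": res["logrank_p"],
                    "cox_coef": res["cox_coef"],
                    "cox_p": res["cox_p"],
                }
            )
    return pd.DataFrame(rows, columns=["stratum", "gene", "n", "logrank_p", "cox_coef", "cox_p"])


def cms_stratified_analysis(
    expression: pd.DataFrame,
    clinical: pd.DataFrame,
    genes=PRESENTATION_GENES,
    subtypes=("CMS2", "CMS3", "CMS4"),
    min_n: int = 10,
) -> pd.DataFrame:
    """Per-consensus-subtype survival analysis of the presentation panel.

    Subtypes outside ``subtypes`` (e.g. the microsatellite-instable-like
    CMS1, typically too small in an MSS cohort) or below ``min_n`` are
    skipped with a logged reason.
    """
    labels = clinical.set_index("patient_id")["cms_label"]
    keep = labels[labels.isin(subtypes)]
    dropped = set(labels.unique()) - set(subtypes)
    if dropped:
        logger.info("subtypes not analyzed: %s", sorted(dropped))
    return stratified_survival(expression, clinical, keep, genes=genes, min_n=min_n)


def paired_tumor_normal_test(
    expression: pd.DataFrame,
    gene: str,
    tumor_suffix: str = "_T",
    normal_suffix: str = "_N",
) -> tuple[float, float]:
    """Paired two-sided t-test of tumor minus normal log expression.

    Returns (mean difference, p-value). Every tumor column must have the
    matching normal column.
    """
    tumor_cols = [c for c in expression.columns if c.endswith(tumor_suffix)]
    pairs = []
    for tc in tumor_cols:
        nc = tc[: -len(tumor_suffix)] + normal_suffix
        if nc not in expression.columns:
            raise ValueError(f"unpaired tumor sample {tc!r}: missing {nc!r}")
        pairs.append((tc, nc))
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs for a paired t-test")
    t_vals = expression.loc[gene, [p[0] for p in pairs]].to_numpy(dtype=float)
    n_vals = expression.loc[gene, [p[1] for p in pairs]].to_numpy(dtype=float)
    diff = t_vals - n_vals
    if np.all(diff == diff[0]) and diff[0] == 0:
        return 0.0, 1.0
    res = stats.ttest_rel(t_vals, n_vals)
    return float(diff.mean()), float(res.pvalue)


def welch_group_test(values: pd.Series, clinical: pd.DataFrame) -> tuple[float, float]:
    """Welch's t-test of a per-patient quantity between prognosis groups."""
    groups = clinical.set_index("patient_id")["group"]
    good = values[groups[groups == "good"].index]
    poor = values[groups[groups == "poor"].index]
    res = stats.ttest_ind(good, poor, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def pca_immune(features: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """PCA of the standardized immune feature block (neoantigen count +
    immune panel expression per patient).

    Returns (sample coordinates on PC1/PC2, explained variance ratios over
    all components, loadings). Sign convention: within each component the
    largest-magnitude loading is positive.
    """
    if len(features) < 3:
        raise ValueError("need at least 3 samples for PCA")
    X = StandardScaler().fit_transform(features.to_numpy(dtype=float))
    n_comp = min(X.shape)
    pca = PCA(n_components=n_comp)
    coords = pca.fit_transform(X)
    loadings = pca.components_
    for i in range(n_comp):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
            coords[:, i] = -coords[:, i]
    coord_df = pd.DataFrame(
        coords[:, :2], index=features.index, columns=["PC1", "PC2"]
    )
    loading_df = pd.DataFrame(
        loadings,
        index=[f"PC{i + 1}" for i in range(n_comp)],
        columns=features.columns,
    )
    return coord_df, pca.explained_variance_ratio_, loading_df
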