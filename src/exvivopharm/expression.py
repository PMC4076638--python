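"""Gene-card Ct normalization and differential expression ranking.

Implements the reference-gene workflow used for multi-target qPCR cards:
relative quantities anchored at the best-expressed sample, reference
stability (M) values, geometric-mean normalization factors,
median-centered log2 matrices, per-gene two-sample ranking with
Benjamini-Hochberg FDR, and single-reference 2^-dCt quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CT_COLUMNS",
    "NormalizedMatrix",
    "load_panel_fixture",
    "relative_quantity",
    "genorm_stability",
    "genorm_rank",
    "normalization_factor",
    "normalize_card",
    "differential_panel",
    "delta_ct_quant",
]

#: Long-format Ct table dialect: one row per well.
CT_COLUMNS = ("sample_id", "class", "gene", "role", "replicate", "ct")


class ExpressionError(ValueError):
    """Raised on malformed Ct tables or normalization inputs."""


def load_panel_fixture() -> pd.DataFrame:
    """Packaged 92-target + 3-reference gene roster (gene, role, status).

    Names other than the few with published differential calls are
    synthetic placeholders standing in for the full card layout.
    """
    with resources.files("exvivopharm.data").joinpath("apoptosis_panel.csv").open("r") as fh:
        return pd.read_csv(fh)


def _mean_ct(ct_table: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicate wells to mean Ct per (gene, sample); NaN-safe."""
    missing = set(CT_COLUMNS) - set(ct_table.columns) - {"class", "replicate"}
    if missing:
        raise ExpressionError(f"Ct table missing columns: {sorted(missing)}")
    bad = ct_table["ct"].dropna()
    if (bad <= 0).any():
        raise ExpressionError("determined Ct values must be > 0")
    return (
        ct_table.groupby(["gene", "sample_id"], sort=True)["ct"]
        .mean()  # NaN (undetermined) replicates are skipped; all-NaN stays NaN
        .unstack("sample_id")
    )


def relative_quantity(ct_table: pd.DataFrame, efficiency: float = 2.0) -> pd.DataFrame:
    """Convert well-level Ct values into per-gene relative quantities.

    Replicates are averaged per (gene, sample); RQ = efficiency ** (Ct_min
    of the gene - Ct of the sample), so the best-expressed sample of every
    gene has RQ = 1.  Undetermined samples propagate as NaN.
    """
    if efficiency <= 1:
        raise ExpressionError(f"amplification efficiency must be > 1, got {efficiency}")
    mean_ct = _mean_ct(ct_table)
    if mean_ct.isna().all(axis=1).any():
        genes = mean_ct.index[mean_ct.isna().all(axis=1)].tolist()
        raise ExpressionError(f"all replicates undetermined for genes: {genes}")
    ct_min = mean_ct.min(axis=1)
    return np.power(efficiency, ct_min.values[:, None] - mean_ct)


def genorm_stability(ref_rq: pd.DataFrame) -> pd.Series:
    """Reference-gene stability M: mean SD of pairwise log2 RQ ratios.

    ``ref_rq`` is references x samples.  For reference j, M_j is the mean
    over all other references k of the sample-wise standard deviation of
    log2(RQ_j / RQ_k).  Lower M = more stable.
    """
    if ref_rq.shape[0] < 2:
        raise ExpressionError("stability needs at least 2 reference genes")
    if ref_rq.shape[1] < 2:
        raise ExpressionError("stability needs at least 2 samples")
    logs = np.log2(ref_rq)
    m = {}
    for j in ref_rq.index:
        sds = [
            float(np.std(logs.loc[j] - logs.loc[k], ddof=1))
            for k in ref_rq.index
            if k != j
        ]
        m[j] = float(np.mean(sds))
    return pd.Series(m, name="M")


def genorm_rank(ref_rq: pd.DataFrame) -> list[tuple[str, float]]:
    """Iterative stability ranking: repeatedly drop the least stable reference.

    Returns (gene, M at elimination) from least to most stable; the final
    two genes are tied and share the last M.  Provided for completeness —
    the default pipeline keeps the fixed reference set.
    """
    remaining = ref_rq.copy()
    eliminated: list[tuple[str, float]] = []
    while remaining.shape[0] > 2:
        m = genorm_stability(remaining)
        worst = m.idxmax()
        eliminated.append((str(worst), float(m[worst])))
        remaining = remaining.drop(index=worst)
    m = genorm_stability(remaining)
    eliminated.extend((str(g), float(m[g])) for g in m.sort_values(ascending=False).index)
    return eliminated


def normalization_factor(ref_rq: pd.DataFrame) -> pd.Series:
    """Per-sample normalization factor: geometric mean of reference RQs."""
    if ref_rq.isna().any().any():
        where = np.argwhere(ref_rq.isna().to_numpy())
        bad = [(str(ref_rq.index[i]), str(ref_rq.columns[j])) for i, j in where[:5]]
        raise ExpressionError(f"missing reference RQ for (gene, sample): {bad}")
    if (ref_rq <= 0).any().any():
        raise ExpressionError("reference RQs must be > 0")
    return pd.Series(
        np.exp(np.log(ref_rq).mean(axis=0)), index=ref_rq.columns, name="NF"
    )


@dataclass
class NormalizedMatrix:
    """Median-centered log2 normalized expression, genes x samples."""

    values: pd.DataFrame
    nf: pd.Series
    stability: pd.Series
    dropped_genes: list[str] = field(default_factory=list)


def normalize_card(
    target_rq: pd.DataFrame,
    nf: pd.Series,
    stability: pd.Series | None = None,
    max_missing_fraction: float = 0.5,
) -> NormalizedMatrix:
    """Scale target RQs by NF, log2-transform and median-center per gene.

    Centering is done in log2 space (log2(RQ/NF) minus its per-gene
    median), which makes the per-gene median exactly 0 for any sample
    count.  Genes undetermined in more than ``max_missing_fraction`` of
    samples are dropped and reported.
    """
    missing_nf = set(target_rq.columns) - set(nf.index)
    if missing_nf:
        raise ExpressionError(f"no normalization factor for samples: {sorted(missing_nf)}")
    if (target_rq <= 0).any().any():
        raise ExpressionError("RQ values must be > 0 (missing values must be NaN, not 0)")
    frac_missing = target_rq.isna().mean(axis=1)
    dropped = frac_missing.index[frac_missing > max_missing_fraction].tolist()
    kept = target_rq.drop(index=dropped)
    log_scaled = np.log2(kept.div(nf[kept.columns], axis=1))
    centered = log_scaled.sub(log_scaled.median(axis=1, skipna=True), axis=0)
    return NormalizedMatrix(
        values=centered,
        nf=nf,
        stability=stability if stability is not None else pd.Series(dtype=float),
        dropped_genes=[str(g) for g in dropped],
    )


def differential_panel(matrix: NormalizedMatrix, classes: pd.Series) -> pd.DataFrame:
    """Rank genes by a two-sided unpaired t test between the two classes.

    Returns a frame sorted by ascending p with columns gene, mean log2
    difference (first class minus second, in sorted label order — so
    NonResponder minus Responder for the standard labels), t, p, BH FDR
    and rank.  Genes with zero variance and zero difference get p = 1.
    """
    classes = classes.reindex(matrix.values.columns)
    if classes.isna().any():
        raise ExpressionError(
            f"missing class labels for samples: {classes.index[classes.isna()].tolist()}"
        )
    levels = sorted(classes.unique())
    if len(levels) != 2:
        raise ExpressionError(f"need exactly 2 classes, got {levels}")
    g0 = matrix.values.loc[:, classes == levels[0]]
    g1 = matrix.values.loc[:, classes == levels[1]]
    if g0.shape[1] < 2 or g1.shape[1] < 2:
        raise ExpressionError("need >= 2 samples per class")

    rows = []
    for gene in matrix.values.index:
        a = g0.loc[gene].dropna().to_numpy()
        b = g1.loc[gene].dropna().to_numpy()
        diff = float(np.mean(a) - np.mean(b))
        if a.size < 2 or b.size < 2:
            t_stat, p = np.nan, np.nan
        elif np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
            t_stat, p = (0.0, 1.0) if diff == 0 else (np.inf * np.sign(diff), 0.0)
        else:
            res = stats.ttest_ind(a, b)
            t_stat, p = float(res.statistic), float(res.pvalue)
        rows.append({"gene": gene, "log2_diff": diff, "t": t_stat, "p": p})
    out = pd.DataFrame(rows).dropna(subset=["p"])
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    out = out.sort_values("p", kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def delta_ct_quant(ct_target, ct_reference, efficiency: float = 2.0):
    """Relative expression versus a single reference: efficiency^-(dCt)."""
    if efficiency <= 1:
        raise ExpressionError(f"amplification efficiency must be > 1, got {efficiency}")
    ct_target = np.asarray(ct_target, dtype=float)
    ct_reference = np.asarray(ct_reference, dtype=float)
    out = np.power(efficiency, -(ct_target - ct_reference))
    out = np.where(np.isnan(ct_target) | np.isnan(ct_reference), np.nan, out)
    return float(out) if out.ndim == 0 else out
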