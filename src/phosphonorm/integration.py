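"""Proteome-transcriptome integration and replicate-level analytics.

Workflow pieces:

* feature matching through a gene <-> protein map (1:1 pairs only);
* left-shifted Gaussian imputation of missing values: per feature, draws
  from N(mean - 3*sd, 0.3*sd) of that feature's observed values — the
  standard treatment of left-censored (low-abundance) missingness;
* per-feature z-scoring;
* all-vs-all replicate Pearson correlation and linear regression between
  the two omics layers within each condition, on complete pairs;
* two-sided independent Student's t-tests comparing the correlation values
  of two conditions;
* intra-omics replicate reproducibility (pairwise r^2 on log2 values) and
  per-feature CVs on linear intensities;
* sample-sample Pearson correlation matrix ordered by single-linkage
  agglomeration on Euclidean distances (the heatmap recipe is
  impute -> z-score -> correlate, in that order).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage

from .matrix import GeneProteinMap, IntensityMatrix, SampleDesign

logger = logging.getLogger(__name__)

__all__ = [
    "ImputationParams",
    "MatchedOmics",
    "match_features",
    "impute_gaussian",
    "zscore_features",
    "crossomics_replicate_correlations",
    "compare_condition_correlations",
    "replicate_reproducibility_and_cv",
    "sample_correlation_clustermap",
]


@dataclass(frozen=True)
class ImputationParams:
    """Downshifted-Gaussian imputation parameters.

    ``downshift`` and ``width`` are in units of each feature's own standard
    deviation: imputed values are drawn from
    N(mean - downshift*sd, (width*sd)^2).
    """

    downshift: float = 3.0
    width: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"width must be > 0, got {self.width}")
        if self.downshift < 0:
            raise ValueError(f"downshift must be >= 0, got {self.downshift}")


class MatchedOmics(NamedTuple):
    proteome: IntensityMatrix
    transcriptome: IntensityMatrix
    pairs: pd.DataFrame  # columns gene_id, protein_group, row-aligned


def match_features(
    proteome: IntensityMatrix,
    transcriptome: IntensityMatrix,
    gpmap: GeneProteinMap,
) -> MatchedOmics:
    """Restrict both matrices to 1:1 mapped features in identical row order.

    Many-to-many gene/protein mappings are resolved by exclusion; only
    unambiguous pairs present in both matrices survive.
    """
    pairs = gpmap.one_to_one()
    pairs = pairs[pairs["protein_group"].isin(proteome.feature_ids)
                  & pairs["gene_id"].isin(transcriptome.feature_ids)]
    if pairs.empty:
        raise ValueError("no overlapping features between proteome and transcriptome")
    pairs = pairs.reset_index(drop=True)
    prot = IntensityMatrix(proteome.data.loc[pairs["protein_group"]], proteome.scale)
    trans = IntensityMatrix(transcriptome.data.loc[pairs["gene_id"]], transcriptome.scale)
    logger.info("matched %d features across omics layers", len(pairs))
    return MatchedOmics(prot, trans, pairs)


def impute_gaussian(matrix: IntensityMatrix, params: ImputationParams) -> IntensityMatrix:
    """Impute missing values from a per-feature left-shifted Gaussian.

    Only missing cells are altered; observed values are returned
    bit-identical.  Features with fewer than 2 observed values cannot
    provide a mean and sd and are dropped with a warning.
    """
    if matrix.scale != "log2":
        raise ValueError("impute_gaussian expects a log2-scale matrix")
    rng = np.random.default_rng(params.seed)
    vals = matrix.data.to_numpy(copy=True)
    n_obs = np.isfinite(vals).sum(axis=1)
    droppable = n_obs < 2
    if droppable.any():
        warnings.warn(
            f"dropping {int(droppable.sum())} features with < 2 observed values")
        vals = vals[~droppable]
    index = matrix.data.index[~droppable]
    for i in range(vals.shape[0]):
        row = vals[i]
        miss = ~np.isfinite(row)
        if not miss.any():
            continue
        obs = row[~miss]
        mu = obs.mean()
        sd = obs.std(ddof=1)
        row[miss] = rng.normal(mu - params.downshift * sd, params.width * sd, miss.sum())
    out = pd.DataFrame(vals, index=index, columns=matrix.data.columns)
    return IntensityMatrix(out, "log2")


def zscore_features(matrix: IntensityMatrix) -> IntensityMatrix:
    """Center and scale each feature row to mean 0, sd 1 (population sd)."""
    vals = matrix.data.to_numpy()
    if not np.isfinite(vals).all():
        raise ValueError("zscore_features requires a complete matrix (impute first)")
    sd = vals.std(axis=1, ddof=0)
    zero = sd == 0
    if zero.any():
        names = matrix.data.index[zero].tolist()
        raise ValueError(f"zero-variance features cannot be z-scored: {names[:10]}")
    z = (vals - vals.mean(axis=1, keepdims=True)) / sd[:, None]
    return IntensityMatrix(pd.DataFrame(z, index=matrix.data.index,
                                        columns=matrix.data.columns), matrix.scale)


def crossomics_replicate_correlations(
    matched: MatchedOmics, design: SampleDesign
) -> pd.DataFrame:
    """All proteomics x transcriptomics replicate pairings per condition.

    For each (cell_type, treatment) group, every pairing of one proteomics
    replicate with one transcriptomics replicate yields a Pearson r and a
    simple linear regression over the matched features, computed on
    complete pairs (both values observed, no imputed data).
    """
    for m in (matched.proteome, matched.transcriptome):
        if m.scale != "log2":
            raise ValueError("cross-omics correlations expect log2 matrices")
    rows = []
    for (ct, tr), samples in design.groups():
        avail_p = [s for s in samples if s in matched.proteome.sample_ids]
        avail_t = [s for s in samples if s in matched.transcriptome.sample_ids]
        if not avail_p or not avail_t:
            warnings.warn(f"group ({ct}, {tr}) lacks replicates in one omics layer; skipped")
            continue
        for sp, st in itertools.product(avail_p, avail_t):
            x = matched.proteome.data[sp].to_numpy()
            y = matched.transcriptome.data[st].to_numpy()
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3:
                continue
            fit = stats.linregress(x[ok], y[ok])
            rows.append({
                "cell_type": ct, "treatment": tr,
                "proteome_sample": sp, "transcriptome_sample": st,
                "pearson_r": fit.rvalue, "r_squared": fit.rvalue ** 2,
                "slope": fit.slope, "intercept": fit.intercept,
                "n_features": int(ok.sum()),
            })
    return pd.DataFrame(rows)


def compare_condition_correlations(
    results: pd.DataFrame,
    group_x: tuple[str, str],
    group_y: tuple[str, str],
) -> dict:
    """Two-sided independent Student's t-test on per-pairing Pearson r values."""
    def pick(g):
        m = (results["cell_type"] == g[0]) & (results["treatment"] == g[1])
        return results.loc[m, "pearson_r"].to_numpy()

    x, y = pick(group_x), pick(group_y)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs >= 2 correlation values")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # near-constant groups are handled below
        t, p = stats.ttest_ind(x, y, equal_var=True)
    if not np.isfinite(p):  # identical constant groups
        t, p = 0.0, 1.0
    return {"group_x": group_x, "group_y": group_y,
            "mean_r_x": float(x.mean()), "mean_r_y": float(y.mean()),
            "t": float(t), "p": float(p), "n_x": len(x), "n_y": len(y)}


def replicate_reproducibility_and_cv(
    matrix: IntensityMatrix, design: SampleDesign
) -> dict:
    """Within-group replicate reproducibility and coefficients of variation.

    Pairwise replicate r^2 is computed on log2 values over complete pairs;
    CV is sd/mean per feature across replicates on the *linear* scale
    (CV is not meaningful on log values).  Groups with a single replicate
    yield no pairwise r^2 and undefined CVs are left missing.
    """
    if matrix.scale == "log2":
        log2_vals = matrix.data
        lin_vals = np.exp2(matrix.data)
    else:
        lin_vals = matrix.data
        with np.errstate(divide="ignore"):
            log2_vals = np.log2(matrix.data.where(matrix.data > 0))
    pair_rows = []
    cv_frames = {}
    for (ct, tr), samples in design.groups():
        cols = [s for s in samples if s in matrix.sample_ids]
        for s1, s2 in itertools.combinations(cols, 2):
            x = log2_vals[s1].to_numpy()
            y = log2_vals[s2].to_numpy()
            ok = np.isfinite(x) & np.isfinite(y)
            r = stats.pearsonr(x[ok], y[ok]).statistic if ok.sum() >= 3 else np.nan
            pair_rows.append({"cell_type": ct, "treatment": tr,
                              "sample_1": s1, "sample_2": s2,
                              "pearson_r": r, "r_squared": r ** 2,
                              "n_features": int(ok.sum())})
        grp = lin_vals[cols]
        if len(cols) >= 2:
            mean = grp.mean(axis=1)
            sd = grp.std(axis=1, ddof=1)
            cv_frames[(ct, tr)] = sd / mean
        else:
            cv_frames[(ct, tr)] = pd.Series(np.nan, index=matrix.feature_ids)
    cv = pd.DataFrame(cv_frames)
    cv.columns = [f"{ct}.{tr}" for ct, tr in cv.columns]
    mean_cv = float(np.nanmean(cv.to_numpy())) if np.isfinite(cv.to_numpy()).any() else np.nan
    return {
        "pairwise": pd.DataFrame(pair_rows),
        "cv_per_feature": cv,
        "mean_cv": mean_cv,
    }


def sample_correlation_clustermap(
    matrix: IntensityMatrix,
) -> tuple[pd.DataFrame, list[str], np.ndarray]:
    """Sample-sample Pearson matrix with single-linkage ordering.

    The input should already be imputed and z-scored (the heatmap recipe's
    steps 1-2).  Returns the symmetric correlation matrix (unit diagonal),
    the leaf order of sample ids, and the scipy linkage matrix.
    """
    vals = matrix.data.to_numpy()
    if not np.isfinite(vals).all():
        raise ValueError("clustermap requires a complete matrix (impute first)")
    arr = matrix.data.corr(method="pearson").to_numpy()
    arr = (arr + arr.T) / 2.0
    np.fill_diagonal(arr, 1.0)
    corr = pd.DataFrame(arr, index=matrix.data.columns, columns=matrix.data.columns)
    if matrix.n_samples > 1:
        Z = linkage(vals.T, method="single", metric="euclidean")
        order = [matrix.data.columns[i] for i in leaves_list(Z)]
    else:
        Z = np.empty((0, 4))
        order = list(matrix.data.columns)
    return corr, order, Z


def plot_clustermap(corr: pd.DataFrame, order: list[str], path) -> None:
    """Render the ordered correlation heatmap to a file (optional output)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    fig, ax = plt.subplots(figsize=(6, 5))
    sns.heatmap(corr.loc[order, order], ax=ax, cmap="vlag", vmin=-1, vmax=1,
                square=True, cbar_kws={"label": "Pearson r"})
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
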