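"""Cell-type proteome profiling: ANOVA, k-means response clusters,
pairwise enrichment.

ANOVA is one-way across all (cell type x treatment) groups on complete
observations per feature; features where any group has fewer than 2
observed values are excluded and counted.  K-means (default k = 6, 25
restarts, fixed seed) clusters significant features by their per-group
mean z-profiles into response categories.  Pairwise enrichment delegates
to the differential-expression engine for all cell-type pairs within each
treatment and the control-vs-treated contrast within each cell type, and
summarizes shared vs cell-type-specific treatment responses.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .diffexp import Contrast, benjamini_hochberg, classify_regulation, differential_expression
from .matrix import IntensityMatrix, SampleDesign

logger = logging.getLogger(__name__)

__all__ = [
    "anova_across_groups",
    "kmeans_response_clusters",
    "pairwise_enrichment_tables",
    "group_mean_profiles",
]


def anova_across_groups(
    matrix: IntensityMatrix, design: SampleDesign, alpha: float = 0.05
) -> tuple[pd.DataFrame, float]:
    """One-way ANOVA per feature across all design groups.

    Returns the per-feature table (F, raw and BH-adjusted p, significance
    at ``alpha``) and the fraction of tested features significant.
    """
    if matrix.scale != "log2":
        raise ValueError("anova_across_groups requires a log2-scale matrix")
    groups = [(key, cols) for key, cols in design.groups() if len(cols) >= 2]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups with >= 2 replicates each")
    blocks = [matrix.data[cols].to_numpy() for _, cols in groups]
    n_feat = matrix.n_features
    F = np.full(n_feat, np.nan)
    p = np.full(n_feat, np.nan)
    tested = np.zeros(n_feat, dtype=bool)
    for i in range(n_feat):
        obs = [b[i][np.isfinite(b[i])] for b in blocks]
        if any(len(o) < 2 for o in obs):
            continue
        tested[i] = True
        if all(np.ptp(o) == 0 for o in obs) and len({o[0] for o in obs}) == 1:
            F[i], p[i] = 0.0, 1.0
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.f_oneway(*obs)
        # nan arises for zero between- and within-group variance: no signal
        F[i] = res.statistic if not np.isnan(res.statistic) else 0.0
        p[i] = res.pvalue if not np.isnan(res.pvalue) else 1.0
    p = np.clip(p, 1e-300, 1.0)
    p[~tested] = np.nan
    p_adj = np.full(n_feat, np.nan)
    if tested.any():
        p_adj[tested] = benjamini_hochberg(p[tested])
    table = pd.DataFrame({
        "feature_id": matrix.feature_ids,
        "F": F, "p_raw": p, "p_adj": p_adj,
        "tested": tested,
        "significant": np.where(tested, p_adj < alpha, False),
    }).reset_index(drop=True)
    frac = float(table.loc[tested, "significant"].mean()) if tested.any() else 0.0
    logger.info("ANOVA: %d/%d tested, %.1f%% significant at adj. p < %g",
                int(tested.sum()), n_feat, 100 * frac, alpha)
    return table, frac


def group_mean_profiles(matrix: IntensityMatrix, design: SampleDesign) -> pd.DataFrame:
    """Per-feature mean over each (cell_type, treatment) group's samples."""
    cols = {}
    for (ct, tr), samples in design.groups():
        avail = [s for s in samples if s in matrix.sample_ids]
        cols[f"{ct}.{tr}"] = matrix.data[avail].mean(axis=1)
    return pd.DataFrame(cols)


def kmeans_response_clusters(
    matrix: IntensityMatrix,
    design: SampleDesign,
    k: int = 6,
    seed: int = 0,
    n_restarts: int = 25,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """K-means on per-group mean z-profiles of (significant) features.

    The matrix should hold z-scored features (restricted to the
    ANOVA-significant set for the response-category use case).  Returns the
    per-feature cluster assignment (clusters numbered 1..k) and the k x
    n_groups cluster mean profiles for heatmap rendering.
    """
    profiles = group_mean_profiles(matrix, design)
    if k > len(profiles):
        raise ValueError(f"k={k} exceeds number of features ({len(profiles)})")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(profiles.to_numpy())
    assignments = pd.DataFrame({
        "feature_id": profiles.index,
        "cluster": labels + 1,
    }).reset_index(drop=True)
    centers = pd.DataFrame(km.cluster_centers_, columns=profiles.columns,
                           index=pd.RangeIndex(1, k + 1, name="cluster"))
    logger.info("k-means: k=%d, inertia=%.3f", k, km.inertia_)
    return assignments, centers


def pairwise_enrichment_tables(
    matrix: IntensityMatrix,
    design: SampleDesign,
    p_thresh: float = 0.05,
    fc_thresh: float = 1.0,
    min_valid: int = 2,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """DE tables with volcano labels for all standard contrasts.

    Contrasts: every cell-type pair within each treatment, and
    treated-vs-control within each cell type.  The summary classifies
    treatment-responsive features as shared (regulated in all cell types)
    or cell-type-specific (regulated in exactly one).
    """
    cts = design.cell_types
    trs = design.treatments
    if len(trs) != 2:
        raise ValueError("expected exactly 2 treatments")
    control, treated = trs
    tables: dict[str, pd.DataFrame] = {}
    for tr in trs:
        for ct_a, ct_b in itertools.combinations(cts, 2):
            c = Contrast(group_a=(ct_a, tr), group_b=(ct_b, tr))
            de = differential_expression(matrix, design, c, min_valid=min_valid)
            de["regulation"] = classify_regulation(de, p_thresh, fc_thresh)
            tables[c.name] = de
    treat_regulated: dict[str, set] = {}
    for ct in cts:
        c = Contrast(group_a=(ct, control), group_b=(ct, treated))
        de = differential_expression(matrix, design, c, min_valid=min_valid)
        de["regulation"] = classify_regulation(de, p_thresh, fc_thresh)
        tables[c.name] = de
        treat_regulated[ct] = set(de.loc[de["regulation"] != "ns", "feature_id"])

    counts = {f: sum(f in s for s in treat_regulated.values())
              for f in set().union(*treat_regulated.values())} if treat_regulated else {}
    summary = pd.DataFrame({
        "cell_type": list(treat_regulated),
        "n_regulated": [len(s) for s in treat_regulated.values()],
    })
    summary.attrs["n_shared_all"] = sum(1 for v in counts.values() if v == len(cts))
    summary.attrs["n_specific"] = sum(1 for v in counts.values() if v == 1)
    return tables, summary
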