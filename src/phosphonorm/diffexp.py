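"""Two-group differential expression on log2 intensity matrices.

Per feature with enough valid values in both groups: log2 fold change =
mean(group B) - mean(group A), p-value from Welch's unequal-variance t-test
on the log2 values, Benjamini-Hochberg adjustment across all tested
features of the contrast.  Features failing the min-valid filter are
reported with missing statistics and excluded from the adjustment.

Volcano-style classification calls a feature ``up`` when adjusted p < 0.05
and log2FC > 1, ``down`` for the mirrored condition, otherwise ``ns``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import IntensityMatrix, SampleDesign

logger = logging.getLogger(__name__)

__all__ = [
    "Contrast",
    "differential_expression",
    "classify_regulation",
    "benjamini_hochberg",
]


@dataclass(frozen=True)
class Contrast:
    """Two disjoint (cell_type, treatment) groups; log2FC is B minus A."""

    group_a: tuple[str, str]
    group_b: tuple[str, str]

    @property
    def name(self) -> str:
        return (f"{self.group_b[0]}.{self.group_b[1]}-vs-"
                f"{self.group_a[0]}.{self.group_a[1]}")

    @classmethod
    def parse(cls, text: str) -> "Contrast":
        """Parse ``"beta.IFNg-vs-beta.control"`` (first token = group B)."""
        try:
            b, a = text.split("-vs-")
            ct_b, tr_b = b.split(".")
            ct_a, tr_a = a.split(".")
        except ValueError as exc:
            raise ValueError(
                f"cannot parse contrast {text!r}; expected 'ct.tr-vs-ct.tr'") from exc
        return cls(group_a=(ct_a, tr_a), group_b=(ct_b, tr_b))

    def resolve(self, design: SampleDesign) -> tuple[list[str], list[str]]:
        a = design.samples_for(*self.group_a)
        b = design.samples_for(*self.group_b)
        if set(a) & set(b):
            raise ValueError(f"contrast groups overlap: {sorted(set(a) & set(b))}")
        if len(a) < 2 or len(b) < 2:
            raise ValueError(
                f"contrast {self.name}: each group needs >= 2 samples "
                f"(got {len(a)} and {len(b)})")
        return a, b


def benjamini_hochberg(p) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        bad = p[~(np.isfinite(p) & (p > 0) & (p <= 1))]
        raise ValueError(f"p-values must be in (0, 1]; offending values: {bad[:5]}")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    matrix: IntensityMatrix,
    design: SampleDesign,
    contrast: Contrast,
    min_valid: int = 2,
) -> pd.DataFrame:
    """Welch t-test DE table for one contrast of a log2 matrix.

    Returns a DataFrame with columns ``feature_id``, ``log2fc``, ``p_raw``,
    ``p_adj``, ``n_A``, ``n_B``, ``tested``; the contrast name is stored in
    ``df.attrs["contrast"]``.
    """
    if matrix.scale != "log2":
        raise ValueError("differential_expression requires a log2-scale matrix")
    cols_a, cols_b = contrast.resolve(design)
    A = matrix.data[cols_a].to_numpy()
    B = matrix.data[cols_b].to_numpy()
    n_a = np.isfinite(A).sum(axis=1)
    n_b = np.isfinite(B).sum(axis=1)
    tested = (n_a >= min_valid) & (n_b >= min_valid)

    mean_a = np.where(n_a > 0, np.nansum(np.where(np.isfinite(A), A, 0.0), axis=1)
                      / np.maximum(n_a, 1), np.nan)
    mean_b = np.where(n_b > 0, np.nansum(np.where(np.isfinite(B), B, 0.0), axis=1)
                      / np.maximum(n_b, 1), np.nan)
    log2fc = np.where(tested, mean_b - mean_a, np.nan)

    import warnings as _warnings
    with np.errstate(invalid="ignore", divide="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # slices failing min_valid are dropped below
        t, p = stats.ttest_ind(B, A, axis=1, equal_var=False, nan_policy="omit")
    p = np.asarray(p, dtype=float)
    # degenerate equality (zero statistic) should never look significant
    zero_diff = tested & np.isclose(log2fc, 0.0, atol=0.0)
    p[zero_diff] = 1.0
    # zero within-group variance with a real difference: evidence is off the
    # t scale; report the smallest representable p rather than dropping it
    broken = tested & ~np.isfinite(p)
    if broken.any():
        logger.warning("%d features with zero variance and nonzero difference", broken.sum())
        p[broken] = 1e-300
    p = np.clip(p, 1e-300, 1.0)
    p[~tested] = np.nan

    p_adj = np.full_like(p, np.nan)
    if tested.any():
        p_adj[tested] = benjamini_hochberg(p[tested])

    out = pd.DataFrame({
        "feature_id": matrix.feature_ids,
        "log2fc": log2fc,
        "p_raw": p,
        "p_adj": p_adj,
        "n_A": n_a,
        "n_B": n_b,
        "tested": tested,
    }).reset_index(drop=True)
    out.attrs["contrast"] = contrast.name
    logger.info("DE %s: %d/%d features tested", contrast.name, int(tested.sum()), len(out))
    return out


def classify_regulation(
    records: pd.DataFrame, p_thresh: float = 0.05, fc_thresh: float = 1.0
) -> pd.Series:
    """Volcano labels: up / down / ns at adj. p < p_thresh, |log2FC| > fc_thresh."""
    p = records["p_adj"].to_numpy()
    fc = records["log2fc"].to_numpy()
    sig = np.isfinite(p) & (p < p_thresh)
    label = np.where(sig & (fc > fc_thresh), "up",
                     np.where(sig & (fc < -fc_thresh), "down", "ns"))
    return pd.Series(label, index=records.index, name="regulation")
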