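"""Proteome normalization of phosphosite regulation.

A phosphosite's measured fold change confounds two sources: a change in
phosphorylation stoichiometry and a change in the parent protein's
abundance.  This module separates them conservatively:

1. **Fold-change correction.**  The parent protein-group's log2 fold change
   is subtracted from the phosphosite's::

       log2FC_corrected = log2FC_phospho - log2FC_protein

   A site with phospho log2FC 2 on a protein that itself moved by log2FC 2
   has corrected FC 0 — its phosphorylation stoichiometry did not change.

2. **p-value dampening.**  The phosphosite's p-value is pushed toward 1 as
   a function of how much of its fold change the protein explains::

       p_dampened = 10 ** (log10(p_ptm) * r_FC)

   where ``p_ptm`` is the raw phospho p-value and ``r_FC`` is the corrected
   log2 FC divided by the original log2 FC, clamped to [0, 1].  If the
   protein's regulation is as strong as or stronger than the phosphosite's
   (r_FC <= 0 before clamping), the dampened p-value is exactly 1; if the
   protein is unchanged (r_FC = 1), the p-value passes through unchanged.
   Because the transform is exponential on the logged p-value, small drops
   in r_FC already cost orders of magnitude: for p_ptm = 10^-k, the
   dampened p is 10^(-k * r_FC).

The clamp is deliberate: without it, a corrected FC exceeding the original
(r > 1) would make the p-value *more* significant, and opposite signs
(r < 0) would invert the transform.  Clamping keeps the procedure strictly
conservative — dampening can never create significance (p_dampened >=
p_ptm always).
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
import pandas as pd

from .diffexp import benjamini_hochberg

logger = logging.getLogger(__name__)

__all__ = [
    "correct_fold_change",
    "damping_ratio",
    "dampen_pvalue",
    "normalize_phospho_dataset",
]

#: Floor applied to p-values of exactly 0 before the log10 transform.
P_FLOOR = 1e-300


def correct_fold_change(log2fc_phospho: float, log2fc_protein: float) -> float:
    """Proteome-corrected phosphosite fold change (log2 units).

    Subtracts the parent protein's log2 fold change from the phosphosite's;
    the result estimates the change in phosphorylation stoichiometry.
    """
    if not (math.isfinite(log2fc_phospho) and math.isfinite(log2fc_protein)):
        raise ValueError(
            f"fold changes must be finite, got phospho={log2fc_phospho}, "
            f"protein={log2fc_protein}")
    return log2fc_phospho - log2fc_protein


def damping_ratio(log2fc_original: float, log2fc_corrected: float) -> float:
    """r_FC: corrected over original log2 FC, clamped to [0, 1].

    r = 1 means the protein explains none of the phospho change (no
    dampening); r = 0 means the protein explains all of it or more
    (p-value forced to 1).  An unregulated site (original FC 0) has nothing
    to dampen, so r = 1.
    """
    if not (math.isfinite(log2fc_original) and math.isfinite(log2fc_corrected)):
        raise ValueError("fold changes must be finite")
    if log2fc_original == 0.0:
        return 1.0
    return float(np.clip(log2fc_corrected / log2fc_original, 0.0, 1.0))


def dampen_pvalue(p_ptm: float, r_fc: float) -> float:
    """Exponential p-value dampening: ``10 ** (log10(p_ptm) * r_fc)``.

    Monotone: non-increasing in r_fc, non-decreasing in p_ptm; always
    >= p_ptm for r_fc in [0, 1], so it can only remove significance.
    """
    if not (0.0 <= r_fc <= 1.0):
        raise ValueError(f"r_fc must be in [0, 1], got {r_fc}")
    if p_ptm == 0.0:
        warnings.warn(f"p-value of exactly 0 floored at {P_FLOOR} before dampening")
        p_ptm = P_FLOOR
    if not (0.0 < p_ptm <= 1.0):
        raise ValueError(f"p_ptm must be in (0, 1], got {p_ptm}")
    return float(10.0 ** (math.log10(p_ptm) * r_fc))


def normalize_phospho_dataset(
    phospho_de: pd.DataFrame,
    protein_de: pd.DataFrame,
    site_to_protein: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join phosphosite DE results to parent-protein DE results and apply
    fold-change correction plus p-value dampening.

    Parameters
    ----------
    phospho_de, protein_de
        DE tables from :func:`phosphonorm.diffexp.differential_expression`
        computed on the *same* contrast (checked via ``attrs["contrast"]``
        when both carry it).
    site_to_protein
        Optional two-column table ``site_id``, ``protein_group``.  When
        omitted, the parent protein group is taken from the site id prefix
        (``<protein_group>_<residue><position>``).

    Matching uses the leading accession of the protein group on both sides.
    Unmatched sites keep their raw statistics with ``matched=False`` and
    r_FC = 1 (no dampening).  Benjamini-Hochberg is re-applied across the
    dampened p-values of all tested sites.
    """
    ca = phospho_de.attrs.get("contrast")
    cb = protein_de.attrs.get("contrast")
    if ca and cb and ca != cb:
        raise ValueError(f"contrast mismatch: phospho {ca!r} vs protein {cb!r}")

    sites = phospho_de.rename(columns={"feature_id": "site_id",
                                       "log2fc": "log2fc_phospho",
                                       "p_raw": "p_ptm"}).copy()
    if site_to_protein is None:
        parent = sites["site_id"].str.rsplit("_", n=1).str[0]
    else:
        lut = dict(zip(site_to_protein["site_id"], site_to_protein["protein_group"]))
        parent = sites["site_id"].map(lut)
    sites["protein_group"] = parent
    sites["lead_acc"] = sites["protein_group"].astype(str).str.split(";").str[0]

    prot = protein_de.loc[protein_de["tested"]].copy() if "tested" in protein_de else protein_de.copy()
    prot["lead_acc"] = prot["feature_id"].astype(str).str.split(";").str[0]
    prot_fc = dict(zip(prot["lead_acc"], prot["log2fc"]))

    fc_protein = sites["lead_acc"].map(prot_fc)
    matched = fc_protein.notna() & sites["log2fc_phospho"].notna()
    fc_phospho = sites["log2fc_phospho"]
    fc_corr = np.where(matched, fc_phospho - fc_protein, fc_phospho)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw_ratio = np.where(fc_phospho == 0.0, 1.0, fc_corr / fc_phospho)
    r_fc = np.where(matched, np.clip(raw_ratio, 0.0, 1.0), 1.0)

    p_ptm = sites["p_ptm"].to_numpy(dtype=float)
    p_damp = np.where(np.isfinite(p_ptm),
                      10.0 ** (np.log10(np.maximum(p_ptm, P_FLOOR)) * r_fc),
                      np.nan)
    # exact pass-through at the identity boundary (avoids log/exp round-trip)
    p_damp = np.where(r_fc == 1.0, p_ptm, p_damp)
    p_damp = np.minimum(p_damp, 1.0)

    tested = np.isfinite(p_damp)
    p_adj = np.full_like(p_damp, np.nan)
    if tested.any():
        p_adj[tested] = benjamini_hochberg(p_damp[tested])

    out = pd.DataFrame({
        "site_id": sites["site_id"],
        "protein_group": sites["protein_group"],
        "log2fc_phospho": fc_phospho,
        "log2fc_protein": fc_protein,
        "log2fc_corrected": np.where(matched, fc_corr, np.nan),
        "r_fc": r_fc,
        "p_ptm": p_ptm,
        "p_dampened": p_damp,
        "p_adj": p_adj,
        "matched": matched.to_numpy(),
    })
    out.attrs["contrast"] = ca or cb or ""
    out.attrs["r_fc_policy"] = "clamped to [0,1]; r=1 when original FC is 0"
    logger.info("proteome normalization: %d/%d sites matched to a protein DE record",
                int(matched.sum()), len(out))
    return out
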