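"""Collapse precursor-level phosphopeptide records to a phosphosite matrix.

A precursor contributes to a site (protein group, position, residue) iff
that site's localization probability meets the class-I cutoff (default
0.75); the cutoff is applied per site, so a multiply-phosphorylated
precursor may support one confident site and fail another.  Site intensity
per sample is the sum of the contributing precursors' intensities (linear
aggregation), which preserves intensity mass; all-missing sums stay
missing.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .matrix import IntensityMatrix, PhosphoReport

logger = logging.getLogger(__name__)

DEFAULT_LOC_CUTOFF = 0.75


def site_id(protein_group: str, position: int, residue: str) -> str:
    return f"{protein_group}_{residue}{position}"


def collapse_to_sites(
    report: PhosphoReport, loc_cutoff: float = DEFAULT_LOC_CUTOFF
) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Collapse a precursor report to a class-I phosphosite x sample matrix.

    Returns the site matrix (linear scale) and a provenance table mapping
    each site to its contributing precursor ids.
    """
    if not (0.0 <= loc_cutoff <= 1.0):
        raise ValueError(f"loc_cutoff must be in [0, 1], got {loc_cutoff}")
    samples = report.sample_ids
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    provenance: dict[str, list[str]] = {}
    meta: dict[str, tuple] = {}
    for rec in report.iter_records():
        vals = np.array([rec["intensities"][s] for s in samples], dtype=float)
        for pos, res, prob in rec["sites"]:
            if prob < loc_cutoff:
                continue
            sid = site_id(rec["protein_group"], pos, res)
            if sid not in sums:
                sums[sid] = np.zeros(len(samples))
                counts[sid] = 0
                provenance[sid] = []
                meta[sid] = (rec["protein_group"], pos, res)
            present = np.isfinite(vals)
            sums[sid][present] += vals[present]
            # track whether any precursor was observed per sample
            counts[sid] += 1
            provenance[sid].append(rec["precursor_id"])

    if not sums:
        empty = IntensityMatrix(pd.DataFrame(columns=samples, dtype=float), "linear")
        return empty, pd.DataFrame(columns=["site_id", "protein_group", "position",
                                            "residue", "n_precursors", "precursor_ids"])

    sids = sorted(sums)
    data = pd.DataFrame([sums[s] for s in sids], index=sids, columns=samples)
    # a cell where every contributing precursor was missing stays missing
    observed = pd.DataFrame(False, index=sids, columns=samples)
    for rec in report.iter_records():
        vals = np.array([rec["intensities"][s] for s in samples], dtype=float)
        for pos, res, prob in rec["sites"]:
            if prob < loc_cutoff:
                continue
            sid = site_id(rec["protein_group"], pos, res)
            observed.loc[sid] |= np.isfinite(vals)
    data = data.where(observed)

    prov = pd.DataFrame({
        "site_id": sids,
        "protein_group": [meta[s][0] for s in sids],
        "position": [meta[s][1] for s in sids],
        "residue": [meta[s][2] for s in sids],
        "n_precursors": [counts[s] for s in sids],
        "precursor_ids": [";".join(provenance[s]) for s in sids],
    })
    logger.info("collapsed %d precursors to %d class-I sites (cutoff %.2f)",
                report.n_precursors, len(sids), loc_cutoff)
    return IntensityMatrix(data, "linear"), prov


def count_identifications(sites: IntensityMatrix, report: PhosphoReport) -> dict:
    """Identification summary: distinct phosphopeptide precursors and
    class-I phosphosites, per sample (non-missing) and in total."""
    per_sample_sites = sites.data.notna().sum(axis=0).to_dict() if sites.n_features else {
        s: 0 for s in report.sample_ids}
    rep = report.table
    per_sample_prec = {
        s: int(rep[s].notna().sum()) if len(rep) else 0 for s in report.sample_ids
    }
    return {
        "total_phosphosites": int(sites.n_features),
        "total_precursors": int(rep["precursor_id"].nunique()) if len(rep) else 0,
        "phosphosites_per_sample": {k: int(v) for k, v in per_sample_sites.items()},
        "precursors_per_sample": per_sample_prec,
    }
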