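"""Readers and writers for the TSV dialects the pipeline touches.

Dialects:

* protein matrix — TSV, first column ``Protein.Group``, one column per
  sample (DIA-NN ``pg_matrix.tsv`` style);
* transcriptome matrix — TSV, first column ``gene_id``;
* phospho report — long TSV with precursor metadata columns followed by one
  intensity column per sample;
* design — TSV with ``sample_id``, ``cell_type``, ``treatment``,
  ``replicate``;
* mapping — two-column TSV ``gene_id``, ``protein_group``.

Zero intensities are treated as missing by default (DIA exports encode
non-detection as blank or 0 depending on settings); pass
``zero_as_missing=False`` to keep zeros.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .matrix import (
    GeneProteinMap,
    IntensityMatrix,
    PhosphoReport,
    SampleDesign,
)

logger = logging.getLogger(__name__)

PROTEIN_FEATURE_COL = "Protein.Group"
GENE_FEATURE_COL = "gene_id"


def _read_matrix(path, feature_col: str, design: SampleDesign | None,
                 zero_as_missing: bool) -> IntensityMatrix:
    df = pd.read_csv(path, sep="\t", dtype={0: str}, float_precision="round_trip")
    if feature_col not in df.columns:
        raise ValueError(f"{path}: expected first column {feature_col!r}, got {df.columns[0]!r}")
    dup = df[feature_col][df[feature_col].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate feature ids: {sorted(dup.unique().tolist())}")
    df = df.set_index(feature_col)
    df.index.name = None
    df = df.apply(pd.to_numeric, errors="coerce")
    if zero_as_missing:
        df = df.where(df != 0.0)
    if design is not None:
        design.check_covers(df.columns)
    mat = IntensityMatrix(df, scale="linear")
    logger.info(
        "read %s: %d features x %d samples, missing fraction %.3f, zero_as_missing=%s",
        path, mat.n_features, mat.n_samples, mat.missing_fraction(), zero_as_missing,
    )
    return mat


def read_protein_matrix(path, design: SampleDesign | None = None,
                        zero_as_missing: bool = True) -> IntensityMatrix:
    """Read a DIA-NN-style protein-group intensity matrix (linear scale)."""
    return _read_matrix(path, PROTEIN_FEATURE_COL, design, zero_as_missing)


def read_transcript_matrix(path, design: SampleDesign | None = None,
                           zero_as_missing: bool = True) -> IntensityMatrix:
    """Read a gene-level count/abundance matrix (linear scale)."""
    return _read_matrix(path, GENE_FEATURE_COL, design, zero_as_missing)


def write_matrix(matrix: IntensityMatrix, path, feature_col: str = PROTEIN_FEATURE_COL) -> None:
    out = matrix.data.copy()
    out.index.name = feature_col
    out.to_csv(path, sep="\t")


def read_phospho_report(path) -> PhosphoReport:
    """Read a long-format precursor-level phospho report.

    Localization probabilities are validated against [0, 1] with the
    offending row number reported.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    report = PhosphoReport(df)
    for idx, row in df.iterrows():
        for p in str(row["localization_probs"]).split(";"):
            v = float(p)
            if not (0.0 <= v <= 1.0) or math.isnan(v):
                raise ValueError(
                    f"{path}: row {idx}: localization probability {p} outside [0, 1]"
                )
    logger.info("read %s: %d precursors, %d samples", path, report.n_precursors,
                len(report.sample_ids))
    return report


def write_phospho_report(report: PhosphoReport, path) -> None:
    report.table.to_csv(path, sep="\t", index=False)


def read_design(path) -> SampleDesign:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return SampleDesign(df)


def write_design(design: SampleDesign, path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def read_gene_protein_map(path) -> GeneProteinMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return GeneProteinMap(df, provenance=str(path))


def write_gene_protein_map(gpmap: GeneProteinMap, path) -> None:
    gpmap.pairs.to_csv(path, sep="\t", index=False)


def log2_transform(matrix: IntensityMatrix, zero_as_missing: bool = True) -> IntensityMatrix:
    """log2-transform a linear-scale matrix.

    Zeros become missing under the default zero policy (log2(0) is not a
    usable intensity); the result carries scale ``log2``.
    """
    if matrix.scale != "linear":
        raise ValueError("log2_transform requires a linear-scale matrix")
    data = matrix.data
    if zero_as_missing:
        data = data.where(data != 0.0)
    elif (data == 0.0).any().any():
        raise ValueError("zero intensities present with zero_as_missing disabled")
    out = np.log2(data)
    logger.info("log2 transform: missing fraction %.3f", float(out.isna().to_numpy().mean()))
    return IntensityMatrix(out, scale="log2")
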