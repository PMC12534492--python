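"""Core data containers shared across the pipeline.

An :class:`IntensityMatrix` is a features x samples abundance table backed by
a pandas DataFrame, with NaN as the explicit missing marker and a scale flag
(``linear`` or ``log2``).  A :class:`SampleDesign` maps every sample column to
its (cell_type, treatment, replicate) labels.  A :class:`GeneProteinMap`
carries gene <-> protein-group identifier pairs for cross-omics matching.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "IntensityMatrix",
    "SampleDesign",
    "GeneProteinMap",
    "PhosphoReport",
    "PHOSPHO_META_COLUMNS",
]

#: Metadata columns of a long-format phosphopeptide precursor report; every
#: remaining column is a per-sample intensity.
PHOSPHO_META_COLUMNS = (
    "precursor_id",
    "protein_group",
    "positions",
    "residues",
    "localization_probs",
    "multiplicity",
)


@dataclass
class IntensityMatrix:
    """Features x samples abundance matrix with explicit missingness.

    Parameters
    ----------
    data
        DataFrame indexed by feature id with one column per sample id.
        Missing values are NaN.
    scale
        ``"linear"`` (raw intensities, >= 0 where present) or ``"log2"``.
    """

    data: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"scale must be 'linear' or 'log2', got {self.scale!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        self.data = self.data.astype(float)
        if self.scale == "linear":
            vals = self.data.to_numpy()
            if np.nanmin(vals, initial=0.0) < 0:
                raise ValueError("linear-scale intensities must be >= 0 where present")

    @property
    def feature_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def missing_fraction(self) -> float:
        return float(self.data.isna().to_numpy().mean()) if self.data.size else 0.0

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(self.data.copy(), self.scale)


@dataclass
class SampleDesign:
    """Per-sample experimental annotation: cell type, treatment, replicate."""

    table: pd.DataFrame  # columns: sample_id, cell_type, treatment, replicate

    REQUIRED = ("sample_id", "cell_type", "treatment", "replicate")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"design table missing columns: {missing}")
        if self.table["sample_id"].duplicated().any():
            dups = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample ids in design: {dups}")
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def cell_types(self) -> list[str]:
        return list(dict.fromkeys(self.table["cell_type"]))

    @property
    def treatments(self) -> list[str]:
        return list(dict.fromkeys(self.table["treatment"]))

    def samples_for(self, cell_type: str, treatment: str) -> list[str]:
        """Sample ids of one (cell_type, treatment) group, in design order."""
        mask = (self.table["cell_type"] == cell_type) & (self.table["treatment"] == treatment)
        return self.table.loc[mask, "sample_id"].tolist()

    def groups(self) -> Iterator[tuple[tuple[str, str], list[str]]]:
        """Iterate (cell_type, treatment) groups with their sample ids."""
        for ct in self.cell_types:
            for tr in self.treatments:
                ids = self.samples_for(ct, tr)
                if ids:
                    yield (ct, tr), ids

    def check_covers(self, sample_ids) -> None:
        unmatched = [s for s in sample_ids if s not in set(self.table["sample_id"])]
        if unmatched:
            raise ValueError(f"samples absent from design: {unmatched}")


@dataclass
class GeneProteinMap:
    """Gene <-> protein-group identifier pairs used for omics integration.

    The mapping is applied as given: features without a pair are dropped from
    integration, never invented.
    """

    pairs: pd.DataFrame  # columns: gene_id, protein_group
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in ("gene_id", "protein_group") if c not in self.pairs.columns]
        if missing:
            raise ValueError(f"mapping table missing columns: {missing}")
        self.pairs = self.pairs[["gene_id", "protein_group"]].drop_duplicates().reset_index(drop=True)

    def one_to_one(self) -> pd.DataFrame:
        """Restrict to unambiguous 1:1 gene-protein pairs.

        Genes mapping to several protein groups and protein groups hit by
        several genes are removed; ambiguity is resolved by exclusion, not by
        guessing.
        """
        p = self.pairs
        ok_gene = ~p["gene_id"].duplicated(keep=False)
        ok_prot = ~p["protein_group"].duplicated(keep=False)
        return p[ok_gene & ok_prot].reset_index(drop=True)


@dataclass
class PhosphoReport:
    """Long-format precursor-level phosphopeptide report.

    One row per precursor with ";"-separated per-site positions, residues and
    localization probabilities, plus one intensity column per sample.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PHOSPHO_META_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"phospho report missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return [c for c in self.table.columns if c not in PHOSPHO_META_COLUMNS]

    @property
    def n_precursors(self) -> int:
        return len(self.table)

    def iter_records(self) -> Iterator[dict]:
        """Yield one parsed record per report row.

        Each record carries ``sites``: a list of (position, residue, prob)
        tuples, positions 1-based on the protein.
        """
        samples = self.sample_ids
        for idx, row in self.table.iterrows():
            positions = parse_int_list(row["positions"])
            residues = str(row["residues"]).split(";")
            probs = parse_float_list(row["localization_probs"])
            if not (len(positions) == len(residues) == len(probs)):
                raise ValueError(
                    f"row {idx}: positions/residues/localization_probs lengths differ"
                )
            for p in probs:
                if not (0.0 <= p <= 1.0):
                    raise ValueError(
                        f"row {idx}: localization probability {p} outside [0, 1]"
                    )
            if any(b <= a for a, b in zip(positions, positions[1:])):
                raise ValueError(f"row {idx}: positions must be strictly increasing")
            yield {
                "precursor_id": row["precursor_id"],
                "protein_group": row["protein_group"],
                "sites": list(zip(positions, residues, probs)),
                "multiplicity": int(row["multiplicity"]),
                "intensities": {s: row[s] for s in samples},
            }


def parse_int_list(value) -> list[int]:
    return [int(x) for x in str(value).split(";")]


def parse_float_list(value) -> list[float]:
    return [float(x) for x in str(value).split(";")]
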