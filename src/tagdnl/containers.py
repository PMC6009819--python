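"""Sample x lipid-feature intensity container and its TSV contract.

The on-disk contract is a TSV with a header row and columns
``sample_id, plate, is_qc, <feature columns named Class(C:DB)>``.
Intensities are nonnegative ion counts in arbitrary units. Features carrying
any missing value are dropped at ingestion (the analyses use the set of
lipids common across the dataset); no imputation is performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lipids import LipidSpecies, parse_lipid_label

__all__ = ["FeatureTable"]

META_COLUMNS = ("sample_id", "plate", "is_qc")


@dataclass
class FeatureTable:
    """Samples x features intensity table with plate and QC-pool metadata.

    Attributes
    ----------
    intensities : DataFrame indexed by sample_id, columns are feature labels.
    plate : per-sample plate identifier (aligned to ``intensities.index``).
    is_qc : boolean per-sample flag marking pooled-QC injections.
    species : parsed :class:`~tagdnl.lipids.LipidSpecies` per feature column.
    """

    intensities: pd.DataFrame
    plate: pd.Series
    is_qc: pd.Series
    species: list[LipidSpecies] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.plate.index.equals(self.intensities.index):
            self.plate = self.plate.reindex(self.intensities.index)
        if not self.is_qc.index.equals(self.intensities.index):
            self.is_qc = self.is_qc.reindex(self.intensities.index)
        self.is_qc = self.is_qc.astype(bool)
        if self.intensities.columns.has_duplicates:
            dups = self.intensities.columns[self.intensities.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature labels: {dups}")
        if self.intensities.isna().any().any():
            bad = self.intensities.columns[self.intensities.isna().any()].tolist()
            warnings.warn(f"dropping {len(bad)} feature(s) with missing values: {bad[:5]}...")
            self.intensities = self.intensities.drop(columns=bad)
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("negative intensities are not allowed")
        if not self.species or len(self.species) != self.intensities.shape[1]:
            self.species = [parse_lipid_label(c) for c in self.intensities.columns]

    # -- views ------------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    @property
    def feature_labels(self) -> list[str]:
        return list(self.intensities.columns)

    def classes(self) -> pd.Series:
        """Lipid class per feature column."""
        return pd.Series([s.lipid_class for s in self.species], index=self.intensities.columns)

    def subjects(self) -> "FeatureTable":
        """Non-QC rows only."""
        keep = ~self.is_qc
        return FeatureTable(
            self.intensities.loc[keep].copy(),
            self.plate.loc[keep].copy(),
            self.is_qc.loc[keep].copy(),
            list(self.species),
        )

    def qc(self) -> "FeatureTable":
        keep = self.is_qc
        return FeatureTable(
            self.intensities.loc[keep].copy(),
            self.plate.loc[keep].copy(),
            self.is_qc.loc[keep].copy(),
            list(self.species),
        )

    def select_class(self, lipid_class: str) -> "FeatureTable":
        """Restrict to feature columns of one lipid class."""
        keep = [s.label for s in self.species if s.lipid_class == lipid_class]
        sp = [s for s in self.species if s.lipid_class == lipid_class]
        return FeatureTable(
            self.intensities[keep].copy(), self.plate.copy(), self.is_qc.copy(), sp
        )

    # -- IO ---------------------------------------------------------------

    def to_tsv(self, path) -> None:
        out = self.intensities.copy()
        out.insert(0, "is_qc", self.is_qc.astype(int))
        out.insert(0, "plate", self.plate)
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path, sep="\t", index_col="sample_id")
        missing = [c for c in ("plate", "is_qc") if c not in df.columns]
        if missing:
            raise ValueError(f"feature table at {path} lacks required column(s) {missing}")
        plate = df["plate"]
        is_qc = df["is_qc"].astype(bool)
        intens = df.drop(columns=["plate", "is_qc"]).astype(float)
        return cls(intens, plate, is_qc)

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.intensities.copy(), self.plate.copy(), self.is_qc.copy(), list(self.species)
        )


def as_matrix(table: FeatureTable) -> np.ndarray:
    return table.intensities.to_numpy(dtype=float)
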