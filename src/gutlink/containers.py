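"""In-memory containers for taxa tables and metabolite feature matrices.

Both containers wrap pandas DataFrames (samples as rows) plus the side
information the analysis needs: gut location and taxonomy for microbial
tables; injection order, QC flags and annotation for LC-MS feature
matrices. Intensity 0 is the missing-value convention for metabolite
features throughout the package.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

LOCATIONS = ("ileum", "cecum", "faeces")
LEVELS = ("ASV", "genus", "species")
MSI_LEVELS = (1, 2, 3, 4)  # unannotated features carry level NaN/None


@dataclass
class TaxaTable:
    """Samples x taxa abundance matrix for one gut location.

    Parameters
    ----------
    data : DataFrame
        Non-negative abundances, one row per sample, one column per taxon.
        Either integer counts or relative abundances.
    location : str
        Gut location the samples come from; one of ``LOCATIONS``.
    level : str
        Taxonomic unit of the columns (``ASV``, ``genus`` or ``species``).
    taxonomy : dict, optional
        taxon_id -> lineage string.
    """

    data: pd.DataFrame
    location: str
    level: str = "ASV"
    taxonomy: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.location not in LOCATIONS:
            raise ValueError(f"unknown location {self.location!r}; expected one of {LOCATIONS}")
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}; expected one of {LEVELS}")
        if not self.data.index.is_unique:
            raise ValueError("sample ids must be unique")
        if not self.data.columns.is_unique:
            raise ValueError("taxon ids must be unique")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")

    # -- basic views -------------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def is_count_table(self) -> bool:
        arr = self.data.to_numpy()
        return bool(np.allclose(arr, np.round(arr)) and arr.max(initial=0) > 1)

    def relative_abundance(self) -> pd.DataFrame:
        """Row-normalized proportions. Rows with zero total raise."""
        totals = self.data.sum(axis=1)
        if (totals == 0).any():
            bad = list(totals.index[totals == 0])
            raise ValueError(f"samples with zero total abundance: {bad}")
        return self.data.div(totals, axis=0)

    def presence(self) -> pd.DataFrame:
        return self.data > 0

    def with_data(self, data: pd.DataFrame) -> "TaxaTable":
        return dataclasses.replace(self, data=data)

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, path: str | Path, taxonomy_path: str | Path | None = None) -> None:
        df = self.data.copy()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t", float_format="%.10g")
        if taxonomy_path is not None:
            tax = self.taxonomy or {}
            pd.DataFrame(
                {"taxon_id": self.taxon_ids,
                 "lineage": [tax.get(t, "") for t in self.taxon_ids]}
            ).to_csv(taxonomy_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, location: str, level: str = "ASV",
                 taxonomy_path: str | Path | None = None) -> "TaxaTable":
        data = pd.read_csv(path, sep="\t", index_col=0)
        taxonomy = None
        if taxonomy_path is not None:
            tax = pd.read_csv(taxonomy_path, sep="\t")
            taxonomy = dict(zip(tax["taxon_id"].astype(str), tax["lineage"].fillna("")))
        return cls(data=data, location=location, level=level, taxonomy=taxonomy)


@dataclass
class MetaboFeatureMatrix:
    """Samples x metabolite-feature intensity matrix with run metadata.

    ``data`` holds non-negative intensities (0 = missing) for biological and
    QC samples alike; ``is_qc`` distinguishes pooled QC injections from test
    samples, ``injection_order`` records the run sequence and ``annotation``
    carries per-feature compound name, MSI confidence level and ion mode.
    """

    data: pd.DataFrame
    injection_order: pd.Series
    is_qc: pd.Series
    annotation: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if not self.data.index.is_unique:
            raise ValueError("sample ids must be unique")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("intensities must be non-negative")
        self.injection_order = self.injection_order.reindex(self.data.index)
        self.is_qc = self.is_qc.reindex(self.data.index).astype(bool)
        if self.injection_order.isna().any():
            raise ValueError("every sample needs an injection order")
        if self.injection_order.duplicated().any():
            raise ValueError("injection orders must be unique")
        if self.annotation.empty:
            self.annotation = pd.DataFrame(
                {"compound": pd.Series("", index=self.data.columns, dtype=object),
                 "msi_level": pd.Series(np.nan, index=self.data.columns),
                 "ion_mode": pd.Series("positive", index=self.data.columns, dtype=object)}
            )
        else:
            self.annotation = self.annotation.reindex(self.data.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_qc(self) -> int:
        return int(self.is_qc.sum())

    def qc_data(self) -> pd.DataFrame:
        return self.data.loc[self.is_qc]

    def test_data(self) -> pd.DataFrame:
        """Intensity matrix restricted to biological (non-QC) samples."""
        return self.data.loc[~self.is_qc]

    def select_features(self, feature_ids) -> "MetaboFeatureMatrix":
        feature_ids = list(feature_ids)
        return MetaboFeatureMatrix(
            data=self.data[feature_ids],
            injection_order=self.injection_order,
            is_qc=self.is_qc,
            annotation=self.annotation.loc[feature_ids],
        )

    def with_data(self, data: pd.DataFrame) -> "MetaboFeatureMatrix":
        return MetaboFeatureMatrix(
            data=data,
            injection_order=self.injection_order,
            is_qc=self.is_qc,
            annotation=self.annotation.loc[data.columns],
        )

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, path: str | Path, annotation_path: str | Path | None = None) -> None:
        df = self.data.copy()
        df.insert(0, "injection_order", self.injection_order.astype(int))
        df.insert(1, "is_qc", self.is_qc.astype(int))
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t", float_format="%.10g")
        if annotation_path is not None:
            ann = self.annotation.copy()
            ann.index.name = "feature_id"
            ann.to_csv(annotation_path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path,
                 annotation_path: str | Path | None = None) -> "MetaboFeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        order = df.pop("injection_order")
        is_qc = df.pop("is_qc").astype(bool)
        annotation = pd.DataFrame()
        if annotation_path is not None:
            annotation = pd.read_csv(annotation_path, sep="\t", index_col=0)
        return cls(data=df, injection_order=order, is_qc=is_qc, annotation=annotation)
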