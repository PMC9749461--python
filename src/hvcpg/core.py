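"""Shared containers and error types for the hvCpG discovery pipeline.

Methylation levels are Beta values (methylated / total intensity, in [0, 1])
on Illumina-array CpG probes.  A *dataset* is one cohort's CpG x sample Beta
matrix plus per-sample covariates; the pipeline treats datasets as disjoint
cohorts (no shared individuals).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd


class ConfigurationError(ValueError):
    """Invalid parameter combination supplied by the user."""


class InputError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass
class MethylationDataset:
    """One study's methylation Beta matrix with sample metadata.

    Parameters
    ----------
    dataset_id
        Short label, unique within an analysis (e.g. ``"Blood_Cauc"``).
    beta
        CpG x sample DataFrame of Beta values in [0, 1]; NaN marks missing.
    covariates
        Sample-indexed DataFrame; recognised columns are ``age`` (years)
        and ``sex`` (``"male"``/``"female"``).  May be empty.
    detection_p
        Optional CpG x sample detection p-value matrix aligned to ``beta``.
    tissue, ethnicity
        Free-text annotations used for reporting only.
    """

    dataset_id: str
    beta: pd.DataFrame
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)
    detection_p: Optional[pd.DataFrame] = None
    tissue: str = ""
    ethnicity: str = ""

    def __post_init__(self) -> None:
        vals = self.beta.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals, initial=np.inf) < 0 or np.nanmax(vals, initial=-np.inf) > 1:
                raise InputError(f"{self.dataset_id}: Beta values outside [0, 1]")
        if self.beta.columns.duplicated().any():
            raise InputError(f"{self.dataset_id}: duplicate sample ids")
        if self.beta.index.duplicated().any():
            raise InputError(f"{self.dataset_id}: duplicate CpG ids")
        if self.detection_p is not None:
            if not self.detection_p.index.equals(self.beta.index) or not (
                self.detection_p.columns.equals(self.beta.columns)
            ):
                raise InputError(
                    f"{self.dataset_id}: detection_p axes do not match beta"
                )

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    @property
    def n_cpgs(self) -> int:
        return self.beta.shape[0]

    def subset_cpgs(self, cpgs) -> "MethylationDataset":
        """Return a copy restricted to ``cpgs`` (order preserved)."""
        keep = self.beta.index.intersection(pd.Index(cpgs))
        return MethylationDataset(
            dataset_id=self.dataset_id,
            beta=self.beta.loc[keep].copy(),
            covariates=self.covariates.copy(),
            detection_p=None if self.detection_p is None else self.detection_p.loc[keep].copy(),
            tissue=self.tissue,
            ethnicity=self.ethnicity,
        )


@dataclass
class ProbeAnnotation:
    """Per-CpG genomic coordinates (hg19-style, 1-based) and reliability flag.

    ``table`` is indexed by CpG id with columns ``chrom`` (str), ``pos``
    (1-based int) and ``reliable`` (bool).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "reliable"}
        missing = required - set(self.table.columns)
        if missing:
            raise InputError(f"annotation missing columns: {sorted(missing)}")
        if self.table.index.duplicated().any():
            raise InputError("duplicate CpG ids in annotation")
        if (self.table["pos"] < 1).any():
            raise InputError("annotation positions must be >= 1 (1-based)")

    @property
    def cpgs(self) -> pd.Index:
        return self.table.index

    def positions(self, cpgs) -> pd.DataFrame:
        """(chrom, pos) rows for ``cpgs``; raises on unannotated ids."""
        idx = pd.Index(cpgs)
        missing = idx.difference(self.table.index)
        if len(missing):
            raise InputError(f"unannotated CpGs: {sorted(missing)[:10]}")
        return self.table.loc[idx, ["chrom", "pos"]]

    def unreliable_ids(self) -> set:
        return set(self.table.index[~self.table["reliable"].astype(bool)])


@dataclass
class FetalStudy:
    """Multi-tissue fetal methylation data for three germ-layer pairs.

    ``groups`` maps a pair label (``"endo-meso"``, ``"endo-ecto"``,
    ``"meso-ecto"``) to a pair of CpG x individual Beta DataFrames
    (tissue A, tissue B) sharing both axes.
    """

    groups: dict

    GROUP_LABELS = ("endo-meso", "endo-ecto", "meso-ecto")

    def __post_init__(self) -> None:
        for name, (a, b) in self.groups.items():
            if not a.index.equals(b.index) or not a.columns.equals(b.columns):
                raise InputError(f"group {name}: tissue matrices misaligned")
            if a.shape[1] < 2:
                raise InputError(f"group {name}: fewer than 2 individuals")

    @property
    def n_individuals(self) -> int:
        return sum(a.shape[1] for a, _ in self.groups.values())

    @property
    def cpgs(self) -> pd.Index:
        first = next(iter(self.groups.values()))
        return first[0].index
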