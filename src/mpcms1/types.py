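"""Core in-memory containers for the screening pipeline.

Internal orientation is fixed to features x samples throughout: the
intensity matrix X has one row per aligned MS1 feature (annotated with
retention time and m/z where available) and one column per sample.
Missing measurements are NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class IntensityMatrix:
    """Features x samples intensity table.

    Parameters
    ----------
    values
        Float array, shape (n_features, n_samples).  Absent measurements
        are NaN; present values are non-negative raw intensities (or log2
        values after transformation).
    feature_ids, sample_ids
        Unique string identifiers for rows and columns.
    rt, mz
        Optional per-feature retention time (seconds) and mass-to-charge.
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    rt: np.ndarray | None = None
    mz: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("intensity values must be a 2-D array")
        nf, ns = self.values.shape
        if len(self.feature_ids) != nf:
            raise ValueError(
                f"{len(self.feature_ids)} feature ids for {nf} matrix rows"
            )
        if len(self.sample_ids) != ns:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {ns} matrix columns"
            )
        if len(set(self.feature_ids)) != nf:
            raise ValueError("duplicate feature ids")
        if len(set(self.sample_ids)) != ns:
            raise ValueError("duplicate sample ids")
        if self.rt is not None:
            self.rt = np.asarray(self.rt, dtype=float)
            if self.rt.shape != (nf,):
                raise ValueError("rt length does not match feature count")
        if self.mz is not None:
            self.mz = np.asarray(self.mz, dtype=float)
            if self.mz.shape != (nf,):
                raise ValueError("mz length does not match feature count")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask of absent entries."""
        return np.isnan(self.values)

    def copy_with(self, values: np.ndarray) -> "IntensityMatrix":
        """New matrix with the same annotations and replaced values."""
        return IntensityMatrix(
            values=np.array(values, dtype=float),
            feature_ids=list(self.feature_ids),
            sample_ids=list(self.sample_ids),
            rt=None if self.rt is None else self.rt.copy(),
            mz=None if self.mz is None else self.mz.copy(),
        )

    def subset_features(self, index: np.ndarray) -> "IntensityMatrix":
        index = np.asarray(index)
        return IntensityMatrix(
            values=self.values[index],
            feature_ids=[self.feature_ids[i] for i in np.flatnonzero(index)]
            if index.dtype == bool
            else [self.feature_ids[i] for i in index],
            sample_ids=list(self.sample_ids),
            rt=None if self.rt is None else self.rt[index],
            mz=None if self.mz is None else self.mz[index],
        )

    def subset_samples(self, index: np.ndarray) -> "IntensityMatrix":
        index = np.asarray(index)
        cols = np.flatnonzero(index) if index.dtype == bool else index
        return IntensityMatrix(
            values=self.values[:, cols],
            feature_ids=list(self.feature_ids),
            sample_ids=[self.sample_ids[i] for i in cols],
            rt=None if self.rt is None else self.rt.copy(),
            mz=None if self.mz is None else self.mz.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_ids
        )


@dataclass
class DesignTable:
    """Sample-to-condition mapping with optional covariates.

    Condition levels keep first-appearance order from the design file so
    downstream outputs line up with how the experiment was laid out.
    """

    sample_ids: list[str]
    condition: list[str]
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.condition = [str(c) for c in self.condition]
        if len(self.sample_ids) != len(self.condition):
            raise ValueError("sample_ids and condition lengths differ")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids in design")

    @property
    def levels(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.condition:
            seen.setdefault(c, None)
        return list(seen)

    def condition_of(self, sample_id: str) -> str:
        return self.condition[self.sample_ids.index(sample_id)]

    def aligned_conditions(self, sample_ids: list[str]) -> list[str]:
        """Conditions in the order of the given sample ids."""
        lookup = dict(zip(self.sample_ids, self.condition))
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise KeyError(f"samples absent from design: {missing}")
        return [lookup[s] for s in sample_ids]

    def subset(self, sample_ids: list[str]) -> "DesignTable":
        keep = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [keep[s] for s in sample_ids]
        cov = None
        if self.covariates is not None:
            cov = self.covariates.iloc[idx].reset_index(drop=True)
        return DesignTable(
            sample_ids=list(sample_ids),
            condition=[self.condition[i] for i in idx],
            covariates=cov,
        )
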