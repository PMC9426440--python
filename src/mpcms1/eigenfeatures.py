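"""Module eigenfeatures and their correlation with experimental conditions.

Each feature module is summarized by its eigenfeature: the first right
singular vector of the module's standardized (per-feature centered and
unit-variance) log2 intensity sub-matrix, i.e. the eigengene construction
applied to MS1 features.  The sign is anchored so the eigenfeature
correlates non-negatively with the module's mean standardized profile.
Eigenfeatures are then correlated (Pearson) with one-hot condition
indicator variables to yield the module x condition profile that drives
condition clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .kmedoids import FeatureClustering
from .types import DesignTable, IntensityMatrix

logger = logging.getLogger(__name__)


@dataclass
class EigenfeatureSet:
    """Modules x samples eigenfeature matrix with variance bookkeeping."""

    E: np.ndarray  # modules x samples, unit-norm rows
    explained_variance: np.ndarray  # fraction per module, in (0, 1]
    sign_anchor: np.ndarray  # bool per module: aligned to mean profile
    module_ids: np.ndarray


@dataclass
class GroupCorrelationProfile:
    """Modules x conditions Pearson correlation matrix."""

    R: np.ndarray
    conditions: list[str]
    module_ids: np.ndarray


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xs, ys = x.std(), y.std()
    if xs == 0 or ys == 0:
        raise ValueError("zero-variance vector in correlation")
    return float(np.dot(x - x.mean(), y - y.mean()) / (len(x) * xs * ys))


def compute_eigenfeatures(log2_matrix, labels) -> EigenfeatureSet:
    """First singular direction per module, sign-anchored to the mean profile.

    Parameters
    ----------
    log2_matrix
        IntensityMatrix (or ndarray) of log2 intensities, features x samples.
    labels
        FeatureClustering or integer array of module ids per feature.
    """
    X = log2_matrix.values if isinstance(log2_matrix, IntensityMatrix) else np.asarray(log2_matrix, float)
    lab = labels.labels if isinstance(labels, FeatureClustering) else np.asarray(labels)
    if X.shape[0] != lab.shape[0]:
        raise ValueError("label count does not match feature count")
    if X.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    module_ids = np.unique(lab)
    E, ev, anchored = [], [], []
    for m in module_ids:
        sub = X[lab == m]
        sd = sub.std(axis=1)
        if np.any(sd == 0):
            raise ValueError(f"zero-variance feature row in module {m}")
        Z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        v = Vt[0]
        mean_profile = Z.mean(axis=0)
        if mean_profile.std() > 0 and _pearson(v, mean_profile) < 0:
            v = -v
        E.append(v / np.linalg.norm(v))
        ev.append(float(s[0] ** 2 / np.sum(s**2)))
        anchored.append(True)
    return EigenfeatureSet(
        E=np.array(E),
        explained_variance=np.array(ev),
        sign_anchor=np.array(anchored, dtype=bool),
        module_ids=module_ids,
    )


def condition_indicators(design: DesignTable) -> tuple[np.ndarray, list[str]]:
    """One-hot conditions x samples matrix in first-appearance level order."""
    levels = design.levels
    if len(levels) < 2:
        raise ValueError("need at least 2 conditions for indicator correlation")
    cond = np.array(design.condition)
    M = np.array([(cond == lv).astype(float) for lv in levels])
    if np.any(M.sum(axis=1) == len(design.sample_ids)):
        raise ValueError("a condition covering all samples has an undefined correlation")
    return M, levels


def correlate_eigenfeatures(
    eigen: EigenfeatureSet, indicators: np.ndarray, conditions: list[str]
) -> GroupCorrelationProfile:
    """Pearson r of every eigenfeature against every condition indicator."""
    E = eigen.E
    if E.shape[1] != indicators.shape[1]:
        raise ValueError("eigenfeature and indicator sample counts differ")
    if np.any(E.std(axis=1) == 0):
        raise ValueError("zero-variance eigenfeature")
    if np.any(indicators.std(axis=1) == 0):
        raise ValueError("constant condition indicator")
    Ez = (E - E.mean(axis=1, keepdims=True)) / E.std(axis=1, keepdims=True)
    Iz = (indicators - indicators.mean(axis=1, keepdims=True)) / indicators.std(
        axis=1, keepdims=True
    )
    R = np.clip(Ez @ Iz.T / E.shape[1], -1.0, 1.0)
    return GroupCorrelationProfile(R=R, conditions=list(conditions), module_ids=eigen.module_ids)
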