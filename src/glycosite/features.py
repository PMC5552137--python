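"""Assembly of the 173-coefficient miscellany feature vector.

Layout (fixed, versioned by position):

====================  ======  ==========================================
block                 length  contents
====================  ======  ==========================================
SVV                      41   raw integer residue codes of the window
FM                       20   frequency vector tau
AAPIV                    20   position-sum vector mu
RAAPIV                   20   reversed position-sum vector eta
grid moments             24   raw(8) | central(8) | Hahn(8) of the 7x7 grid
PRIM moments             24   same three families of the 20x20 PRIM
RPRIM moments            24   same three families of the 20x20 RPRIM
====================  ======  ==========================================

Total 41 + 3*20 + 3*24 = 173.  An all-zero matrix has no centroid, so its
central-moment block is defined as zeros (degenerate-centroid convention).

Features are standardized (zero mean, unit spread on the training set)
before network training; Hahn and raw moments of 20x20 incidence matrices
span many orders of magnitude and gradient descent needs comparable scales.
Constant features keep spread 1 so they pass through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import moments as mom
from . import position_composition as pc
from .peptide_windows import SiteWindow

#: Total feature vector length.
FEATURE_LENGTH = 173

#: Length of one raw|central|Hahn moment block.
MOMENT_BLOCK = 24


def matrix_moment_block(matrix: np.ndarray) -> np.ndarray:
    """raw(8) | central(8) | Hahn(8) moments of a square matrix (24 values).

    For an all-zero matrix the centroid is undefined; its central block is
    zeros by convention (raw and Hahn blocks are zero by linearity anyway).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("moment block requires a square matrix")
    raw = mom.raw_moments(matrix)
    if raw[(0, 0)] == 0:
        central = np.zeros(8)
    else:
        central = mom.central_moments(matrix).as_array()
    hahn = mom.hahn_moments(matrix)
    return np.concatenate([raw.as_array(), central, hahn.as_array()])


def assemble_feature_vector(window: SiteWindow) -> np.ndarray:
    """The 173-coefficient feature vector of one window (pure function)."""
    codes = window.codes
    grid = mom.reshape_to_grid(codes)
    parts = [
        codes.astype(float),
        pc.frequency_vector(window),
        pc.aapiv(window),
        pc.raapiv(window),
        matrix_moment_block(grid),
        matrix_moment_block(pc.prim(window)),
        matrix_moment_block(pc.rprim(window)),
    ]
    fv = np.concatenate(parts)
    assert fv.size == FEATURE_LENGTH
    return fv


def feature_matrix(windows: Sequence[SiteWindow]
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Stack windows into (X, y); unknown labels become -1 in y."""
    X = np.stack([assemble_feature_vector(w) for w in windows])
    y = np.array([-1 if w.label is None else w.label for w in windows],
                 dtype=np.int64)
    return X, y


@dataclass
class ScalerParams:
    """Per-feature location/spread learned on training data only."""

    mean: np.ndarray
    scale: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        if self.mean.shape != self.scale.shape:
            raise ValueError("mean/scale shape mismatch")
        if np.any(self.scale <= 0):
            raise ValueError("scale must be positive")


def fit_scaler(X: np.ndarray) -> ScalerParams:
    """Estimate standardization parameters on a training feature matrix.

    Spread is the population standard deviation; features with zero spread
    (constants, e.g. the central SVV asparagine code) fall back to 1.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("cannot fit scaler on an empty set")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    return ScalerParams(mean, scale)


def apply_scaler(params: ScalerParams | None, X: np.ndarray) -> np.ndarray:
    """Standardize a feature matrix (or single vector) with fitted params."""
    if params is None:
        raise ValueError("scaler has not been fitted")
    X = np.asarray(X, dtype=float)
    return (X - params.mean) / params.scale


def write_feature_table(windows: Sequence[SiteWindow], path: str | Path) -> None:
    """Headered CSV: id, label, f000..f172, one row per window."""
    X, y = feature_matrix(windows)
    df = pd.DataFrame(X, columns=[f"f{i:03d}" for i in range(FEATURE_LENGTH)])
    df.insert(0, "label", y)
    df.insert(0, "id", [w.identifier for w in windows])
    df.to_csv(path, index=False)


def read_feature_table(path: str | Path
                       ) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Read a feature CSV back as (ids, X, y); label -1 means unknown."""
    df = pd.read_csv(path)
    ids = df["id"].astype(str).tolist()
    y = df["label"].to_numpy(dtype=np.int64)
    X = df[[c for c in df.columns if c.startswith("f")]].to_numpy(dtype=float)
    if X.shape[1] != FEATURE_LENGTH:
        raise ValueError(f"expected {FEATURE_LENGTH} features, got {X.shape[1]}")
    return ids, X, y
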