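"""Position- and composition-variant window descriptors.

Five extractors quantify where and how often each of the 20 standard
residues occurs in a window (padding code 0 is invisible to all of them,
but real residues keep their ordinal positions in the padded window so all
windows share one coordinate system):

PRIM
    20 x 20 position-relative incidence matrix.  Entry (i, j) is the sum of
    relative positions of every occurrence of residue j with respect to the
    *first* occurrence of residue i: sum_p (p - f_i) over 1-based positions
    p of j, with f_i the first position of i.  Occurrences of j before the
    first i contribute negatively.  Rows/columns of absent residues are 0.
RPRIM
    PRIM of the reversed window.
Frequency vector
    tau_i = occurrence count of residue i (composition only).
AAPIV
    mu_i = sum of the 1-based ordinal positions of residue i (accumulative
    absolute position incidence vector).
RAAPIV
    AAPIV of the reversed window.

On pad-free windows of length k the exact identity
mu_i + eta_i = (k + 1) * tau_i links the three vectors (a position p in the
forward window is position k + 1 - p in the reversed one).
"""

from __future__ import annotations

import numpy as np

from .peptide_windows import SiteWindow

N_RESIDUES = 20


def _codes(window: SiteWindow | np.ndarray) -> np.ndarray:
    if isinstance(window, SiteWindow):
        return window.codes
    return np.asarray(window, dtype=np.int64)


def prim(window: SiteWindow | np.ndarray) -> np.ndarray:
    """Forward position-relative incidence matrix (20 x 20)."""
    codes = _codes(window)
    if codes.size == 0:
        raise ValueError("empty window")
    A = np.zeros((N_RESIDUES, N_RESIDUES), dtype=float)
    positions = np.arange(1, codes.size + 1)
    present = codes > 0
    first = {}
    for p, c in zip(positions[present], codes[present]):
        if c not in first:
            first[c] = p
    for i_code, f in first.items():
        for p, j_code in zip(positions[present], codes[present]):
            A[i_code - 1, j_code - 1] += p - f
    return A


def rprim(window: SiteWindow | np.ndarray) -> np.ndarray:
    """Reverse PRIM: the PRIM of the reversed window."""
    return prim(_codes(window)[::-1])


def frequency_vector(window: SiteWindow | np.ndarray) -> np.ndarray:
    """Per-residue occurrence counts tau (padding excluded)."""
    codes = _codes(window)
    return np.bincount(codes, minlength=N_RESIDUES + 1)[1:].astype(float)


def aapiv(window: SiteWindow | np.ndarray) -> np.ndarray:
    """Accumulative absolute position incidence vector mu."""
    codes = _codes(window)
    mu = np.zeros(N_RESIDUES, dtype=float)
    for p, c in enumerate(codes, start=1):
        if c > 0:
            mu[c - 1] += p
    return mu


def raapiv(window: SiteWindow | np.ndarray) -> np.ndarray:
    """Reverse AAPIV: the AAPIV of the reversed window."""
    return aapiv(_codes(window)[::-1])
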