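"""Residue encoding and fixed-length site-vicinity windows.

Candidate N-linked glycosylation sites are asparagine (N) residues.  Around
each candidate the predictor looks at a fixed-length window of ``2r + 1``
residues (default ``r = 20``, i.e. 41-mers) called the site vicinity vector:
the candidate plus twenty flanking residues on each side.  Residues are
substituted by integer codes so the window becomes a numeric vector; any
unique, consistent assignment carries the same information, and here the
twenty standard amino acids are coded 1..20 in alphabetical one-letter order
with 0 reserved for padding and non-standard letters.

Windows that run past either terminus of the protein are zero-padded so every
window shares one coordinate system.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

#: The twenty standard amino acids, alphabetical by one-letter code.
#: Position in this string + 1 is the residue's integer code.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Padding / non-standard residue code.
PAD_CODE = 0

#: Default flank width r; windows have length 2r + 1 = 41.
DEFAULT_FLANK = 20

_CODE_OF = {aa: i + 1 for i, aa in enumerate(AMINO_ACIDS)}

ASPARAGINE_CODE = _CODE_OF["N"]  # 12


class InvalidSiteError(ValueError):
    """Raised when a window is requested at a position outside the protein."""


class WindowTableError(ValueError):
    """Raised when a window-table row is malformed; carries the line number."""


def encode_residue(letter: str) -> int:
    """Integer code of a single residue letter.

    Case-insensitive.  Standard residues map to 1..20 (A=1 ... Y=20);
    every other letter (X, B, Z, U, O, J, gaps) maps to 0.  This is lossy
    for non-standard letters, by design, so real database sequences parse.
    """
    if len(letter) != 1:
        raise ValueError(f"expected a single character, got {letter!r}")
    return _CODE_OF.get(letter.upper(), PAD_CODE)


def decode_residue(code: int) -> str:
    """Inverse of :func:`encode_residue` on codes 1..20; 0 decodes to ``'-'``."""
    if code == PAD_CODE:
        return "-"
    if not 1 <= code <= 20:
        raise ValueError(f"residue code out of range: {code}")
    return AMINO_ACIDS[code - 1]


def encode_sequence(sequence: str) -> np.ndarray:
    """Encode a residue string into an integer code array."""
    return np.array([encode_residue(c) for c in sequence], dtype=np.int64)


@dataclass(frozen=True)
class ProteinRecord:
    """A protein primary sequence with its identifier."""

    identifier: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.identifier!r}")
        object.__setattr__(self, "sequence", self.sequence.upper())


@dataclass(frozen=True)
class SiteWindow:
    """A fixed-length integer-encoded window centered on a candidate site.

    ``codes`` has length ``2r + 1``; the central element is the candidate
    residue.  ``label`` is 1 (glycosylated), 0 (not), or None (unknown).
    """

    codes: np.ndarray
    site_position: int = 0
    label: int | None = None
    identifier: str = ""

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=np.int64)
        if codes.ndim != 1 or len(codes) % 2 == 0:
            raise ValueError("window must be a 1-D odd-length code vector")
        if codes.min() < 0 or codes.max() > 20:
            raise ValueError("residue codes must lie in 0..20")
        if self.label not in (0, 1, None):
            raise ValueError(f"label must be 0, 1 or None, got {self.label!r}")
        object.__setattr__(self, "codes", codes)

    @property
    def radius(self) -> int:
        return len(self.codes) // 2

    @property
    def center_code(self) -> int:
        return int(self.codes[self.radius])

    def window_string(self) -> str:
        """Residue letters of the window; padding rendered as ``'-'``."""
        return "".join(decode_residue(int(c)) for c in self.codes)

    def reversed(self) -> "SiteWindow":
        return SiteWindow(self.codes[::-1].copy(), self.site_position,
                          self.label, self.identifier)


def window_from_string(
    window: str, label: int | None = None, identifier: str = "",
    site_position: int = 0,
) -> SiteWindow:
    """Build a :class:`SiteWindow` from a residue string ('-' = padding)."""
    return SiteWindow(encode_sequence(window), site_position, label, identifier)


def enumerate_candidate_sites(protein: ProteinRecord) -> list[int]:
    """1-based positions of every asparagine in the sequence, ascending."""
    return [i + 1 for i, c in enumerate(protein.sequence) if c == "N"]


def extract_window(protein: ProteinRecord, site: int,
                   r: int = DEFAULT_FLANK) -> SiteWindow:
    """Extract the ``2r + 1``-residue window centered on a 1-based site.

    Positions falling outside the sequence are zero-padded, so terminal
    sites yield windows of the same length as interior ones.
    """
    n = len(protein.sequence)
    if not 1 <= site <= n:
        raise InvalidSiteError(
            f"site {site} outside sequence of length {n} ({protein.identifier})")
    codes = np.zeros(2 * r + 1, dtype=np.int64)
    lo = max(site - 1 - r, 0)
    hi = min(site + r, n)
    segment = encode_sequence(protein.sequence[lo:hi])
    codes[lo - (site - 1 - r): lo - (site - 1 - r) + len(segment)] = segment
    return SiteWindow(codes, site_position=site, identifier=protein.identifier)


def windows_from_protein(protein: ProteinRecord,
                         r: int = DEFAULT_FLANK) -> list[SiteWindow]:
    """One window per candidate (asparagine) site in the protein."""
    return [extract_window(protein, s, r)
            for s in enumerate_candidate_sites(protein)]


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record FASTA file into :class:`ProteinRecord` objects."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinRecord(rec.id, str(rec.seq)))
    return records


_TABLE_HEADER = "id\twindow\tlabel"


def write_window_table(windows: Iterable[SiteWindow], path: str | Path) -> None:
    """Write windows to the TSV window-table format (id, window, label).

    Unknown labels are written as ``?``.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_TABLE_HEADER + "\n")
        for w in windows:
            lab = "?" if w.label is None else str(w.label)
            fh.write(f"{w.identifier}\t{w.window_string()}\t{lab}\n")


def read_window_table(path: str | Path,
                      expected_length: int = 2 * DEFAULT_FLANK + 1
                      ) -> list[SiteWindow]:
    """Read the TSV window-table format written by :func:`write_window_table`.

    Raises :class:`WindowTableError` naming the offending line on a bad row.
    """
    windows: list[SiteWindow] = []
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if header != _TABLE_HEADER:
            raise WindowTableError(
                f"line 1: expected header {_TABLE_HEADER!r}, got {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise WindowTableError(f"line {lineno}: expected 3 columns")
            ident, window, lab = parts
            if len(window) != expected_length:
                raise WindowTableError(
                    f"line {lineno}: window length {len(window)} != "
                    f"{expected_length}")
            if lab == "1":
                label: int | None = 1
            elif lab == "0":
                label = 0
            elif lab == "?":
                label = None
            else:
                raise WindowTableError(
                    f"line {lineno}: label must be 0, 1 or ?, got {lab!r}")
            windows.append(window_from_string(window, label, ident))
    return windows
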