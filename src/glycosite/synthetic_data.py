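"""Seeded generator of labeled 41-mer candidate-site windows.

Real N-linked glycosylation occurs on asparagine almost exclusively within
the N-X-[S/T] sequon (X any residue except proline).  The generator emulates
exactly that structure: every window carries N at the central position
(position 21 of 41); positive windows carry S or T two residues downstream
(center + 2) with high probability and suppress proline at center + 1, while
negative windows carry the sequon only rarely.  All other positions are
drawn from a background distribution (uniform over the 20 standard residues
by default).

The class signal is therefore controlled by the gap between
``sequon_prob_pos`` and ``sequon_prob_neg``: at 0.95 / 0.05 the classes are
well separated; with equal probabilities they are exchangeable and no
classifier can beat chance.  The generator does not emulate real flanking
composition biases, homology structure, or annotation noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .peptide_windows import (ASPARAGINE_CODE, DEFAULT_FLANK, SiteWindow,
                              encode_residue)

_ST_CODES = (encode_residue("S"), encode_residue("T"))
_PROLINE_CODE = encode_residue("P")


def _uniform_background() -> np.ndarray:
    return np.full(20, 1.0 / 20.0)


@dataclass
class SimConfig:
    """Study conditions for the synthetic benchmark."""

    n_pos: int = 200
    n_neg: int = 200
    sequon_prob_pos: float = 0.95
    sequon_prob_neg: float = 0.05
    background: np.ndarray = field(default_factory=_uniform_background)
    flank: int = DEFAULT_FLANK
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("counts must be non-negative")
        for p in (self.sequon_prob_pos, self.sequon_prob_neg):
            if not 0.0 <= p <= 1.0:
                raise ValueError("sequon probabilities must lie in [0, 1]")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (20,) or bg.min() < 0 or not np.isclose(bg.sum(), 1.0):
            raise ValueError("background must be a 20-residue distribution")
        self.background = bg / bg.sum()


def _draw_background(rng: np.random.Generator, cfg: SimConfig, size: int,
                     exclude: tuple[int, ...] = ()) -> np.ndarray:
    """Residue codes 1..20 from the background, optionally renormalized
    to exclude some residues."""
    probs = cfg.background.copy()
    for code in exclude:
        probs[code - 1] = 0.0
    probs /= probs.sum()
    return rng.choice(np.arange(1, 21), size=size, p=probs)


def generate_window(cfg: SimConfig, label: int,
                    rng: np.random.Generator) -> SiteWindow:
    """One labeled window: N at the center, sequon by label probability."""
    if label not in (0, 1):
        raise ValueError("label must be 0 or 1")
    r = cfg.flank
    codes = _draw_background(rng, cfg, 2 * r + 1)
    codes[r] = ASPARAGINE_CODE
    p_sequon = cfg.sequon_prob_pos if label == 1 else cfg.sequon_prob_neg
    if rng.random() < p_sequon:
        codes[r + 2] = _ST_CODES[rng.integers(2)]
    else:
        codes[r + 2] = _draw_background(rng, cfg, 1, exclude=_ST_CODES)[0]
    if label == 1 and codes[r + 1] == _PROLINE_CODE:
        # proline directly after the asparagine blocks glycosylation
        codes[r + 1] = _draw_background(rng, cfg, 1,
                                        exclude=(_PROLINE_CODE,))[0]
    return SiteWindow(codes, site_position=r + 1, label=label)


def generate_dataset(cfg: SimConfig) -> list[SiteWindow]:
    """n_pos positive + n_neg negative windows, reproducibly shuffled."""
    rng = np.random.default_rng(cfg.seed)
    windows = [generate_window(cfg, 1, rng) for _ in range(cfg.n_pos)]
    windows += [generate_window(cfg, 0, rng) for _ in range(cfg.n_neg)]
    order = rng.permutation(len(windows))
    shuffled = []
    for rank, i in enumerate(order):
        w = windows[i]
        shuffled.append(SiteWindow(w.codes, w.site_position, w.label,
                                   identifier=f"sim{rank:05d}"))
    return shuffled
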