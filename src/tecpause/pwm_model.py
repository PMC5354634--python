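"""Position weight matrices around pause sites, mono- and dinucleotide.

Sequences flanking each pause are aligned at the pause position, symbol
frequencies are tallied per offset (position frequency matrix), and weights
are the natural log of frequency over the background symbol frequency in the
considered genes.  Scoring a position sums the weights over all offsets.
The dinucleotide alphabet uses the 16 overlapping dinucleotides starting at
each offset, which lets the matrix express nearest-neighbor (stacking)
preferences the mononucleotide matrix cannot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import ConcatenatedTranscriptome
from .pause_calling import PauseSet

_MONO = ["A", "C", "G", "T"]
_DI = [a + b for a in _MONO for b in _MONO]

DEFAULT_OFFSETS = (-10, 5)


@dataclass
class PWMModel:
    """Log-ratio weights, shape (n_offsets, n_symbols)."""

    alphabet: str  # 'mono' or 'di'
    offsets: tuple[int, int]  # inclusive range
    weights: np.ndarray
    background: np.ndarray

    @property
    def symbols(self) -> list[str]:
        return _MONO if self.alphabet == "mono" else _DI

    @property
    def offset_values(self) -> np.ndarray:
        return np.arange(self.offsets[0], self.offsets[1] + 1)

    def max_score(self) -> float:
        return float(np.sum(np.max(self.weights, axis=1)))


def _positions_to_array(pauses) -> np.ndarray:
    if isinstance(pauses, PauseSet):
        return pauses.positions
    return np.asarray(pauses, dtype=np.int64)


def _symbol_track(transcriptome: ConcatenatedTranscriptome, alphabet: str) -> np.ndarray:
    """Per-position symbol code; -1 where undefined (N, or gene-crossing dinucleotide).

    For 'di' the symbol at position p is the dinucleotide (p, p+1); it is
    undefined at the last base of each gene.
    """
    codes = transcriptome.codes.astype(np.int64)
    if alphabet == "mono":
        return np.where(codes < 4, codes, -1)
    if alphabet != "di":
        raise ValueError(f"alphabet must be 'mono' or 'di', got {alphabet!r}")
    n = len(codes)
    out = np.full(n, -1, dtype=np.int64)
    if n >= 2:
        a, b = codes[:-1], codes[1:]
        ok = (a < 4) & (b < 4)
        out[:-1] = np.where(ok, 4 * a + b, -1)
    out[transcriptome.boundaries[1:] - 1] = -1  # last base of each gene
    return out


def _window_matrix(sym: np.ndarray, gene_id: np.ndarray, sites: np.ndarray,
                   offsets: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Symbol codes in each site's window; boolean mask of fully-valid sites.

    A site is usable only when every offset stays inside the site's gene and
    carries a defined symbol.
    """
    lo, hi = offsets
    offs = np.arange(lo, hi + 1)
    idx = sites[:, None] + offs[None, :]
    n = len(sym)
    inside = (idx >= 0) & (idx < n)
    idx_c = np.clip(idx, 0, n - 1)
    win = np.where(inside, sym[idx_c], -1)
    same_gene = inside & (gene_id[idx_c] == gene_id[np.clip(sites, 0, n - 1)][:, None])
    usable = np.all((win >= 0) & same_gene, axis=1)
    return win, usable


def build_pfm(pauses, transcriptome: ConcatenatedTranscriptome,
              offsets: tuple[int, int] = DEFAULT_OFFSETS,
              alphabet: str = "mono") -> tuple[np.ndarray, int]:
    """Position frequency matrix: counts of each symbol at each offset.

    Returns (counts of shape (n_offsets, n_symbols), number of usable pauses).
    Pauses whose window leaves the gene or touches an N are dropped.
    """
    sites = _positions_to_array(pauses)
    if len(sites) == 0:
        raise ValueError("no pause sites provided")
    sym = _symbol_track(transcriptome, alphabet)
    win, usable = _window_matrix(sym, transcriptome.gene_id, sites, offsets)
    n_used = int(np.sum(usable))
    if n_used == 0:
        raise ValueError("no pause site has a fully valid flanking window")
    win = win[usable]
    n_sym = 4 if alphabet == "mono" else 16
    n_off = offsets[1] - offsets[0] + 1
    counts = np.zeros((n_off, n_sym), dtype=np.int64)
    for j in range(n_off):
        counts[j] = np.bincount(win[:, j], minlength=n_sym)
    return counts, n_used


def background_frequencies(transcriptome: ConcatenatedTranscriptome,
                           alphabet: str = "mono",
                           gene_mask: np.ndarray | None = None) -> np.ndarray:
    """Symbol frequencies over the considered genes (optionally a gene subset)."""
    sym = _symbol_track(transcriptome, alphabet)
    if gene_mask is not None:
        keep = gene_mask[transcriptome.gene_id]
        sym = sym[keep]
    sym = sym[sym >= 0]
    n_sym = 4 if alphabet == "mono" else 16
    freq = np.bincount(sym, minlength=n_sym).astype(float)
    return freq / freq.sum()


def pfm_to_pwm(pfm_counts: np.ndarray, background: np.ndarray,
               offsets: tuple[int, int] = DEFAULT_OFFSETS,
               alphabet: str = "mono", pseudocount: float = 1.0) -> PWMModel:
    """Log-ratio transform: weight = ln(freq / background).

    A pseudocount is added to every cell before normalizing so unseen symbols
    get a finite (strongly negative) weight rather than -inf.
    """
    background = np.asarray(background, dtype=float)
    counts = np.asarray(pfm_counts, dtype=float) + pseudocount
    freq = counts / counts.sum(axis=1, keepdims=True)
    if np.any((background <= 0) & (freq > 0)):
        raise ValueError("background frequency of 0 for an observed symbol")
    with np.errstate(divide="ignore"):  # pseudocount=0 may leave true zeros
        weights = np.log(freq / background)
    return PWMModel(alphabet=alphabet, offsets=offsets, weights=weights,
                    background=background)


def build_pwm(pauses, transcriptome: ConcatenatedTranscriptome,
              offsets: tuple[int, int] = DEFAULT_OFFSETS, alphabet: str = "mono",
              pseudocount: float = 1.0,
              gene_mask: np.ndarray | None = None) -> PWMModel:
    """Convenience: PFM + background + log transform in one call."""
    pfm, _ = build_pfm(pauses, transcriptome, offsets, alphabet)
    bg = background_frequencies(transcriptome, alphabet, gene_mask)
    return pfm_to_pwm(pfm, bg, offsets, alphabet, pseudocount)


def score_positions(pwm: PWMModel, transcriptome: ConcatenatedTranscriptome) -> np.ndarray:
    """Sum of PWM weights over the window at every position; NaN where invalid."""
    sym = _symbol_track(transcriptome, pwm.alphabet)
    n = len(sym)
    lo, hi = pwm.offsets
    gene_id = transcriptome.gene_id
    scores = np.zeros(n)
    bad = np.zeros(n, dtype=bool)
    for j, off in enumerate(range(lo, hi + 1)):
        idx = np.arange(n) + off
        inside = (idx >= 0) & (idx < n)
        idx_c = np.clip(idx, 0, n - 1)
        s = sym[idx_c]
        ok = inside & (s >= 0) & (gene_id[idx_c] == gene_id)
        bad |= ~ok
        scores += np.where(ok, pwm.weights[j, np.clip(s, 0, None)], 0.0)
    scores[bad] = np.nan
    return scores
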