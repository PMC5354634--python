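"""Nucleosome-distance benchmark: pause probability vs distance to nearest dyad.

The score of a position is the empirical pause probability at its signed
distance (in transcription direction) to the nearest mapped nucleosome
center, fitted at single-base resolution up to ``max_dist`` (500 bp).
Positions farther than that get the mean pause probability, so they are
uninformative rather than penalized.  A 61-bp running average is provided
for display only; scoring uses the raw per-distance probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import ConcatenatedTranscriptome
from .pause_calling import PauseSet

DEFAULT_MAX_DIST = 500


@dataclass
class NucleosomeDistanceScore:
    """Pause probability lookup over signed distances -max_dist..max_dist."""

    max_dist: int
    lookup: np.ndarray  # length 2*max_dist+1; NaN where the distance was never seen
    fallback: float  # mean pause probability over scored positions

    def score(self, distances: np.ndarray) -> np.ndarray:
        """Scores for signed distances (may be +/-inf for chromosome without centers)."""
        d = np.asarray(distances, dtype=float)
        out = np.full(d.shape, self.fallback)
        finite = np.isfinite(d) & (np.abs(d) <= self.max_dist)
        idx = (d[finite].astype(np.int64)) + self.max_dist
        vals = self.lookup[idx]
        out[finite] = np.where(np.isnan(vals), self.fallback, vals)
        return out


def distance_to_nearest(position: int, centers: np.ndarray, strand: str = "+") -> float:
    """Signed distance from one genomic position to its nearest center.

    Positive = the position lies downstream of the nucleosome in transcription
    direction; ties between two equidistant centers break toward the
    downstream center (the one yielding a negative signed distance).
    Returns +inf when the chromosome has no centers.
    """
    centers = np.asarray(centers)
    if len(centers) == 0:
        return float("inf")
    j = np.searchsorted(centers, position)
    best = None
    for k in (j - 1, j):
        if 0 <= k < len(centers):
            d_gen = position - int(centers[k])
            d = d_gen if strand == "+" else -d_gen
            if best is None or abs(d) < abs(best) or (abs(d) == abs(best) and d < best):
                best = d
    return float(best)


def signed_distances(transcriptome: ConcatenatedTranscriptome,
                     centers: dict[str, np.ndarray]) -> np.ndarray:
    """Signed transcription-direction distance to nearest center, per position."""
    n = len(transcriptome)
    out = np.full(n, np.inf)
    for g, gene in enumerate(transcriptome.genes):
        cs = centers.get(gene.chrom)
        lo, hi = int(transcriptome.boundaries[g]), int(transcriptome.boundaries[g + 1])
        if cs is None or len(cs) == 0:
            continue
        if gene.strand == "+":
            gpos = np.arange(gene.start, gene.end)
        else:
            gpos = np.arange(gene.end - 1, gene.start - 1, -1)
        j = np.searchsorted(cs, gpos)
        left = np.clip(j - 1, 0, len(cs) - 1)
        right = np.clip(j, 0, len(cs) - 1)
        d_left = gpos - cs[left]
        d_right = gpos - cs[right]
        d_left[j - 1 < 0] = np.iinfo(np.int64).max // 2
        d_right[j >= len(cs)] = np.iinfo(np.int64).max // 2
        if gene.strand == "-":
            d_left, d_right = -d_left, -d_right
        pick_left = np.abs(d_left) < np.abs(d_right)
        tie = np.abs(d_left) == np.abs(d_right)
        d = np.where(pick_left, d_left, d_right)
        # tie: choose the downstream center = more negative signed distance
        d = np.where(tie, np.minimum(d_left, d_right), d)
        out[lo:hi] = d
    return out


def fit_pause_probability_by_distance(pauses, centers: dict[str, np.ndarray],
                                      transcriptome: ConcatenatedTranscriptome,
                                      max_dist: int = DEFAULT_MAX_DIST,
                                      position_mask: np.ndarray | None = None
                                      ) -> tuple[NucleosomeDistanceScore, np.ndarray]:
    """Fit the per-distance pause probability lookup; returns (model, distances).

    ``position_mask`` optionally restricts the scored positions (e.g. to
    expression-filtered genes); the fallback equals the mean pause fraction
    over the scored positions.
    """
    positions = pauses.positions if isinstance(pauses, PauseSet) else np.asarray(pauses)
    n = len(transcriptome)
    is_pause = np.zeros(n, dtype=bool)
    is_pause[positions] = True
    dists = signed_distances(transcriptome, centers)
    mask = np.ones(n, dtype=bool) if position_mask is None else np.asarray(position_mask, bool)
    if not np.any(mask):
        raise ValueError("no positions to score")
    in_range = mask & np.isfinite(dists) & (np.abs(dists) <= max_dist)
    if not np.any(in_range):
        raise ValueError(f"no position within {max_dist} bp of a nucleosome center")
    idx = dists[in_range].astype(np.int64) + max_dist
    totals = np.bincount(idx, minlength=2 * max_dist + 1).astype(float)
    pause_counts = np.bincount(idx[is_pause[in_range]], minlength=2 * max_dist + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        lookup = pause_counts / totals
    lookup[totals == 0] = np.nan
    fallback = float(np.mean(is_pause[mask]))
    return NucleosomeDistanceScore(max_dist=max_dist, lookup=lookup, fallback=fallback), dists


def smooth_profile(values: np.ndarray, width: int = 61) -> np.ndarray:
    """Centered running mean with end truncation (display smoothing only)."""
    if width < 1 or width % 2 == 0:
        raise ValueError(f"width must be odd and >= 1, got {width}")
    x = np.asarray(values, dtype=float)
    n = len(x)
    h = width // 2
    good = ~np.isnan(x)
    c1 = np.concatenate([[0.0], np.cumsum(np.where(good, x, 0.0))])
    cn = np.concatenate([[0], np.cumsum(good.astype(np.int64))])
    i = np.arange(n)
    lo = np.maximum(i - h, 0)
    hi = np.minimum(i + h + 1, n)
    m = cn[hi] - cn[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (c1[hi] - c1[lo]) / m
    out[m == 0] = np.nan
    return out
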