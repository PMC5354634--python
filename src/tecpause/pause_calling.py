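"""Pause calling: local-outlier detection on 3'-end coverage.

A position is a pause when its read count strictly exceeds the local mean by
``nsd`` local standard deviations, computed over a centered window of
``width`` positions (default 201 bp, 4 SD).  Windows are truncated at gene
boundaries by default so a window never mixes counts from two genes; the
``cross_gene_boundaries`` switch restores plain windows over the raw
concatenated track.  The focal position is included in its own window and the
population (1/n) standard deviation is used; both choices are recorded in the
resulting :class:`PauseSet`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import ConcatenatedTranscriptome, CoverageTrack


@dataclass
class PauseSet:
    """Called pause positions (sorted, concatenated coordinates) plus parameters."""

    positions: np.ndarray
    nsd: float
    width: int
    strain: str = "other"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("pause positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.positions)


def _segment_stats(counts: np.ndarray, width: int) -> tuple[np.ndarray, np.ndarray]:
    """Truncated centered-window mean/SD for one contiguous segment, O(n)."""
    n = len(counts)
    h = width // 2
    x = counts.astype(np.float64)
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])
    i = np.arange(n)
    lo = np.maximum(i - h, 0)
    hi = np.minimum(i + h + 1, n)
    m = hi - lo
    s1 = c1[hi] - c1[lo]
    s2 = c2[hi] - c2[lo]
    mean = s1 / m
    var = s2 / m - mean * mean
    np.maximum(var, 0.0, out=var)  # clamp fp negatives
    return mean, np.sqrt(var)


def local_stats(track: CoverageTrack, transcriptome: ConcatenatedTranscriptome | None,
                width: int = 201, cross_gene_boundaries: bool = False
                ) -> tuple[np.ndarray, np.ndarray]:
    """Per-position local mean and population SD of counts.

    ``width`` must be odd so the window is centered; windows are truncated at
    segment ends.  With ``cross_gene_boundaries=True`` (or no transcriptome)
    the whole concatenated track is one segment.
    """
    if width < 3 or width % 2 == 0:
        raise ValueError(f"width must be odd and >= 3, got {width}")
    counts = np.asarray(track.counts)
    if cross_gene_boundaries or transcriptome is None:
        return _segment_stats(counts, width)
    n = len(counts)
    mean = np.empty(n)
    sd = np.empty(n)
    bounds = transcriptome.boundaries
    for g in range(transcriptome.n_genes):
        lo, hi = int(bounds[g]), int(bounds[g + 1])
        mean[lo:hi], sd[lo:hi] = _segment_stats(counts[lo:hi], width)
    return mean, sd


def call_pauses(track: CoverageTrack, transcriptome: ConcatenatedTranscriptome | None = None,
                nsd: float = 4.0, width: int = 201,
                cross_gene_boundaries: bool = False) -> PauseSet:
    """Call positions whose count strictly exceeds local mean + nsd * local SD.

    Windows with SD = 0 (locally constant coverage) never yield a call:
    strictness of the inequality makes count > mean impossible there.
    """
    if nsd <= 0:
        raise ValueError("nsd must be positive")
    mean, sd = local_stats(track, transcriptome, width, cross_gene_boundaries)
    counts = np.asarray(track.counts)
    called = counts > mean + nsd * sd
    return PauseSet(
        positions=np.flatnonzero(called),
        nsd=nsd,
        width=width,
        strain=track.strain,
        meta={
            "focal_in_window": True,
            "population_sd": True,
            "cross_gene_boundaries": bool(cross_gene_boundaries),
        },
    )


def pause_zscores(track: CoverageTrack, transcriptome: ConcatenatedTranscriptome | None = None,
                  width: int = 201, cross_gene_boundaries: bool = False) -> np.ndarray:
    """(count - local mean) / local SD; inf-free: SD = 0 positions get NaN."""
    mean, sd = local_stats(track, transcriptome, width, cross_gene_boundaries)
    counts = np.asarray(track.counts, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (counts - mean) / sd
    z[sd == 0] = np.nan
    return z
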