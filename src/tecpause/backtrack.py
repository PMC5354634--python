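"""Backtrack classification from paired dst1-delta and WT pause sets.

In a TFIIS-deletion (dst1-delta) strain the sequenced 3' end marks where RNA
polymerase first paused; in WT, cleavage of the backtracked transcript moves
the observed 3' end upstream by the backtrack depth.  Each dst1-delta pause
is therefore classified by the offset to the nearest WT pause upstream of it
(same gene, transcript coordinates): offset 0-1 = no/short backtrack,
2-15 = long backtrack, no WT pause within 0-15 = excluded from the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ConcatenatedTranscriptome
from .pause_calling import PauseSet

SHORT_MAX = 1
LONG_MAX = 15


@dataclass(frozen=True)
class BacktrackCall:
    dst1_position: int
    wt_offset: int | None  # bases upstream to the nearest WT pause, or None
    klass: str  # 'short' | 'long' | 'excluded'


def classify_backtracks(dst1_pauses, wt_pauses,
                        transcriptome: ConcatenatedTranscriptome | None = None
                        ) -> list[BacktrackCall]:
    """Classify every dst1-delta pause by its nearest upstream WT pause.

    The nearest (smallest-offset) WT pause within 0..15 bases upstream wins;
    the search never crosses gene boundaries.  The three classes partition
    the input exactly.
    """
    dst1 = dst1_pauses.positions if isinstance(dst1_pauses, PauseSet) else np.asarray(dst1_pauses, dtype=np.int64)
    wt = wt_pauses.positions if isinstance(wt_pauses, PauseSet) else np.asarray(wt_pauses, dtype=np.int64)
    wt = np.sort(wt)
    calls: list[BacktrackCall] = []
    for p in dst1:
        p = int(p)
        j = np.searchsorted(wt, p, side="right") - 1  # nearest WT pause <= p
        offset: int | None = None
        if j >= 0:
            cand = int(wt[j])
            off = p - cand
            same_gene = True
            if transcriptome is not None:
                same_gene = transcriptome.gene_of(p) == transcriptome.gene_of(cand)
            if off <= LONG_MAX and same_gene:
                offset = off
        if offset is None:
            calls.append(BacktrackCall(p, None, "excluded"))
        elif offset <= SHORT_MAX:
            calls.append(BacktrackCall(p, offset, "short"))
        else:
            calls.append(BacktrackCall(p, offset, "long"))
    return calls


def calls_to_frame(calls: list[BacktrackCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "dst1_position": [c.dst1_position for c in calls],
            "wt_offset": [c.wt_offset for c in calls],
            "class": [c.klass for c in calls],
        }
    )


def class_fractions(calls: list[BacktrackCall]) -> dict[str, float]:
    """Fraction of total dst1-delta pauses per class (sums to 1)."""
    n = len(calls)
    if n == 0:
        return {"short": float("nan"), "long": float("nan"), "excluded": float("nan")}
    out = {}
    for k in ("short", "long", "excluded"):
        out[k] = sum(c.klass == k for c in calls) / n
    return out


def long_fraction_by_dtec(calls: list[BacktrackCall], dtec: np.ndarray,
                          bin_width: float = 1.0) -> pd.DataFrame:
    """Fraction of long backtracks among short+long, binned by dTEC.

    Excluded calls and calls without a valid dTEC are dropped; empty bins are
    omitted.  Columns: bin_center, n, n_long, frac_long.
    """
    pos = np.array([c.dst1_position for c in calls if c.klass != "excluded"], dtype=np.int64)
    is_long = np.array([c.klass == "long" for c in calls if c.klass != "excluded"], dtype=bool)
    if len(pos) == 0:
        return pd.DataFrame(columns=["bin_center", "n", "n_long", "frac_long"])
    x = np.asarray(dtec, dtype=float)[pos]
    ok = np.isfinite(x)
    x, is_long = x[ok], is_long[ok]
    bins = np.floor(x / bin_width).astype(np.int64)
    rows = []
    for b in np.unique(bins):
        sel = bins == b
        rows.append(
            {
                "bin_center": (b + 0.5) * bin_width,
                "n": int(np.sum(sel)),
                "n_long": int(np.sum(is_long[sel])),
                "frac_long": float(np.mean(is_long[sel])),
            }
        )
    return pd.DataFrame(rows)
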