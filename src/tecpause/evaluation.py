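"""Predictor evaluation: ROC/AUC, pause-odds curves, metagene profiles, nulls.

The AUC is computed from an explicit ROC over the unique score thresholds,
which makes it exactly the Mann-Whitney U statistic normalized by
``n_pos * n_neg`` with half credit for ties.  Logistic fits of pause (or
long-backtrack) probability on dTEC are maximum-likelihood, per-site and
unbinned; binned pause-fraction curves are for display and linearity checks.
Metagene profiles around sites come with a pointwise-extremes resampling
band: with 1000 resamples of site sets of equal size, escaping the band at
an offset corresponds to p < 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io_formats import ConcatenatedTranscriptome, CoverageTrack


# ---------------------------------------------------------------------------
# ROC / AUC

@dataclass
class ROCResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """ROC over unique thresholds and its trapezoidal area.

    Tied scores collapse onto a single threshold, so the area equals the
    pairwise probability P(score_pos > score_neg) + 0.5 P(tie).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same shape")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative label")
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    y = labels[order]
    # cut after the last element of each tied block
    distinct = np.flatnonzero(np.diff(s) != 0)
    cuts = np.concatenate([distinct, [len(s) - 1]])
    tp = np.cumsum(y)[cuts]
    fp = np.cumsum(~y)[cuts]
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    thresholds = np.concatenate([[np.inf], s[cuts]])
    return ROCResult(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


# ---------------------------------------------------------------------------
# Pause fraction and log-odds vs score

def pause_fraction_by_score(scores: np.ndarray, labels: np.ndarray,
                            bin_width: float = 1.0) -> pd.DataFrame:
    """Per-bin pause fraction (and odds where defined) as a function of score.

    Non-finite scores are dropped; empty bins are omitted; odds = f/(1-f) is
    NaN for pure bins (f of exactly 0 or 1).
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    ok = np.isfinite(x)
    x, y = x[ok], y[ok]
    bins = np.floor(x / bin_width).astype(np.int64)
    rows = []
    for b in np.unique(bins):
        sel = bins == b
        n = int(sel.sum())
        f = float(np.mean(y[sel]))
        rows.append(
            {
                "bin_center": (b + 0.5) * bin_width,
                "n": n,
                "n_pause": int(np.sum(y[sel])),
                "frac": f,
                "odds": f / (1.0 - f) if 0.0 < f < 1.0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class OddsFit:
    """Logistic fit log-odds(label) = alpha + beta * score."""

    alpha: float
    beta: float
    alpha_se: float
    beta_se: float
    converged: bool
    n: int

    def odds(self, score: np.ndarray) -> np.ndarray:
        return np.exp(self.alpha + self.beta * np.asarray(score, dtype=float))

    def beta_ci(self, z: float = 1.96) -> tuple[float, float]:
        return self.beta - z * self.beta_se, self.beta + z * self.beta_se


def fit_log_odds(scores: np.ndarray, labels: np.ndarray) -> OddsFit:
    """Maximum-likelihood logistic regression of labels on a single score."""
    x = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(float)
    ok = np.isfinite(x)
    x, y = x[ok], y[ok]
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need both classes present to fit log-odds")
    X = sm.add_constant(x)
    res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    if not res.mle_retvals.get("converged", False):
        raise RuntimeError(f"logistic fit did not converge: {res.mle_retvals}")
    return OddsFit(
        alpha=float(res.params[0]),
        beta=float(res.params[1]),
        alpha_se=float(res.bse[0]),
        beta_se=float(res.bse[1]),
        converged=True,
        n=len(y),
    )


# ---------------------------------------------------------------------------
# Metagene profiles and resampling null band

def _gather_windows(values: np.ndarray, sites: np.ndarray, halfwidth: int
                    ) -> tuple[np.ndarray, np.ndarray]:
    """(n_sites, 2h+1) window matrix and mask of sites with fully finite flanks."""
    n = len(values)
    offs = np.arange(-halfwidth, halfwidth + 1)
    idx = np.asarray(sites, dtype=np.int64)[:, None] + offs[None, :]
    inside = (idx >= 0) & (idx < n)
    win = np.where(inside, values[np.clip(idx, 0, n - 1)], np.nan)
    usable = np.all(np.isfinite(win), axis=1)
    return win, usable


def average_profile(values: np.ndarray, sites: np.ndarray, halfwidth: int = 30) -> np.ndarray:
    """Mean of ``values`` at offsets -halfwidth..halfwidth across usable sites."""
    values = np.asarray(values, dtype=float)
    win, usable = _gather_windows(values, np.asarray(sites), halfwidth)
    if not np.any(usable):
        raise ValueError("no site has a fully valid flanking window")
    return win[usable].mean(axis=0)


def usable_profile_sites(values: np.ndarray, sites: np.ndarray, halfwidth: int = 30) -> np.ndarray:
    """Subset of sites whose whole window is finite (the ones the profile used)."""
    _, usable = _gather_windows(np.asarray(values, float), np.asarray(sites), halfwidth)
    return np.asarray(sites)[usable]


def running_sum(profile: np.ndarray, width: int = 8) -> np.ndarray:
    """Centered sliding-window sum; ends without a full window are NaN.

    For even width the window at index j spans j - width//2 .. j + width//2 - 1,
    matching an 8-base hybrid centered just 5' of the focal offset.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    x = np.asarray(profile, dtype=float)
    n = len(x)
    out = np.full(n, np.nan)
    lo_off = -(width // 2)
    hi_off = lo_off + width  # exclusive
    for j in range(n):
        lo, hi = j + lo_off, j + hi_off
        if lo < 0 or hi > n:
            continue
        out[j] = np.sum(x[lo:hi])
    return out


@dataclass
class ProfileWithNull:
    offsets: np.ndarray
    observed: np.ndarray
    lo: np.ndarray  # pointwise minimum over resampled profiles
    hi: np.ndarray  # pointwise maximum
    n_sites: int
    n_resamples: int


def null_band(values: np.ndarray, observed_sites: np.ndarray,
              candidate_sites: np.ndarray, halfwidth: int = 30,
              n_resamples: int = 1000, seed: int | np.random.Generator = 0
              ) -> ProfileWithNull:
    """Observed metagene profile with a pointwise-extremes resampling band.

    Each resample draws ``n_sites`` positions (without replacement) from the
    candidate set — all valid positions of the considered genes — and the
    band is the pointwise min/max over ``n_resamples`` resampled profiles,
    i.e. the p < 1/(n_resamples) envelope on each side.
    """
    values = np.asarray(values, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed_sites = usable_profile_sites(values, observed_sites, halfwidth)
    n_sites = len(observed_sites)
    if n_sites == 0:
        raise ValueError("no usable observed sites")
    candidates = usable_profile_sites(values, candidate_sites, halfwidth)
    if n_sites > len(candidates):
        raise ValueError(f"cannot resample {n_sites} sites from {len(candidates)} candidates")
    observed = average_profile(values, observed_sites, halfwidth)
    width = 2 * halfwidth + 1
    lo = np.full(width, np.inf)
    hi = np.full(width, -np.inf)
    for _ in range(n_resamples):
        pick = rng.choice(candidates, size=n_sites, replace=False)
        prof = average_profile(values, pick, halfwidth)
        np.minimum(lo, prof, out=lo)
        np.maximum(hi, prof, out=hi)
    return ProfileWithNull(
        offsets=np.arange(-halfwidth, halfwidth + 1),
        observed=observed,
        lo=lo,
        hi=hi,
        n_sites=n_sites,
        n_resamples=n_resamples,
    )


# ---------------------------------------------------------------------------
# Expression filtering

def expression_filter(track: CoverageTrack, transcriptome: ConcatenatedTranscriptome
                      ) -> np.ndarray:
    """Boolean per-gene mask of genes with above-average read density.

    Density = total counts / gene length; the threshold is the unweighted mean
    density across genes, with a strict inequality (so a perfectly uniform
    dataset retains nothing).
    """
    counts = np.asarray(track.counts, dtype=float)
    bounds = transcriptome.boundaries
    totals = np.add.reduceat(counts, bounds[:-1])
    lengths = np.diff(bounds)
    density = totals / lengths
    return density > density.mean()


def gene_position_mask(transcriptome: ConcatenatedTranscriptome,
                       gene_mask: np.ndarray) -> np.ndarray:
    """Expand a per-gene mask to a per-position mask."""
    return np.asarray(gene_mask, dtype=bool)[transcriptome.gene_id]
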