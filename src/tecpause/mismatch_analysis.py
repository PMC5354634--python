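"""Thermodynamic discrimination against transcriptional errors.

A wrong ribonucleotide at the penultimate 3' position destabilizes the
RNA:DNA hybrid, raising dTEC in the forward-translocation (dst1) convention
and therefore raising both the odds of pausing and, given a pause, the odds
of a long backtrack.  With logistic fits odds = exp(alpha + beta * dTEC),
the per-site effect of an error is the odds ratio exp(beta * (dTEC_mm -
dTEC)) — independent of alpha — and the combined pause-then-long-backtrack
effect is the per-site product of the two ratios.

How to summarize per-site odds ratios into a single fold is a genuine
choice; the report carries the mean and median of the per-site ratios and
the ratio of mean odds, so all common summaries are available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .energy_model import EnergyProfile, NNEnergyTable, mismatch_delta_tec_track
from .evaluation import OddsFit
from .io_formats import ConcatenatedTranscriptome


def mismatch_dtec_distribution(transcriptome: ConcatenatedTranscriptome,
                               profile: EnergyProfile,
                               mismatch_table: NNEnergyTable,
                               mode: str = "dst1",
                               position_mask: np.ndarray | None = None) -> pd.DataFrame:
    """Paired (dTEC, dTEC_mm) for every site valid in the pausing analysis.

    ``position_mask`` restricts sites to those the pausing analysis used
    (e.g. expression-filtered genes).  Only sites where both values are
    defined are returned.  Coverage caveat: the bundled mismatch set covers
    one error identity per template base (rA.dA, rC.dC, rG.dG, rU.dT), not
    the full 12-mismatch spectrum.
    """
    base, adjusted = mismatch_delta_tec_track(transcriptome, profile, mismatch_table, mode)
    ok = np.isfinite(base) & np.isfinite(adjusted)
    if position_mask is not None:
        ok &= np.asarray(position_mask, dtype=bool)
    sites = np.flatnonzero(ok)
    return pd.DataFrame({"site": sites, "dtec": base[sites], "dtec_mm": adjusted[sites]})


@dataclass
class MismatchReport:
    n_sites: int
    mean_shift: float  # mean dTEC_mm - dTEC, kJ/mol
    pause_fold_mean: float
    pause_fold_median: float
    pause_fold_odds_ratio: float  # ratio of mean odds
    backtrack_fold_mean: float
    backtrack_fold_median: float
    backtrack_fold_odds_ratio: float
    combined_fold_mean: float  # mean of per-site pause x backtrack products
    combined_fold_median: float

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def predicted_fold_changes(pairs: pd.DataFrame, pause_fit: OddsFit,
                           backtrack_fit: OddsFit) -> MismatchReport:
    """Predicted fold changes in pausing and long backtracking from an error.

    Per site: pause odds ratio exp(beta_pause * shift), long-backtrack odds
    ratio exp(beta_bt * shift), combined = their product (pause then long
    backtrack, composed per site before averaging).  All ratios depend only
    on the fitted slopes, never on the intercepts.
    """
    if pause_fit is None or backtrack_fit is None:
        raise ValueError("both a pause fit and a backtrack fit are required")
    shift = (pairs["dtec_mm"] - pairs["dtec"]).to_numpy()
    if len(shift) == 0:
        raise ValueError("no paired sites provided")
    pause_or = np.exp(pause_fit.beta * shift)
    bt_or = np.exp(backtrack_fit.beta * shift)

    def odds_ratio_of_means(fit: OddsFit) -> float:
        o_mm = np.exp(fit.beta * (pairs["dtec_mm"].to_numpy()))
        o = np.exp(fit.beta * (pairs["dtec"].to_numpy()))
        return float(np.mean(o_mm) / np.mean(o))

    return MismatchReport(
        n_sites=len(shift),
        mean_shift=float(np.mean(shift)),
        pause_fold_mean=float(np.mean(pause_or)),
        pause_fold_median=float(np.median(pause_or)),
        pause_fold_odds_ratio=odds_ratio_of_means(pause_fit),
        backtrack_fold_mean=float(np.mean(bt_or)),
        backtrack_fold_median=float(np.median(bt_or)),
        backtrack_fold_odds_ratio=odds_ratio_of_means(backtrack_fit),
        combined_fold_mean=float(np.mean(pause_or * bt_or)),
        combined_fold_median=float(np.median(pause_or * bt_or)),
    )
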