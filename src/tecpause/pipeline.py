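"""End-to-end orchestration: pauses -> predictors -> ROC table -> backtracks -> errors.

``full_run`` reproduces the figure-level analyses on one dataset (real files
or a seeded synthetic dataset): pause calling for both strains, energy and
dTEC profiles, PWM / nucleosome / energy predictor scores and their ROC
comparison, metagene dTEC profile with a resampling null band, backtrack
classification and the long-backtrack curve, and the mismatch fold-change
report.  Every artifact is a TSV (plus an optional PNG per figure analog)
under the output directory, and a JSON manifest records parameters, seed and
package version so a run can be repeated bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, backtrack, evaluation, io_formats, mismatch_analysis
from .energy_model import build_energy_profile, build_energy_table, delta_tec_track
from .nucleosome_model import fit_pause_probability_by_distance
from .pause_calling import call_pauses
from .pwm_model import build_pwm, score_positions
from .synthetic_data import SyntheticSpec, generate_dataset

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs and parameters of a full run; defaults are the study conventions."""

    # real-data inputs (all None -> synthetic mode)
    genome: str | None = None
    genes: str | None = None
    wt_plus: str | None = None
    wt_minus: str | None = None
    dst1_plus: str | None = None
    dst1_minus: str | None = None
    nucleosomes: str | None = None
    # parameters
    seed: int = 0
    nsd: float = 4.0
    width: int = 201
    temperature: float = 303.0
    pwm_offsets: tuple[int, int] = (-10, 5)
    bin_width: float = 1.0  # kJ/mol, for fraction/odds curves
    max_nuc_dist: int = 500
    halfwidth: int = 30
    n_resamples: int = 1000
    expression_filter: bool = True
    plots: bool = False
    outdir: str = "tecpause_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        if "pwm_offsets" in raw:
            raw["pwm_offsets"] = tuple(raw["pwm_offsets"])
        return cls(**raw)

    def validate(self) -> None:
        real = [self.genome, self.genes, self.wt_plus, self.wt_minus,
                self.dst1_plus, self.dst1_minus, self.nucleosomes]
        if any(v is not None for v in real) and any(v is None for v in real):
            raise ValueError("real-data mode needs all of genome/genes/tracks/nucleosomes")
        if self.nsd <= 0 or self.width % 2 == 0:
            raise ValueError("nsd must be > 0 and width odd")


@dataclass
class RunResult:
    auc_table: pd.DataFrame
    backtrack_fractions: dict[str, float]
    pause_fit: evaluation.OddsFit
    backtrack_fit: evaluation.OddsFit | None
    mismatch: mismatch_analysis.MismatchReport | None
    n_pauses: dict[str, int]
    outdir: Path
    manifest: dict = field(default_factory=dict)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def _load_real(config: RunConfig):
    genome = io_formats.read_fasta(config.genome)
    genes = io_formats.read_bed_genes(config.genes)
    tx = io_formats.build_concatenated_transcriptome(genome, genes)

    def track(plus, minus, strain):
        t = io_formats.read_bedgraph(plus, tx, "+", strain)
        t2 = io_formats.read_bedgraph(minus, tx, "-", strain)
        return io_formats.CoverageTrack(counts=t.counts + t2.counts, strain=strain)

    wt = track(config.wt_plus, config.wt_minus, "WT")
    dst1 = track(config.dst1_plus, config.dst1_minus, "dst1")
    nucs = io_formats.read_nucleosome_table(config.nucleosomes)
    profile = build_energy_profile(tx, temperature=config.temperature)
    return tx, profile, wt, dst1, nucs


def full_run(config: RunConfig, synthetic_spec: SyntheticSpec | None = None) -> RunResult:
    """Run every analysis stage and write all artifacts under ``config.outdir``."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    if config.genome is not None:
        tx, profile, wt, dst1, nucs = _stage("load_inputs")(_load_real)(config)
        truth = None
    else:
        spec = synthetic_spec or SyntheticSpec(seed=config.seed,
                                               temperature=config.temperature)
        ds = _stage("simulate")(generate_dataset)(spec)
        tx, profile, wt, dst1, nucs = ds.transcriptome, ds.profile, ds.wt, ds.dst1, ds.nucleosomes
        truth = ds.truth

    dtec = _stage("energy_profile")(delta_tec_track)(profile, "dst1")

    pauses = {}
    for strain, track in (("WT", wt), ("dst1", dst1)):
        pauses[strain] = _stage(f"call_pauses_{strain}")(call_pauses)(
            track, tx, nsd=config.nsd, width=config.width)
        logger.info("%s: %d pauses called", strain, len(pauses[strain]))

    # expression filter applies to predictor evaluation, per the Methods
    if config.expression_filter:
        gene_mask = evaluation.expression_filter(dst1, tx)
        if not np.any(gene_mask):
            gene_mask = np.ones(tx.n_genes, dtype=bool)
    else:
        gene_mask = np.ones(tx.n_genes, dtype=bool)
    pos_mask = evaluation.gene_position_mask(tx, gene_mask)

    labels = np.zeros(len(tx), dtype=bool)
    labels[pauses["dst1"].positions] = True

    scores = {}
    scores["energy"] = dtec
    for alphabet in ("mono", "di"):
        pwm = _stage(f"pwm_{alphabet}")(build_pwm)(
            pauses["dst1"], tx, offsets=config.pwm_offsets,
            alphabet=alphabet, gene_mask=gene_mask)
        scores[f"{alphabet}_pwm"] = score_positions(pwm, tx)
    nuc_model, _dists = _stage("nucleosome_model")(fit_pause_probability_by_distance)(
        pauses["dst1"], nucs, tx, max_dist=config.max_nuc_dist, position_mask=pos_mask)
    from .nucleosome_model import signed_distances
    scores["nucleosome"] = nuc_model.score(signed_distances(tx, nucs))

    rows = []
    roc_curves = {}
    for name in ("di_pwm", "mono_pwm", "energy", "nucleosome"):
        s = scores[name]
        ok = pos_mask & np.isfinite(s)
        roc = _stage(f"roc_{name}")(evaluation.roc_auc)(s[ok], labels[ok])
        roc_curves[name] = roc
        rows.append({"model": name, "auc": roc.auc, "n": int(ok.sum()),
                     "n_pos": int(labels[ok].sum())})
    auc_table = pd.DataFrame(rows)
    auc_table.to_csv(out / "auc_table.tsv", sep="\t", index=False)

    # pause fraction / odds vs dTEC and the per-site logistic fit
    ok = pos_mask & np.isfinite(dtec)
    curve = evaluation.pause_fraction_by_score(dtec[ok], labels[ok], config.bin_width)
    curve.to_csv(out / "pause_fraction_vs_dtec.tsv", sep="\t", index=False)
    pause_fit = _stage("pause_fit")(evaluation.fit_log_odds)(dtec[ok], labels[ok])

    # metagene dTEC profile around dst1 pauses with resampling null band
    candidates = np.flatnonzero(pos_mask & np.isfinite(dtec))
    band = _stage("null_band")(evaluation.null_band)(
        dtec, pauses["dst1"].positions, candidates, halfwidth=config.halfwidth,
        n_resamples=config.n_resamples, seed=rng)
    pd.DataFrame({"offset": band.offsets, "observed": band.observed,
                  "null_lo": band.lo, "null_hi": band.hi}).to_csv(
        out / "dtec_profile_null_band.tsv", sep="\t", index=False)

    # backtracks
    calls = _stage("backtrack")(backtrack.classify_backtracks)(
        pauses["dst1"], pauses["WT"], tx)
    backtrack.calls_to_frame(calls).to_csv(out / "backtrack_calls.tsv", sep="\t", index=False)
    fractions = backtrack.class_fractions(calls)
    bt_curve = backtrack.long_fraction_by_dtec(calls, dtec, config.bin_width)
    bt_curve.to_csv(out / "long_backtrack_vs_dtec.tsv", sep="\t", index=False)

    backtrack_fit = None
    mismatch_report = None
    informative = [c for c in calls if c.klass != "excluded" and np.isfinite(dtec[c.dst1_position])]
    kls = np.array([c.klass == "long" for c in informative])
    if len(informative) >= 10 and 0 < kls.sum() < len(kls):
        xs = dtec[[c.dst1_position for c in informative]]
        backtrack_fit = _stage("backtrack_fit")(evaluation.fit_log_odds)(xs, kls)
        mm_table = build_energy_table("RNA:DNA-mismatch", config.temperature)
        pairs = _stage("mismatch_dtec")(mismatch_analysis.mismatch_dtec_distribution)(
            tx, profile, mm_table, "dst1", pos_mask)
        mismatch_report = _stage("mismatch_folds")(mismatch_analysis.predicted_fold_changes)(
            pairs, pause_fit, backtrack_fit)
        pd.DataFrame([mismatch_report.as_dict()]).to_csv(
            out / "mismatch_report.tsv", sep="\t", index=False)

    if config.plots:
        _stage("plots")(_write_plots)(out, roc_curves, curve, band, bt_curve)

    manifest = {
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "mode": "real" if config.genome else "synthetic",
        "n_pauses": {k: int(len(v)) for k, v in pauses.items()},
        "n_genes_retained": int(gene_mask.sum()),
        "backtrack_fractions": fractions,
        "pause_fit": {"alpha": pause_fit.alpha, "beta": pause_fit.beta},
        "truth_n_pauses": None if truth is None else int(len(truth.pauses)),
    }
    if backtrack_fit is not None:
        manifest["backtrack_fit"] = {"alpha": backtrack_fit.alpha, "beta": backtrack_fit.beta}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    return RunResult(
        auc_table=auc_table,
        backtrack_fractions=fractions,
        pause_fit=pause_fit,
        backtrack_fit=backtrack_fit,
        mismatch=mismatch_report,
        n_pauses={k: len(v) for k, v in pauses.items()},
        outdir=out,
        manifest=manifest,
    )


def _write_plots(out: Path, roc_curves, frac_curve, band, bt_curve) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    ax = axes[0, 0]
    for name, roc in roc_curves.items():
        ax.plot(roc.fpr, roc.tpr, label=f"{name} (AUC {roc.auc:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.5)
    ax.set(xlabel="false positive rate", ylabel="true positive rate", title="Pause prediction")
    ax.legend(fontsize=7)

    ax = axes[0, 1]
    ax.plot(frac_curve["bin_center"], frac_curve["frac"], "o-")
    ax.set(xlabel="dTEC (kJ/mol)", ylabel="fraction of sites with a pause")

    ax = axes[1, 0]
    ax.plot(band.offsets, band.observed, label="pause sites")
    ax.fill_between(band.offsets, band.lo, band.hi, alpha=0.3, color="gray",
                    label="p<0.001 null band")
    ax.set(xlabel="offset from pause (nt)", ylabel="mean dTEC (kJ/mol)")
    ax.legend(fontsize=7)

    ax = axes[1, 1]
    if len(bt_curve):
        ax.plot(bt_curve["bin_center"], bt_curve["frac_long"], "o-")
    ax.set(xlabel="dTEC (kJ/mol)", ylabel="fraction long backtracks")

    fig.tight_layout()
    fig.savefig(out / "figures.png", dpi=150)
    plt.close(fig)
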