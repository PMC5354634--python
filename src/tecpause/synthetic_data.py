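"""Synthetic NET-seq datasets with planted, recoverable structure.

The generator emulates the four inputs of the real-data pipeline — genome
FASTA, gene BED, strand-specific 3'-end bedGraph tracks for WT and a
TFIIS-deletion (dst1-delta) strain, and a nucleosome-center table — with the
statistical structure the analysis assumes:

* i.i.d. genome at a fixed GC content, genes tiled with gaps on both strands;
* per-gene expression rates lognormal, background counts Poisson;
* initial (dst1-delta) pauses Bernoulli per position with
  P(pause) = logistic(alpha + beta * dTEC_dst1), so pause odds are
  log-linear in the planted thermodynamic signal;
* each pause classified long/short by a second logistic in dTEC, and its WT
  partner pause planted 2-15 (long) or 0-1 (short) bases upstream;
* pause positions carry Poisson(rate * enrichment) extra counts;
* nucleosome centers at normal(165, 15) spacings, independent of pausing —
  deliberately uninformative, so the nucleosome benchmark should score ~0.5.

Everything is driven by one seeded Generator: a fixed seed reproduces the
dataset exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats
from .energy_model import EnergyProfile, build_energy_profile, delta_tec_track
from .io_formats import ConcatenatedTranscriptome, CoverageTrack, GeneInterval


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic dataset (defaults are the study conditions)."""

    seed: int = 0
    n_genes: int = 100
    gene_length_range: tuple[int, int] = (1500, 3500)
    intergenic_gap: int = 300
    n_chromosomes: int = 2
    gc_content: float = 0.40
    # expression: lognormal per-gene rate, background Poisson(rate * depth)
    expression_mu: float = 0.0
    expression_sigma: float = 0.75
    depth: float = 1.0
    # pause model: P(pause at i) = logistic(alpha + beta * dTEC_dst1(i))
    alpha: float = -4.0
    beta: float = 0.5  # per kJ/mol
    enrichment: float = 30.0
    # backtrack model: P(long | pause) = logistic(alpha_b + beta_b * dTEC_dst1)
    alpha_b: float = -0.6
    beta_b: float = 0.3
    long_offsets: tuple[int, int] = (2, 15)
    short_offsets: tuple[int, int] = (0, 1)
    # nucleosomes: successive spacings ~ normal(spacing_mean, spacing_sd)
    nucleosome_spacing_mean: float = 165.0
    nucleosome_spacing_sd: float = 15.0
    temperature: float = 303.0

    def __post_init__(self):
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")


@dataclass
class TruthTables:
    """Planted ground truth for parameter-recovery tests."""

    pauses: pd.DataFrame  # position, gene, dtec, is_long, offset, wt_position
    gene_rates: np.ndarray
    nucleosomes: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class Dataset:
    spec: SyntheticSpec
    genome: dict[str, str]
    genes: list[GeneInterval]
    transcriptome: ConcatenatedTranscriptome
    profile: EnergyProfile
    dtec_dst1: np.ndarray
    wt: CoverageTrack
    dst1: CoverageTrack
    nucleosomes: dict[str, np.ndarray]
    truth: TruthTables


def _random_sequence(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=probs)])


def generate_genome(spec: SyntheticSpec, rng: np.random.Generator
                    ) -> tuple[dict[str, str], list[GeneInterval]]:
    """Random genome with genes tiled along chromosomes, strands alternating."""
    lo, hi = spec.gene_length_range
    if lo >= hi or lo < 1:
        raise ValueError("infeasible gene length range")
    lengths = rng.integers(lo, hi, size=spec.n_genes)
    per_chrom = max(1, -(-spec.n_genes // spec.n_chromosomes))  # ceil
    genome: dict[str, str] = {}
    genes: list[GeneInterval] = []
    g = 0
    for c in range(spec.n_chromosomes):
        chrom = f"chr{'I' * (c + 1)}"
        pos = spec.intergenic_gap
        spans = []
        while g < spec.n_genes and len(spans) < per_chrom:
            length = int(lengths[g])
            strand = "+" if g % 2 == 0 else "-"
            spans.append((pos, pos + length, strand, f"gene{g:04d}"))
            pos += length + spec.intergenic_gap
            g += 1
        chrom_len = pos
        genome[chrom] = _random_sequence(rng, chrom_len, spec.gc_content)
        for start, end, strand, name in spans:
            genes.append(GeneInterval(chrom, start, end, strand, name))
    return genome, genes


def simulate_nucleosomes(spec: SyntheticSpec, genome: dict[str, str],
                         rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Nucleosome centers at cumulative normal-spaced positions per chromosome."""
    centers: dict[str, np.ndarray] = {}
    for chrom, seq in genome.items():
        out = []
        pos = float(rng.uniform(0, spec.nucleosome_spacing_mean))
        while pos < len(seq):
            out.append(int(pos))
            step = rng.normal(spec.nucleosome_spacing_mean, spec.nucleosome_spacing_sd)
            pos += max(step, 1.0)
        centers[chrom] = np.unique(np.asarray(out, dtype=np.int64))
    return centers


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def simulate_netseq(spec: SyntheticSpec, transcriptome: ConcatenatedTranscriptome,
                    dtec_dst1: np.ndarray, rng: np.random.Generator
                    ) -> tuple[CoverageTrack, CoverageTrack, TruthTables]:
    """Simulate WT and dst1-delta coverage with planted pauses and backtracks.

    Counts are background Poisson(rate * depth) everywhere, plus
    Poisson(rate * depth * enrichment) extra reads at each planted pause
    position (dst1-delta) and at its upstream WT partner position (WT).
    Positions without a defined dTEC never receive a planted pause.
    """
    n = len(transcriptome)
    rates = np.exp(rng.normal(spec.expression_mu, spec.expression_sigma,
                              size=transcriptome.n_genes))
    pos_rate = rates[transcriptome.gene_id] * spec.depth

    logit = spec.alpha + spec.beta * np.where(np.isfinite(dtec_dst1), dtec_dst1, 0.0)
    p_pause = _sigmoid(logit)
    p_pause[~np.isfinite(dtec_dst1)] = 0.0
    is_pause = rng.random(n) < p_pause
    pause_pos = np.flatnonzero(is_pause)

    # class and WT partner offset per pause
    p_long = _sigmoid(spec.alpha_b + spec.beta_b * dtec_dst1[pause_pos])
    is_long = rng.random(len(pause_pos)) < p_long
    offsets = np.empty(len(pause_pos), dtype=np.int64)
    gene_off = pause_pos - transcriptome.boundaries[transcriptome.gene_id[pause_pos]]
    for k, (p, long_, goff) in enumerate(zip(pause_pos, is_long, gene_off)):
        if long_:
            lo, hi = spec.long_offsets
            hi = min(hi, int(goff))
            if hi < lo:  # too close to the gene start for any long backtrack
                is_long[k] = False
                lo, hi = spec.short_offsets
                hi = min(hi, int(goff))
        else:
            lo, hi = spec.short_offsets
            hi = min(hi, int(goff))
        offsets[k] = rng.integers(lo, hi + 1)
    wt_pos = pause_pos - offsets

    dst1_counts = rng.poisson(pos_rate)
    dst1_counts[pause_pos] += rng.poisson(pos_rate[pause_pos] * spec.enrichment)
    wt_counts = rng.poisson(pos_rate)
    np.add.at(wt_counts, wt_pos, rng.poisson(pos_rate[wt_pos] * spec.enrichment))

    truth = TruthTables(
        pauses=pd.DataFrame(
            {
                "position": pause_pos,
                "gene": transcriptome.gene_id[pause_pos],
                "dtec": dtec_dst1[pause_pos],
                "is_long": is_long,
                "offset": offsets,
                "wt_position": wt_pos,
            }
        ),
        gene_rates=rates,
    )
    return (
        CoverageTrack(counts=wt_counts, strain="WT"),
        CoverageTrack(counts=dst1_counts, strain="dst1"),
        truth,
    )


def generate_dataset(spec: SyntheticSpec) -> Dataset:
    """Full synthetic dataset: genome, genes, tracks, nucleosomes, truth."""
    rng = np.random.default_rng(spec.seed)
    genome, genes = generate_genome(spec, rng)
    transcriptome = io_formats.build_concatenated_transcriptome(genome, genes)
    profile = build_energy_profile(transcriptome, temperature=spec.temperature)
    dtec = delta_tec_track(profile, "dst1")
    wt, dst1, truth = simulate_netseq(spec, transcriptome, dtec, rng)
    truth.nucleosomes = simulate_nucleosomes(spec, genome, rng)
    return Dataset(
        spec=spec,
        genome=genome,
        genes=genes,
        transcriptome=transcriptome,
        profile=profile,
        dtec_dst1=dtec,
        wt=wt,
        dst1=dst1,
        nucleosomes=truth.nucleosomes,
        truth=truth,
    )


def write_dataset(ds: Dataset, outdir) -> None:
    """Write the dataset in the formats the real-data pipeline reads."""
    out = Path(outdir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    io_formats.write_fasta(ds.genome, out / "genome.fa")
    io_formats.write_bed_genes(ds.genes, out / "genes.bed")
    for strain, track in (("wt", ds.wt), ("dst1", ds.dst1)):
        for strand, tag in (("+", "plus"), ("-", "minus")):
            io_formats.write_bedgraph(track, ds.transcriptome, strand,
                                      out / f"{strain}_{tag}.bedgraph")
    io_formats.write_nucleosome_table(ds.nucleosomes, out / "nucleosomes.tsv")
    ds.truth.pauses.to_csv(out / "truth" / "pauses.tsv", sep="\t", index=False)
    pd.DataFrame({"gene": range(len(ds.truth.gene_rates)),
                  "rate": ds.truth.gene_rates}).to_csv(
        out / "truth" / "gene_rates.tsv", sep="\t", index=False)
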