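# Methods

## Coordinate system

All analyses run on a single axis: the considered genes concatenated in
input order, each written 5′→3′ on its coding strand (minus-strand genes
reverse-complemented). Internal coordinates are 0-based half-open. bedGraph
input/output uses the standard 0-based half-open dialect; the nucleosome
table defaults to 1-based positions (configurable). Gene order is recorded
in run manifests so runs are reproducible. Concatenation-edge effects are
handled by making window computations gene-aware (below) rather than by
masking.

## Nearest-neighbor energies

Duplex melting free energy is a sum over dinucleotide stacks,
ΔG = ΔH − T·ΔS at a configurable temperature (default 303 K), stored as a
*positive* melting energy in kJ/mol (larger = more stable). Only stack
terms are summed: initiation, terminal-AT and salt corrections are omitted,
because every quantity the pipeline uses is a difference between equal-length
windows in which such constant terms cancel. Bundled parameter tables:

- `dna_dna_unified.tsv` — the unified DNA/DNA nearest-neighbor set
  (ΔH, ΔS per stack). Entries satisfy reverse-complement symmetry
  E(xy) = E(rc(xy)), which the tests verify for all 16 keys.
- `rna_dna_hybrid.tsv` — the RNA/DNA hybrid set, keyed by the coding-strand
  dinucleotide (the coding strand is the RNA strand; U written as T).
- `rna_dna_mismatch_synthetic.tsv` — a clearly-labelled **synthetic
  stand-in** for internal RNA:DNA mismatch stacks: matched hybrid stacks
  destabilized by an enthalpic per-stack penalty chosen per mismatch
  identity (rG·dG 0.5 < rU·dT 0.8 < rA·dA 1.2 < rC·dC 1.3 kcal/mol),
  matching the qualitative stability ordering of internal RNA/DNA
  mismatches. Quantitative error-discrimination numbers therefore
  illustrate the machinery, not measured thermodynamics; all exact tests
  of the mismatch code use closed forms or an identity table.

The per-position energy track assigns each stack to the more-3′ of its two
bases; the first base of every gene, and any stack touching an N, is
invalid (NaN), and invalidity propagates through every window that uses it,
so windows never silently cross gene joins.

## TEC stability and ΔTEC

TEC stability of an 8-base window is its RNA:DNA melting energy minus its
DNA:DNA melting energy. A window [a, b] sums the stacks at positions
a+1 .. b (7 stacks, fully internal): under this convention the two
shared-boundary windows of each mode cover consecutive, non-overlapping
stacks, and the window sum equals the substring duplex-energy difference
exactly (the oracle the tests use). An 8-stack alternative is available
via `stacks_per_window=8`.

ΔTEC compares registers one translocation step apart (hybrid length fixed
at 8 bp):

- `dst1` (initial pauses): ΔTEC(i) = TEC(i−10..i−3) − TEC(i−3..i+4);
- `wt` (backtracked pauses): ΔTEC(i) = TEC(i−7..i) − TEC(i−14..i−7).

Positive ΔTEC ⇒ the current register is thermodynamically favored ⇒
pause-prone. The vectorized track is a cumulative-sum implementation
verified position-by-position against the scalar brute force.

## Transcriptional mismatches

An error at the penultimate 3′ base (position i−1 relative to the 3′ end i)
replaces the RNA:DNA energies of the two stacks flanking i−1 (stacks i−1
and i) with mismatch-table values; both flanking stacks are adjusted (the
one-stack variant is a config switch away in the scalar API). The covered
error set is one mismatch per template base (rU·dT, rG·dG, rC·dC, rA·dA),
so sequence determines the mismatch identity. In `dst1` mode both affected
stacks lie in the subtracted prospective window, hence destabilization
raises ΔTEC; in `wt` mode both lie in the current window. Fold changes in
pausing/long backtracking are per-site odds ratios exp(β·ΔΔTEC) under the
fitted logistic models — independent of the intercepts — summarized as the
mean and median of per-site ratios plus the ratio of mean odds, since the
choice of summary is genuinely open.

## Pause calling

A pause is a position whose count strictly exceeds the local mean by
`nsd` (default 4) local standard deviations over a centered `width`
(default 201) window. Choices the data do not dictate, recorded in the
output metadata: the focal position is included in its own window;
population (1/n) SD; windows truncate at gene boundaries (a
`cross_gene_boundaries` switch restores plain concatenated-track windows).
Strict inequality means sd = 0 regions can never call. Calling is
scale-equivariant: multiplying counts by c > 0 leaves the called set
unchanged.

## Predictors and evaluation

*PWMs.* Symbol frequencies at offsets −10..+5 around pauses (window extent
a package default; it covers the hybrid and the downstream duplex), with a
pseudocount of 1 per cell, log-ratio against the background symbol
frequency of the considered genes (natural log; scores are comparative so
the base is immaterial). The dinucleotide alphabet uses the 16 overlapping
dinucleotides starting at each offset. Training and evaluation are
in-sample by default, matching the study design this package reproduces.

*Nucleosome benchmark.* Score = empirical pause probability at the signed
(transcription-direction) distance to the nearest nucleosome center,
fitted at 1-bp resolution up to 500 bp; beyond that, the mean pause
probability. Ties between equidistant centers break toward the downstream
center. The 61-bp running average exists for display only. Note an honest
limitation: evaluated in-sample, a 1001-bin empirical lookup partially
memorizes its positives, inflating AUC when positives are few (the
inflation is ~0.02 with ~35k positives over 2.5×10⁵ positions and grows as
positives shrink).

*ROC/AUC.* Explicit ROC over unique score thresholds with trapezoidal
area; ties collapse to one threshold, making the AUC exactly the
Mann–Whitney statistic with half credit for ties (tested to 10⁻¹², and
cross-checked against scikit-learn).

*Logistic fits.* Maximum-likelihood logistic regression (statsmodels) of
pause (or long-backtrack) labels on per-site unbinned ΔTEC. Binned
fraction/odds curves (1 kJ/mol bins) are for display and linearity checks
only.

*Null bands.* Metagene profiles around sites come with a pointwise-extremes
band over 1000 resamples of equal-size random site sets drawn from all
valid positions; escaping the band corresponds to p < 0.001 per offset.
Resampling is driven by an explicit seed and is byte-reproducible.

*Expression filter.* Genes with read density (total counts / length)
strictly above the unweighted mean density across genes; applied to
predictor evaluation.

## Backtrack classification

Each *dst1Δ* pause takes the nearest WT pause 0–15 nt upstream within the
same gene: offset 0–1 ⇒ short/no backtrack, 2–15 ⇒ long, none ⇒ excluded.
The three classes partition the pause set exactly. The long-fraction curve
bins non-excluded calls by ΔTEC (1 kJ/mol).

## Synthetic data generator

The generator emulates the four real inputs with the statistical structure
the analysis assumes. Defaults (the study conditions): 100 genes of
uniform(1500, 3500) bp on 2 chromosomes with 300-bp gaps and alternating
strands (~2.5×10⁵ transcribed positions); GC 0.40 (yeast-like);
per-gene rates lognormal(0, 0.75) at depth 1 (mean ~1 read/position,
NET-seq-like sparse coverage); pause occurrence Bernoulli with
P = logistic(−4 + 0.5·ΔTEC_dst1); pause positions get
Poisson(rate·30) extra reads; long-vs-short class
P(long) = logistic(−0.6 + 0.3·ΔTEC); WT partner offsets uniform on 2–15
(long) or {0, 1} (short), truncated at the gene start; nucleosome spacings
normal(165, 15) bp, independent of everything else. One seeded generator
drives all randomness; a fixed seed reproduces the dataset byte for byte.

What the defaults imply, and what passing tests do and do not show: with
the real ΔTEC spread (sd ≈ 6.8 kJ/mol) the planted pause density is ~14%
of positions — much denser than real NET-seq pausing. At that density the
local-SD threshold is dominated by neighboring planted spikes, so the
4σ caller recovers only the extreme tail of the planted set (~1.4%, at
perfect precision) regardless of sequencing depth (calling is
scale-equivariant). Parameter-recovery results on planted truth
(logistic slope to within a few percent at 5×10⁵ sites) therefore
demonstrate the estimation machinery, not caller sensitivity on sparse
real data. Likewise, nearest-partner backtrack matching is contaminated by
neighboring pauses' partners at this density, attenuating the fitted
long-backtrack slope below the planted 0.3 even though every unambiguous
case classifies correctly. The generator does not model clustered pausing,
RNA secondary structure, sequencing error, or read-level artifacts.

## Numerical choices and degenerate inputs

- Energies and ΔTEC propagate NaN for any window touching a gene start or
  an N; callers mask rather than raise.
- Local-stat windows clamp negative variances from floating-point
  cancellation to zero.
- Empty bins are omitted from binned curves; pure bins (fraction 0 or 1)
  are excluded from odds transforms.
- `pause_fraction_by_score` and the curve utilities drop non-finite scores
  with a tally rather than failing.
- Resampling without replacement; requesting more sites than candidates is
  an error.
- Uniform read density across genes retains no genes under the strict
  expression filter (logged, degenerate by construction).

## Problem sizes

Test and acceptance runs use the generator defaults (~2.5×10⁵ positions);
slope-recovery checks use 200 genes (~5×10⁵ positions) with a 5-seed
battery; null bands use 1000 resamples of up to 2000 sites. These sizes
were chosen so the complete suite exercises every stage at full fidelity
in well under a coffee break on one core.
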