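"""Nearest-neighbor duplex melting energies and TEC stability differences.

The stability proxy for the transcription elongation complex (TEC) at a
transcribed position is the melting free energy of the 8-bp RNA:DNA hybrid
inside RNA polymerase minus the melting free energy of the same sequence as
re-annealed DNA:DNA duplex.  Both are nearest-neighbor sums of dinucleotide
stack energies, dG = dH - T*dS evaluated at 303 K and stored as *positive*
melting energies in kJ/mol (larger = harder to melt = more stable).

The pausing predictor dTEC(i) compares the TEC stability of the hybrid in its
current register with the register one translocation step away:

* ``dst1`` mode (initial pauses, pre-backtrack): current hybrid = bases
  [i-10, i-3], prospective post-translocation hybrid = bases [i-3, i+4];
  dTEC = TEC(current) - TEC(prospective).
* ``wt`` mode (backtracked pauses): current hybrid = bases [i-7, i],
  backtracked hybrid = bases [i-14, i-7]; dTEC = TEC(current) - TEC(backtracked).

Positive dTEC means leaving the current register costs energy, i.e. the
position is thermodynamically pause-prone.

A window [a, b] of 8 bases contributes the stacks at positions a+1..b
(7 stacks, fully internal), so the two shared-boundary windows of each mode
cover consecutive, non-overlapping stacks.  An 8-stack convention (include
the stack ending at a) is available via ``stacks_per_window=8``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .io_formats import ConcatenatedTranscriptome

KCAL_TO_KJ = 4.184
DEFAULT_TEMPERATURE = 303.0  # kelvin

_BASES = "ACGT"
_DINUCS = [a + b for a in _BASES for b in _BASES]

#: coding-strand base at the error position -> covered mismatch identity
MISMATCH_IDENTITY = {"A": "rU.dT", "C": "rG.dG", "G": "rC.dC", "T": "rA.dA"}

_DATA_FILES = {
    "DNA:DNA": "dna_dna_unified.tsv",
    "RNA:DNA": "rna_dna_hybrid.tsv",
    "RNA:DNA-mismatch": "rna_dna_mismatch_synthetic.tsv",
}


@dataclass
class NNEnergyTable:
    """Dinucleotide -> melting free energy (kJ/mol) at a fixed temperature.

    ``entries`` is keyed by the coding-strand dinucleotide (5'->3').  For the
    mismatch kind, ``mismatch_entries`` is keyed by ``(dinucleotide, side)``
    where ``side`` marks which base of the stack carries the transcriptional
    error ('5p' or '3p').
    """

    kind: str
    temperature: float
    entries: dict[str, float] = field(default_factory=dict)
    mismatch_entries: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive kelvin")

    def energy(self, dinuc: str) -> float:
        try:
            return self.entries[dinuc]
        except KeyError:
            raise KeyError(f"no nearest-neighbor entry for stack {dinuc!r}") from None

    def mismatch_energy(self, dinuc: str, side: str) -> float:
        try:
            return self.mismatch_entries[(dinuc, side)]
        except KeyError:
            raise KeyError(f"no mismatch entry for stack {dinuc!r} (side {side})") from None

    def as_array(self) -> np.ndarray:
        """Entries as a length-16 array indexed by 4*code(x) + code(y)."""
        arr = np.full(16, np.nan)
        for k, v in self.entries.items():
            arr[4 * _BASES.index(k[0]) + _BASES.index(k[1])] = v
        return arr


def _read_param_tsv(name: str) -> list[list[str]]:
    rows = []
    with resources.files("tecpause.data").joinpath(name).open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("stack\t"):
                continue
            rows.append(line.split("\t"))
    return rows


def build_energy_table(kind: str, temperature: float = DEFAULT_TEMPERATURE) -> NNEnergyTable:
    """Build an :class:`NNEnergyTable` from the bundled dH/dS parameter files.

    The stored value is the positive melting free energy
    ``-(dH - T*dS)`` converted from kcal/mol to kJ/mol.  dG of duplex
    formation is negative for every stack at physiological temperatures, so
    entries come out positive; they are linear in T by construction.
    """
    if kind not in _DATA_FILES:
        raise ValueError(f"unknown table kind {kind!r}; expected one of {sorted(_DATA_FILES)}")
    table = NNEnergyTable(kind=kind, temperature=temperature)
    rows = _read_param_tsv(_DATA_FILES[kind])
    if kind == "RNA:DNA-mismatch":
        for stack, side, dh, ds in rows:
            dg_kcal = float(dh) - temperature * float(ds) / 1000.0
            table.mismatch_entries[(stack, side)] = -dg_kcal * KCAL_TO_KJ
        missing = [(d, s) for d in _DINUCS for s in ("5p", "3p")
                   if (d, s) not in table.mismatch_entries]
    else:
        for stack, dh, ds in rows:
            dg_kcal = float(dh) - temperature * float(ds) / 1000.0
            table.entries[stack] = -dg_kcal * KCAL_TO_KJ
        missing = [d for d in _DINUCS if d not in table.entries]
    if missing:
        raise ValueError(f"{kind} parameter file is missing entries: {missing}")
    return table


def duplex_melting_energy(seq: str, table: NNEnergyTable) -> float:
    """Melting energy (kJ/mol) of ``seq`` as a sum over consecutive stacks.

    Only stack terms are summed (no initiation or terminal corrections);
    a length-1 sequence has no stacks and melts for free.
    """
    seq = seq.upper()
    for i, c in enumerate(seq):
        if c not in _BASES:
            raise ValueError(f"invalid base {c!r} at position {i}")
    return float(sum(table.energy(seq[i : i + 2]) for i in range(len(seq) - 1)))


# ---------------------------------------------------------------------------
# Per-position tracks

def per_position_energies(transcriptome: ConcatenatedTranscriptome,
                          table: NNEnergyTable) -> np.ndarray:
    """Stack energy assigned to the more-3' base of each dinucleotide.

    ``e[i]`` is the energy of the stack formed by bases i-1 and i.  NaN where
    the stack is undefined: the first base of each gene (no same-gene 5'
    neighbor) and anywhere either base is N.
    """
    codes = transcriptome.codes
    n = len(codes)
    e = np.full(n, np.nan)
    if n < 2:
        return e
    lut = table.as_array()
    prev, cur = codes[:-1], codes[1:]
    ok = (prev < 4) & (cur < 4)
    idx = np.where(ok, 4 * prev.astype(np.int64) + cur.astype(np.int64), 0)
    vals = np.where(ok, lut[idx], np.nan)
    e[1:] = vals
    # first base of every gene has no upstream neighbor within the gene
    e[transcriptome.boundaries[:-1]] = np.nan
    # stacks spanning a gene junction are already killed by the line above
    return e


@dataclass
class EnergyProfile:
    """Per-position RNA:DNA and DNA:DNA stack energies and their difference."""

    e_rna: np.ndarray
    e_dna: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE
    stacks_per_window: int = 7

    def __post_init__(self):
        if self.stacks_per_window not in (7, 8):
            raise ValueError("stacks_per_window must be 7 (internal stacks) or 8")
        if len(self.e_rna) != len(self.e_dna):
            raise ValueError("RNA and DNA energy tracks differ in length")

    def __len__(self) -> int:
        return len(self.e_rna)

    @property
    def d(self) -> np.ndarray:
        """Per-stack RNA:DNA minus DNA:DNA melting energy, kJ/mol."""
        return self.e_rna - self.e_dna

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.e_rna) & ~np.isnan(self.e_dna)


def build_energy_profile(transcriptome: ConcatenatedTranscriptome,
                         temperature: float = DEFAULT_TEMPERATURE,
                         stacks_per_window: int = 7) -> EnergyProfile:
    rna = build_energy_table("RNA:DNA", temperature)
    dna = build_energy_table("DNA:DNA", temperature)
    return EnergyProfile(
        e_rna=per_position_energies(transcriptome, rna),
        e_dna=per_position_energies(transcriptome, dna),
        temperature=temperature,
        stacks_per_window=stacks_per_window,
    )


def _window_stack_sum(values: np.ndarray, a: int, b: int, stacks_per_window: int) -> float:
    """Sum of stack values for the 8-base window [a, b] inclusive."""
    lo = a + 1 if stacks_per_window == 7 else a
    if lo < 0 or b >= len(values):
        return float("nan")
    return float(np.sum(values[lo : b + 1]))


def tec_stability(window: tuple[int, int], profile: EnergyProfile) -> float:
    """TEC stability of the hybrid occupying bases [a, b] (inclusive), kJ/mol.

    Equals RNA:DNA melting energy minus DNA:DNA melting energy of the window
    substring; NaN if any required stack is invalid.
    """
    a, b = window
    return _window_stack_sum(profile.d, a, b, profile.stacks_per_window)


#: hybrid length assumed constant throughout
HYBRID_LENGTH = 8

#: inclusive base windows (current, other-register) relative to position i
TEC_WINDOWS = {
    "dst1": ((-10, -3), (-3, 4)),  # current vs prospective (downstream) register
    "wt": ((-7, 0), (-14, -7)),  # current vs backtracked (upstream) register
}


def delta_tec(i: int, mode: str, profile: EnergyProfile) -> float:
    """TEC stability difference at a single position (kJ/mol)."""
    if mode not in TEC_WINDOWS:
        raise ValueError(f"mode must be 'dst1' or 'wt', got {mode!r}")
    (ca, cb), (oa, ob) = TEC_WINDOWS[mode]
    cur = tec_stability((i + ca, i + cb), profile)
    other = tec_stability((i + oa, i + ob), profile)
    return cur - other


def delta_tec_track(profile: EnergyProfile, mode: str) -> np.ndarray:
    """Vectorized dTEC for every position; NaN where any window stack is invalid.

    Implemented with cumulative sums over the d track; gene boundaries and N
    positions propagate through the NaN at their stacks, so windows never
    silently cross genes.
    """
    if mode not in TEC_WINDOWS:
        raise ValueError(f"mode must be 'dst1' or 'wt', got {mode!r}")
    d = profile.d
    n = len(d)
    filled = np.where(np.isnan(d), 0.0, d)
    bad = np.isnan(d).astype(np.int64)
    cs = np.concatenate([[0.0], np.cumsum(filled)])
    cb = np.concatenate([[0], np.cumsum(bad)])

    def rangesum(lo_off: int, hi_off: int) -> tuple[np.ndarray, np.ndarray]:
        # sum of d[i+lo_off .. i+hi_off] per i, plus bad-stack count
        i = np.arange(n)
        lo = i + lo_off
        hi = i + hi_off + 1
        ok = (lo >= 0) & (hi <= n)
        lo_c = np.clip(lo, 0, n)
        hi_c = np.clip(hi, 0, n)
        s = cs[hi_c] - cs[lo_c]
        nbad = cb[hi_c] - cb[lo_c]
        s[~ok] = np.nan
        nbad = np.where(ok, nbad, 1)
        return s, nbad

    first = 1 if profile.stacks_per_window == 7 else 0
    (ca, cb_), (oa, ob) = TEC_WINDOWS[mode]
    s_cur, bad_cur = rangesum(ca + first, cb_)
    s_oth, bad_oth = rangesum(oa + first, ob)
    out = s_cur - s_oth
    out[(bad_cur > 0) | (bad_oth > 0)] = np.nan
    return out


# ---------------------------------------------------------------------------
# Transcriptional mismatches

def mismatch_adjusted_energy(i: int, transcriptome: ConcatenatedTranscriptome,
                             profile: EnergyProfile, mismatch_table: NNEnergyTable,
                             mode: str = "dst1") -> tuple[float, float]:
    """(dTEC(i), dTEC_mm(i)) with a transcriptional error at the penultimate base i-1.

    The error replaces the RNA:DNA energies of the two stacks flanking i-1
    (stacks i-1 and i) with mismatch-table values; dTEC is recomputed with the
    adjusted stacks in whichever window contains them.  The covered error per
    template base is the homo-mismatch set rA.dA / rC.dC / rG.dG / rU.dT, so
    the mismatch identity is fully determined by the sequence.
    """
    base = delta_tec(i, mode, profile)
    if np.isnan(base):
        return base, float("nan")
    deltas = _mismatch_stack_deltas_at(transcriptome, profile, mismatch_table, i)
    if deltas is None:
        return base, float("nan")
    return base, _apply_mismatch(base, deltas, mode, profile.stacks_per_window, i)


def _mismatch_stack_deltas_at(transcriptome, profile, mismatch_table, i):
    seq = transcriptome.sequence
    if i < 2 or i >= len(seq):
        return None
    if np.isnan(profile.e_rna[i - 1]) or np.isnan(profile.e_rna[i]):
        return None
    up, mm_base, down = seq[i - 2], seq[i - 1], seq[i]
    if "N" in (up, mm_base, down):
        return None
    d_left = mismatch_table.mismatch_energy(up + mm_base, "3p") - profile.e_rna[i - 1]
    d_right = mismatch_table.mismatch_energy(mm_base + down, "5p") - profile.e_rna[i]
    return d_left, d_right


def _stack_in_window(stack: int, i: int, window: tuple[int, int], stacks_per_window: int) -> bool:
    a, b = i + window[0], i + window[1]
    lo = a + 1 if stacks_per_window == 7 else a
    return lo <= stack <= b


def _apply_mismatch(base: float, deltas: tuple[float, float], mode: str,
                    stacks_per_window: int, i: int) -> float:
    cur_w, oth_w = TEC_WINDOWS[mode]
    adj = base
    for stack, dlt in zip((i - 1, i), deltas):
        if _stack_in_window(stack, i, cur_w, stacks_per_window):
            adj += dlt
        if _stack_in_window(stack, i, oth_w, stacks_per_window):
            adj -= dlt
    return adj


def mismatch_delta_tec_track(transcriptome: ConcatenatedTranscriptome,
                             profile: EnergyProfile, mismatch_table: NNEnergyTable,
                             mode: str = "dst1") -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (dTEC, dTEC_mm) tracks for an error at the penultimate base.

    In dst1 mode both affected stacks (i-1 and i) lie in the prospective
    window, so dTEC_mm = dTEC - delta; in wt mode both lie in the current
    window, so dTEC_mm = dTEC + delta.  delta < 0 for a destabilizing
    mismatch, hence errors raise dTEC in dst1 mode (pause-promoting).
    """
    base = delta_tec_track(profile, mode)
    seq_codes = transcriptome.codes
    n = len(seq_codes)
    e_rna = profile.e_rna

    # vectorized stack deltas: lut keyed by (dinuc, side)
    lut3 = np.full(16, np.nan)
    lut5 = np.full(16, np.nan)
    for a in range(4):
        for b in range(4):
            dn = _BASES[a] + _BASES[b]
            lut3[4 * a + b] = mismatch_table.mismatch_energy(dn, "3p")
            lut5[4 * a + b] = mismatch_table.mismatch_energy(dn, "5p")

    delta = np.full(n, np.nan)
    i = np.arange(2, n)
    up, mm, down = seq_codes[i - 2], seq_codes[i - 1], seq_codes[i]
    ok = (up < 4) & (mm < 4) & (down < 4)
    ok &= ~np.isnan(e_rna[i - 1]) & ~np.isnan(e_rna[i])
    left_idx = 4 * up.astype(np.int64) + mm.astype(np.int64)
    right_idx = 4 * mm.astype(np.int64) + down.astype(np.int64)
    with np.errstate(invalid="ignore"):
        dlt = (lut3[left_idx] - e_rna[i - 1]) + (lut5[right_idx] - e_rna[i])
    delta[i] = np.where(ok, dlt, np.nan)

    sign = -1.0 if mode == "dst1" else 1.0
    adjusted = base + sign * delta
    return base, adjusted
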