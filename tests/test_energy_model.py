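import numpy as np
import pytest

from tecpause import energy_model as em
from tecpause.io_formats import GeneInterval, build_concatenated_transcriptome, reverse_complement

RNG = np.random.default_rng(11)


def random_seq(n, rng=RNG):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestEnergyTables:
    def test_temperature_is_stored_and_default_is_303(self, dna_table):
        assert dna_table.temperature == 303.0

    def test_all_16_stacks_present_and_positive(self, dna_table, rna_table):
        for t in (dna_table, rna_table):
            assert len(t.entries) == 16
            assert all(v > 0 for v in t.entries.values())

    def test_dna_reverse_complement_symmetry(self, dna_table):
        for d in dna_table.entries:
            assert dna_table.energy(d) == pytest.approx(
                dna_table.energy(reverse_complement(d)), abs=1e-12)

    def test_entries_linear_and_decreasing_in_temperature(self):
        # dG = dH - T*dS with dS < 0: melting energy falls as T rises, linearly
        t1 = em.build_energy_table("DNA:DNA", 290.0)
        t2 = em.build_energy_table("DNA:DNA", 303.0)
        t3 = em.build_energy_table("DNA:DNA", 316.0)
        for d in t1.entries:
            assert t1.energy(d) > t2.energy(d) > t3.energy(d)
            midpoint = (t1.energy(d) + t3.energy(d)) / 2
            assert t2.energy(d) == pytest.approx(midpoint, abs=1e-9)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown table kind"):
            em.build_energy_table("RNA:RNA")


class TestDuplexMeltingEnergy:
    def test_single_base_has_no_stacks(self, dna_table, rna_table):
        assert em.duplex_melting_energy("A", dna_table) == 0.0
        assert em.duplex_melting_energy("G", rna_table) == 0.0

    def test_rc_symmetric_dinucleotides_match(self, dna_table):
        assert em.duplex_melting_energy("AG", dna_table) == pytest.approx(
            em.duplex_melting_energy("CT", dna_table))

    @pytest.mark.parametrize("table_fixture", ["dna_table", "rna_table"])
    def test_hand_summed_stacks(self, table_fixture, request):
        table = request.getfixturevalue(table_fixture)
        seq = "ACGT"
        expected = table.energy("AC") + table.energy("CG") + table.energy("GT")
        assert em.duplex_melting_energy(seq, table) == pytest.approx(expected)

    def test_matches_stack_sum_on_random_sequences(self, dna_table, rna_table):
        rng = np.random.default_rng(5)
        for _ in range(50):
            seq = random_seq(int(rng.integers(2, 21)), rng)
            for table in (dna_table, rna_table):
                oracle = sum(table.energy(seq[i:i + 2]) for i in range(len(seq) - 1))
                assert em.duplex_melting_energy(seq, table) == pytest.approx(oracle)

    def test_additivity_over_a_shared_base(self, dna_table):
        rng = np.random.default_rng(6)
        for _ in range(20):
            s1, s2 = random_seq(8, rng), random_seq(8, rng)
            seq = s1 + s2
            junction = dna_table.energy(s1[-1] + s2[0])
            assert em.duplex_melting_energy(seq, dna_table) == pytest.approx(
                em.duplex_melting_energy(s1, dna_table)
                + em.duplex_melting_energy(s2, dna_table) + junction)

    def test_invalid_base_rejected(self, dna_table):
        with pytest.raises(ValueError, match="invalid base"):
            em.duplex_melting_energy("ACNG", dna_table)


class TestPerPositionEnergies:
    def test_first_base_of_each_gene_is_invalid(self, small_transcriptome, dna_table):
        tx, _, _ = small_transcriptome
        e = em.per_position_energies(tx, dna_table)
        for b in tx.boundaries[:-1]:
            assert np.isnan(e[b])

    def test_homopolymer_energy_is_constant(self, dna_table):
        tx = build_concatenated_transcriptome(
            {"c": "AAAA"}, [GeneInterval("c", 0, 4, "+", "g")])
        e = em.per_position_energies(tx, dna_table)
        assert np.isnan(e[0])
        np.testing.assert_allclose(e[1:], dna_table.energy("AA"))

    def test_assignment_to_more_3prime_base(self, dna_table):
        tx = build_concatenated_transcriptome(
            {"c": "ACGT"}, [GeneInterval("c", 0, 4, "+", "g")])
        e = em.per_position_energies(tx, dna_table)
        assert e[1] == pytest.approx(dna_table.energy("AC"))
        assert e[3] == pytest.approx(dna_table.energy("GT"))

    def test_n_bases_invalidate_adjacent_stacks(self, dna_table):
        tx = build_concatenated_transcriptome(
            {"c": "ACNGT"}, [GeneInterval("c", 0, 5, "+", "g")])
        e = em.per_position_energies(tx, dna_table)
        assert np.isnan(e[2]) and np.isnan(e[3])
        assert np.isfinite(e[1]) and np.isfinite(e[4])


class TestTecStability:
    def test_window_equals_rna_minus_dna_substring_energy(
            self, small_transcriptome, small_profile, dna_table, rna_table):
        tx, _, _ = small_transcriptome
        rng = np.random.default_rng(8)
        for _ in range(30):
            a = int(rng.integers(1, len(tx) - em.HYBRID_LENGTH))
            b = a + em.HYBRID_LENGTH - 1
            got = em.tec_stability((a, b), small_profile)
            sub = tx.sequence[a : b + 1]
            if "N" in sub or tx.gene_of(a) != tx.gene_of(b):
                assert np.isnan(got)
                continue
            oracle = (em.duplex_melting_energy(sub, rna_table)
                      - em.duplex_melting_energy(sub, dna_table))
            assert got == pytest.approx(oracle, abs=1e-9)

    def test_identical_tables_give_zero(self, small_transcriptome, dna_table):
        tx, _, _ = small_transcriptome
        e = em.per_position_energies(tx, dna_table)
        prof = em.EnergyProfile(e_rna=e.copy(), e_dna=e.copy())
        assert em.tec_stability((10, 17), prof) == pytest.approx(0.0)


class TestDeltaTec:
    def test_homopolymer_is_zero_in_both_modes(self, dna_table, rna_table):
        tx = build_concatenated_transcriptome(
            {"c": "A" * 60}, [GeneInterval("c", 0, 60, "+", "g")])
        prof = em.EnergyProfile(
            e_rna=em.per_position_energies(tx, rna_table),
            e_dna=em.per_position_energies(tx, dna_table))
        for mode in ("dst1", "wt"):
            assert em.delta_tec(30, mode, prof) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("mode", ["dst1", "wt"])
    def test_scalar_matches_brute_force_window_difference(
            self, mode, small_transcriptome, small_profile, dna_table, rna_table):
        tx, _, _ = small_transcriptome
        rng = np.random.default_rng(9)
        (ca, cb), (oa, ob) = em.TEC_WINDOWS[mode]
        for i in rng.integers(20, len(tx) - 20, size=200):
            i = int(i)
            got = em.delta_tec(i, mode, small_profile)
            lo = min(i + ca, i + oa)
            hi = max(i + cb, i + ob)
            if tx.gene_of(max(lo, 0)) != tx.gene_of(min(hi, len(tx) - 1)) or lo < 1:
                continue
            cur = tx.sequence[i + ca : i + cb + 1]
            oth = tx.sequence[i + oa : i + ob + 1]
            oracle = (
                em.duplex_melting_energy(cur, rna_table)
                - em.duplex_melting_energy(cur, dna_table)
                - em.duplex_melting_energy(oth, rna_table)
                + em.duplex_melting_energy(oth, dna_table)
            )
            assert got == pytest.approx(oracle, abs=1e-9)

    @pytest.mark.parametrize("mode", ["dst1", "wt"])
    def test_track_matches_scalar(self, mode, small_profile):
        track = em.delta_tec_track(small_profile, mode)
        rng = np.random.default_rng(10)
        for i in rng.integers(0, len(track), size=300):
            i = int(i)
            scalar = em.delta_tec(i, mode, small_profile)
            if np.isnan(scalar):
                assert np.isnan(track[i])
            else:
                assert track[i] == pytest.approx(scalar, abs=1e-9)

    def test_dst1_windows_cover_consecutive_disjoint_stacks(self):
        (ca, cb), (oa, ob) = em.TEC_WINDOWS["dst1"]
        cur_stacks = set(range(ca + 1, cb + 1))
        oth_stacks = set(range(oa + 1, ob + 1))
        assert len(cur_stacks) == len(oth_stacks) == 7
        assert not cur_stacks & oth_stacks
        assert cur_stacks | oth_stacks == set(range(-9, 5))

    def test_translation_covariance(self, dna_table, rna_table):
        rng = np.random.default_rng(12)
        core = random_seq(80, rng)
        shift = 11
        for pad in ("", random_seq(shift, rng)):
            tx = build_concatenated_transcriptome(
                {"c": pad + core}, [GeneInterval("c", 0, len(pad) + 80, "+", "g")])
            prof = em.EnergyProfile(
                e_rna=em.per_position_energies(tx, rna_table),
                e_dna=em.per_position_energies(tx, dna_table))
            if not pad:
                base = em.delta_tec_track(prof, "dst1")
            else:
                shifted = em.delta_tec_track(prof, "dst1")
        # interior values must line up exactly under the shift
        np.testing.assert_allclose(shifted[shift + 20 : shift + 60], base[20:60], atol=1e-9)

    def test_eight_stack_convention_supported(self, small_transcriptome, dna_table, rna_table):
        tx, _, _ = small_transcriptome
        prof8 = em.EnergyProfile(
            e_rna=em.per_position_energies(tx, rna_table),
            e_dna=em.per_position_energies(tx, dna_table),
            stacks_per_window=8)
        d = prof8.d
        i = 40
        (ca, cb), (oa, ob) = em.TEC_WINDOWS["dst1"]
        oracle = np.nansum(d[i + ca : i + cb + 1]) - np.nansum(d[i + oa : i + ob + 1])
        assert em.delta_tec(i, "dst1", prof8) == pytest.approx(oracle, abs=1e-9)


class TestMismatchAdjustment:
    def test_identity_mismatch_table_changes_nothing(self, small_transcriptome, small_profile, rna_table):
        tx, _, _ = small_transcriptome
        ident = em.NNEnergyTable(kind="RNA:DNA-mismatch", temperature=303.0)
        for d, v in rna_table.entries.items():
            ident.mismatch_entries[(d, "5p")] = v
            ident.mismatch_entries[(d, "3p")] = v
        base, adj = em.mismatch_delta_tec_track(tx, small_profile, ident, "dst1")
        ok = np.isfinite(base) & np.isfinite(adj)
        np.testing.assert_allclose(adj[ok], base[ok], atol=1e-9)

    def test_destabilizing_mismatch_raises_dtec_in_dst1_mode(
            self, small_transcriptome, small_profile, mismatch_table):
        tx, _, _ = small_transcriptome
        base, adj = em.mismatch_delta_tec_track(tx, small_profile, mismatch_table, "dst1")
        ok = np.isfinite(base) & np.isfinite(adj)
        assert np.all(adj[ok] >= base[ok] - 1e-9)

    def test_matches_brute_force_window_recomputation(
            self, small_transcriptome, small_profile, mismatch_table):
        """Oracle: rebuild both windows from scratch with substituted stacks."""
        tx, _, _ = small_transcriptome
        prof = small_profile
        rng = np.random.default_rng(13)
        checked = 0
        for i in rng.integers(20, len(tx) - 20, size=100):
            i = int(i)
            base, adj = em.mismatch_adjusted_energy(i, tx, prof, mismatch_table, "dst1")
            if np.isnan(adj):
                continue
            e_rna_mm = prof.e_rna.copy()
            seq = tx.sequence
            e_rna_mm[i - 1] = mismatch_table.mismatch_energy(seq[i - 2] + seq[i - 1], "3p")
            e_rna_mm[i] = mismatch_table.mismatch_energy(seq[i - 1] + seq[i], "5p")
            prof_mm = em.EnergyProfile(e_rna=e_rna_mm, e_dna=prof.e_dna)
            oracle = em.delta_tec(i, "dst1", prof_mm)
            assert adj == pytest.approx(oracle, abs=1e-9)
            checked += 1
        assert checked > 50

    def test_track_matches_scalar(self, small_transcriptome, small_profile, mismatch_table):
        tx, _, _ = small_transcriptome
        base_t, adj_t = em.mismatch_delta_tec_track(tx, small_profile, mismatch_table, "wt")
        rng = np.random.default_rng(14)
        for i in rng.integers(0, len(tx), size=100):
            i = int(i)
            base, adj = em.mismatch_adjusted_energy(i, tx, small_profile, mismatch_table, "wt")
            np.testing.assert_allclose([base_t[i], adj_t[i]], [base, adj], atol=1e-9, equal_nan=True)
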