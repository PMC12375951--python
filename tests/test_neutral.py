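"""Neutral codon transition probabilities against brute-force enumeration."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from abselect import neutral as nt
from abselect.neutral import KmerNeutralProvider, NucleotideRates, TableNeutralProvider
from abselect.seqcodec import CODONS, NT_INDEX, PCP, CodonSequence, translate


def brute_force_codon_probs(lam3, sub3, t, parent_codon):
    """Oracle: enumerate the 4x4x4 outcome space from the three independent
    per-position distributions."""
    per_pos = []
    for k in range(3):
        stay = math.exp(-lam3[k] * t)
        v = [(1 - stay) * sub3[k][b] for b in range(4)]
        v[NT_INDEX[parent_codon[k]]] = stay
        per_pos.append(v)
    out = np.zeros(64)
    for i, codon in enumerate(CODONS):
        out[i] = (
            per_pos[0][NT_INDEX[codon[0]]]
            * per_pos[1][NT_INDEX[codon[1]]]
            * per_pos[2][NT_INDEX[codon[2]]]
        )
    return out


def uniform_alt(codon):
    sub = np.full((3, 4), 1 / 3)
    for k in range(3):
        sub[k, NT_INDEX[codon[k]]] = 0.0
    return sub


class TestCodonProbs:
    def test_matches_enumeration_oracle(self):
        lam = [0.1, 0.2, 0.3]
        sub = uniform_alt("ATG")
        got = nt.codon_probs(lam, sub, 1.0, "ATG")
        want = brute_force_codon_probs(lam, sub, 1.0, "ATG")
        np.testing.assert_allclose(got, want, atol=1e-12)
        assert got.sum() == pytest.approx(1.0, abs=1e-12)

    def test_t_zero_is_point_mass_on_parent(self):
        got = nt.codon_probs([0.5, 0.5, 0.5], uniform_alt("GCT"), 0.0, "GCT")
        assert got[CODONS.index("GCT")] == 1.0
        assert got.sum() == 1.0

    def test_single_position_change_product_form(self):
        # AGC -> AGG over sites with rates (l7, l8, l9):
        # exp(-l7 t) exp(-l8 t) (1 - exp(-l9 t)) s9G
        lam = [0.11, 0.07, 0.23]
        sub = np.zeros((3, 4))
        sub[0] = [0.0, 0.2, 0.5, 0.3]   # parent A
        sub[1] = [0.1, 0.4, 0.0, 0.5]   # parent G
        sub[2] = [0.25, 0.0, 0.6, 0.15]  # parent C
        t = 0.8
        got = nt.codon_probs(lam, sub, t, "AGC")
        want = (
            math.exp(-lam[0] * t) * math.exp(-lam[1] * t)
            * (1 - math.exp(-lam[2] * t)) * sub[2][NT_INDEX["G"]]
        )
        assert got[CODONS.index("AGG")] == pytest.approx(want, rel=1e-12)

    @given(
        st.lists(st.floats(0.0, 3.0), min_size=3, max_size=3),
        st.sampled_from(["ATG", "GGG", "TCA", "CAT"]),
        st.floats(0.0, 4.0),
    )
    def test_normalization_and_oracle_property(self, lam, parent, t):
        sub = uniform_alt(parent)
        got = nt.codon_probs(lam, sub, t, parent)
        assert got.sum() == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(
            got, brute_force_codon_probs(lam, sub, t, parent), atol=1e-12
        )

    def test_negative_t_raises(self):
        with pytest.raises(ValueError):
            nt.codon_probs([0.1] * 3, uniform_alt("ATG"), -0.5, "ATG")

    def test_ambiguous_parent_raises(self):
        with pytest.raises(ValueError):
            nt.codon_probs([0.1] * 3, uniform_alt("ATG"), 1.0, "ANG")


class TestNonsynProfile:
    def test_zero_at_t_zero(self, uniform_rates):
        seq = CodonSequence("ATGGCTTTT")
        p = nt.nonsyn_profile(seq, uniform_rates(9), 0.0)
        np.testing.assert_array_equal(p, np.zeros(3))

    def test_single_codon_matches_oracle_sum(self, uniform_rates):
        seq = CodonSequence("ATG")
        provider = uniform_rates(3)
        p = nt.nonsyn_profile(seq, provider, 1.0)
        rates = provider.rates("ATG")
        full = brute_force_codon_probs(rates.lam, rates.sub, 1.0, "ATG")
        want = sum(
            full[i] for i, c in enumerate(CODONS)
            if translate(c) not in ("M", "*")
        )
        assert p[0] == pytest.approx(want, abs=1e-12)

    def test_masked_entry_for_ambiguous_codon(self, uniform_rates):
        seq = CodonSequence("ATGGNTTTT")
        p = nt.nonsyn_profile(seq, uniform_rates(9), 0.5)
        assert np.isnan(p[1]) and np.isfinite(p[[0, 2]]).all()

    def test_all_ambiguous_warns(self, uniform_rates):
        seq = CodonSequence("NNNNNN")
        with pytest.warns(UserWarning, match="masked"):
            p = nt.nonsyn_profile(seq, uniform_rates(6), 0.5)
        assert np.isnan(p).all()

    def test_small_t_linearization(self, uniform_rates):
        """dp_j/dt at t=0 equals the sum of lambda_i s_ib over
        single-nucleotide nonsynonymous changes."""
        seq = CodonSequence("ATGGCT")
        provider = uniform_rates(6)
        rates = provider.rates(seq.nucleotides)
        eps = 1e-7
        numeric = nt.nonsyn_profile(seq, provider, eps) / eps
        for j, codon in enumerate(seq.codons):
            analytic = 0.0
            for k in range(3):
                for b, base in enumerate("ACGT"):
                    if base == codon[k]:
                        continue
                    mutant = codon[:k] + base + codon[k + 1:]
                    if translate(mutant) not in (translate(codon), "*"):
                        analytic += rates.lam[3 * j + k] * rates.sub[3 * j + k, b]
            assert numeric[j] == pytest.approx(analytic, rel=1e-4)


class TestProviders:
    def test_table_provider_rezeroes_parent_base(self):
        lam = np.array([0.5, 1.0, 1.5])
        sub = np.full((3, 4), 0.25)
        provider = TableNeutralProvider(NucleotideRates(lam, sub))
        rates = provider.rates("ACG")
        for i, base in enumerate("ACG"):
            assert rates.sub[i, NT_INDEX[base]] == 0.0
            assert rates.sub[i].sum() == pytest.approx(1.0)

    def test_provider_determinism(self, kmer_provider):
        seq = "ATGGCTTTTCCA"
        a, b = kmer_provider.rates(seq), kmer_provider.rates(seq)
        assert np.array_equal(a.lam, b.lam) and np.array_equal(a.sub, b.sub)

    def test_length_mismatch_raises(self, uniform_rates):
        with pytest.raises(ValueError):
            uniform_rates(6).rates("ATGGCTTTT")

    def test_table_tsv_round_trip(self, tmp_path, uniform_rates):
        provider = uniform_rates(9)
        provider.to_tsv(tmp_path / "rates.tsv")
        back = TableNeutralProvider.from_tsv(tmp_path / "rates.tsv")
        seq = "ATGGCTTTT"
        np.testing.assert_allclose(back.rates(seq).lam, provider.rates(seq).lam)
        np.testing.assert_allclose(back.rates(seq).sub, provider.rates(seq).sub)

    def test_kmer_tsv_round_trip(self, tmp_path, kmer_provider):
        kmer_provider.to_tsv(tmp_path / "kmer.tsv")
        back = KmerNeutralProvider.from_tsv(tmp_path / "kmer.tsv")
        seq = "ATGGCTTTTCCAGGA"
        np.testing.assert_allclose(back.rates(seq).lam, kmer_provider.rates(seq).lam)
        np.testing.assert_allclose(back.rates(seq).sub, kmer_provider.rates(seq).sub)


class TestEstimateKmerRates:
    def _pair(self, parent, child):
        return PCP(parent, child)

    def test_closed_form_rate(self):
        # central site context observed 4 times, mutated once: -log(3/4)
        pcps = []
        # context 'AACGA' centered on C at position 2 of an 9-mer
        for child_mid in ["C", "C", "C", "T"]:
            p = "AAACGAAAT"
            c = p[:3] + child_mid + p[4:]
            pcps.append(self._pair(p, c))
        provider = nt.estimate_kmer_rates(pcps, k=5)
        rate, _ = provider.table["AACGA"]
        assert rate == pytest.approx(-math.log(3 / 4), rel=1e-12)

    def test_zero_mutations_zero_rate_uniform_smoothing(self):
        pcps = [self._pair("AAACGAAAT", "AAACGAAAT")] * 100
        provider = nt.estimate_kmer_rates(pcps, k=5)
        rate, sub = provider.table["AACGA"]
        assert rate == 0.0
        alternates = sub[sub > 0]
        np.testing.assert_allclose(alternates, 1 / 3)

    def test_add_one_smoothed_distribution(self):
        # center C mutated to A twice, G once, T once -> (3/7, 2/7, 2/7)
        pcps = []
        p = "AAACGAAAT"
        for child_mid in ["A", "A", "G", "T"]:
            pcps.append(self._pair(p, p[:3] + child_mid + p[4:]))
        provider = nt.estimate_kmer_rates(pcps, k=5)
        _, sub = provider.table["AACGA"]
        np.testing.assert_allclose(
            sub[[NT_INDEX["A"], NT_INDEX["G"], NT_INDEX["T"]]],
            [3 / 7, 2 / 7, 2 / 7],
        )
        assert sub[NT_INDEX["C"]] == 0.0

    def test_even_k_and_empty_input_raise(self):
        with pytest.raises(ValueError):
            nt.estimate_kmer_rates([self._pair("AAACGAAAT", "AAACGAAAT")], k=4)
        with pytest.raises(ValueError):
            nt.estimate_kmer_rates([], k=5)
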