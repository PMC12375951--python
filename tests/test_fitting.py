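"""Mutation-selection composition, losses, branch lengths, training loop."""

import math

import numpy as np
import pytest

from abselect import fitting as ft
from abselect import synthetic_data as sd
from abselect.neutral import neutral_codon_probs, nonsyn_profile
from abselect.seqcodec import CODONS, PCP, CodonSequence, translate
from abselect.selection import SelectionModelConfig, build_selection_model


def single_factor(value: float = 1.0):
    model = build_selection_model(SelectionModelConfig(family="single"))
    # invert the wiggle so the emitted factor equals `value` exactly
    beta = model.config.beta
    theta = value ** (1 / beta) if value >= 1 else 1 + math.log(value) / beta
    model._params["theta"].data[:] = theta
    return model


class TestMutselProbs:
    def setup_method(self):
        self.parent = CodonSequence("ATGGCTTGG")
        self.rng = np.random.default_rng(0)

    def _neutral(self, provider, t=0.4):
        return neutral_codon_probs(self.parent, provider, t)

    def test_neutral_limit_identity(self, uniform_rates):
        probs = self._neutral(uniform_rates(9))
        ms = ft.mutsel_probs(probs, self.parent, np.ones(3))
        for j in range(3):
            wt = ms.wt_idx[j]
            for c in range(64):
                if translate(CODONS[c]) == "*":
                    assert ms.codon_probs[j, c] == 0.0
                elif c != wt:
                    assert ms.codon_probs[j, c] == pytest.approx(probs[j, c], abs=1e-12)
        # m_j equals the neutral nonsynonymous sum
        np.testing.assert_allclose(
            ms.nonsyn, nonsyn_profile(self.parent, uniform_rates(9), 0.4), atol=1e-12
        )

    def test_factor_scales_aggregate(self, uniform_rates):
        probs = self._neutral(uniform_rates(9))
        base = ft.mutsel_probs(probs, self.parent, np.ones(3)).nonsyn
        doubled = ft.mutsel_probs(probs, self.parent, np.full(3, 2.0)).nonsyn
        np.testing.assert_allclose(doubled, 2 * base, rtol=1e-10)

    def test_wt_is_remainder_and_rows_sum_to_one(self, uniform_rates):
        probs = self._neutral(uniform_rates(9))
        ms = ft.mutsel_probs(probs, self.parent, np.array([0.3, 1.7, 2.5]))
        sums = np.nansum(ms.codon_probs, axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-10)
        assert np.all(ms.codon_probs[ms.mask] >= 0)

    def test_clamp_activates_above_one(self, uniform_rates):
        # big t and huge factor force the aggregate over 1
        probs = self._neutral(uniform_rates(9), t=4.5)
        ms = ft.mutsel_probs(probs, self.parent, np.full(3, 50.0))
        assert ms.clamped.any()
        assert np.nanmax(np.nansum(ms.codon_probs, axis=1)) == pytest.approx(1.0, abs=1e-9)
        assert np.all(ms.nonsyn[ms.mask] <= ft.CLAMP + 1e-12)

    def test_length_mismatch_raises(self, uniform_rates):
        probs = self._neutral(uniform_rates(9))
        with pytest.raises(ValueError):
            ft.mutsel_probs(probs, self.parent, np.ones(4))


class TestPcpLoss:
    def test_bernoulli_closed_forms(self):
        assert ft.bce_terms(np.array([0.25]), np.array([0.0]))[0] == pytest.approx(
            -math.log(0.75), rel=1e-12
        )
        two = ft.bce_terms(np.array([0.25, 0.5]), np.array([1.0, 0.0])).sum()
        assert two == pytest.approx(-math.log(0.25) - math.log(0.5), rel=1e-12)

    def test_matches_independent_bernoulli_nll(self, uniform_rates):
        """Neutral limit: pcp_loss equals a from-scratch Bernoulli NLL built
        on enumerated neutral codon probabilities (agreement to 1e-10)."""
        parent = CodonSequence("ATGGCTTGGAAA")
        child = CodonSequence("ATGGTTTGGAAA")  # A->V at codon 1
        pcp = PCP(parent, child)
        provider = uniform_rates(12)
        t = 0.37
        loss = ft.pcp_loss(pcp, single_factor(1.0), provider, t)

        rates = provider.rates(parent.nucleotides)
        ref = 0.0
        from test_neutral import brute_force_codon_probs

        for j, codon in enumerate(parent.codons):
            lam3 = rates.lam[3 * j : 3 * j + 3]
            sub3 = rates.sub[3 * j : 3 * j + 3]
            full = brute_force_codon_probs(lam3, sub3, t, codon)
            p_ns = sum(
                full[i] for i, c in enumerate(CODONS)
                if translate(c) not in (translate(codon), "*")
            )
            y = parent.aa[j] != child.aa[j]
            ref -= math.log(p_ns) if y else math.log(1 - p_ns)
        assert loss == pytest.approx(ref, abs=1e-10)

    def test_infinite_loss_surfaces_at_impossible_substitution(self, uniform_rates):
        pcp = PCP("ATGGCT", "ATGACT")
        loss = ft.pcp_loss(pcp, single_factor(1.0), uniform_rates(6), 0.0)
        assert math.isinf(loss)

    def test_negative_t_raises(self, uniform_rates):
        with pytest.raises(ValueError):
            ft.pcp_loss(PCP("ATGGCT", "ATGGCT"), single_factor(), uniform_rates(6), -1)


class TestBranchLength:
    def test_recovers_generating_t_against_grid_oracle(self, kmer_provider):
        """t* agrees with a fine grid search on the same objective and sits
        near the generating value for a long neutral simulation."""
        from abselect.simulate import sample_child

        naive = sd.gen_naive(300, rng=5)
        model = single_factor(1.0)
        t_true = 0.08
        child = sample_child(naive, model, kmer_provider, t_true,
                             np.random.default_rng(42))
        pcp = PCP(naive, child)
        res = ft.optimize_branch_length(pcp, model, kmer_provider)
        grid = np.exp(np.linspace(np.log(1e-4), np.log(1.0), 400))
        nlls = [ft.codon_nll(pcp, model, kmer_provider, t) for t in grid]
        t_grid = grid[int(np.argmin(nlls))]
        assert res.t == pytest.approx(t_grid, rel=2e-2)
        assert res.t == pytest.approx(t_true, rel=0.5)
        assert not res.pinned

    def test_scale_symmetry_rate_time_product(self, uniform_rates):
        """Doubling all rates halves the fitted t: only lambda*t is known."""
        from abselect.neutral import NucleotideRates, TableNeutralProvider

        naive = sd.gen_naive(200, rng=6)
        model = single_factor(1.0)
        base = uniform_rates(600)
        doubled = TableNeutralProvider(
            NucleotideRates(base._rates.lam * 2, base._rates.sub)
        )
        from abselect.simulate import sample_child

        child = sample_child(naive, model, base, 0.2, np.random.default_rng(1))
        pcp = PCP(naive, child)
        t1 = ft.optimize_branch_length(pcp, model, base).t
        t2 = ft.optimize_branch_length(pcp, model, doubled).t
        assert t2 == pytest.approx(t1 / 2, rel=2e-2)

    def test_synonymous_substitutions_pull_t_up(self, uniform_rates):
        """A child with extra synonymous changes gets a larger t even though
        its amino-acid sequence is unchanged."""
        parent = CodonSequence("CTTCGTTCT" * 20)
        few = list(parent.codons)
        many = list(parent.codons)
        for j in range(0, 60, 3):
            many[j] = {"CTT": "CTC", "CGT": "CGC", "TCT": "TCC"}[many[j]]
        for j in (0, 30):
            few[j] = {"CTT": "CTC"}.get(few[j], few[j])
        model = single_factor(1.0)
        provider = uniform_rates(180)
        t_few = ft.optimize_branch_length(
            PCP(parent, CodonSequence("".join(few))), model, provider).t
        t_many = ft.optimize_branch_length(
            PCP(parent, CodonSequence("".join(many))), model, provider).t
        assert t_many > t_few

    def test_no_substitutions_pins_at_minimum_with_flag(self, uniform_rates):
        pcp = PCP("ATGGCT", "ATGGCT")
        res = ft.optimize_branch_length(pcp, single_factor(1.0), uniform_rates(6))
        assert res.pinned and res.t == pytest.approx(ft.T_MIN, rel=2e-3)

    def test_batch_optimizer_agrees_with_scalar(self, kmer_provider, context_truth,
                                                small_pcps):
        ds = ft.PCPDataset.build(small_pcps[:50], kmer_provider)
        t_batch, _, _ = ds.optimize_branch_lengths(context_truth)
        for i in (0, 7, 23, 49):
            res = ft.optimize_branch_length(small_pcps[i], context_truth, kmer_provider)
            assert t_batch[i] == pytest.approx(res.t, rel=1e-2)


class TestFit:
    def test_cycles_zero_leaves_model_untouched(self, kmer_provider, small_pcps):
        model = build_selection_model(
            SelectionModelConfig(heads=2, dims_per_head=4, layers=1, max_len=80), seed=9
        )
        before = {k: v.data.copy() for k, v in model.named_parameters().items()}
        state = ft.fit(small_pcps[:100], model, kmer_provider, cycles=0)
        for k, v in model.named_parameters().items():
            assert np.array_equal(before[k], v.data)
        assert state.branch_lengths.shape == (100,)
        assert np.all(state.branch_lengths > 0)

    def test_single_factor_recovers_neutrality(self, kmer_provider, neutral_truth):
        """Fitting the one-parameter model to neutral simulations returns a
        factor close to 1."""
        pcps = sd.gen_pcp_dataset(1500, neutral_truth, kmer_provider, seed=77)
        model = build_selection_model(SelectionModelConfig(family="single"))
        state = ft.fit(pcps, model, kmer_provider, cycles=2, epochs_per_cycle=2,
                       batch_size=256, lr=3e-2, seed=5)
        assert 0.9 <= model.factor <= 1.1
        assert state.cycles_done == 2

    def test_loss_trace_non_increasing(self, kmer_provider, context_truth):
        pcps = sd.gen_pcp_dataset(800, context_truth, kmer_provider, seed=55)
        model = build_selection_model(
            SelectionModelConfig(heads=2, dims_per_head=8, layers=1, max_len=80,
                                 dropout=0.0), seed=2
        )
        state = ft.fit(pcps, model, kmer_provider, cycles=3, epochs_per_cycle=1,
                       batch_size=128, seed=4)
        train = [rec["train_loss"] for rec in state.loss_trace]
        assert train[-1] <= train[0] + 1e-6
        val = [rec["val_loss"] for rec in state.loss_trace]
        assert val[-1] <= val[0] + 5e-3  # held-out loss improves too

    def test_empty_training_set_raises(self, kmer_provider):
        model = build_selection_model(SelectionModelConfig(family="single"))
        with pytest.raises(ValueError):
            ft.fit([], model, kmer_provider)

    def test_identifiability_under_time_inflation(self, kmer_provider, neutral_truth):
        """Simulating with all true branch lengths doubled changes fitted t,
        not the fitted selection factor (synonymous signal anchors t)."""
        factors = []
        for scale, seed in ((1.0, 31), (2.0, 31)):
            pcps = sd.gen_pcp_dataset(
                1200, neutral_truth, kmer_provider, seed=seed,
                mean_branch=0.05 * scale,
            )
            model = build_selection_model(SelectionModelConfig(family="single"))
            ft.fit(pcps, model, kmer_provider, cycles=2, epochs_per_cycle=2,
                   batch_size=256, lr=3e-2, seed=5)
            factors.append(model.factor)
        assert factors[1] == pytest.approx(factors[0], abs=0.12)
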