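"""GY94 rate matrices, pruning likelihoods, and maximum-likelihood fits."""

import itertools

import numpy as np
import pytest

import dupsel as d
from dupsel.genetics import CodonAlignment
from dupsel.likelihood import (
    CODON_INDEX,
    N_CODONS,
    _eigen_decompose,
    equal_frequencies,
    f3x4_frequencies,
    empirical_codon_frequencies,
    build_rate_matrix,
    transition_probabilities,
)
from dupsel.models import BranchModelSpec, SiteModelSpec
from dupsel.simulate import biased_frequencies
from dupsel.trees import LabeledTree


RANDOM_PARAMS = [(2.0, 0.3), (0.5, 1.7), (5.0, 0.05)]


class TestRateMatrix:
    @pytest.mark.parametrize("kappa,omega", RANDOM_PARAMS)
    def test_rows_sum_to_zero(self, kappa, omega):
        pi = biased_frequencies(0.7)
        Q = build_rate_matrix(kappa, omega, pi)
        assert np.abs(Q.sum(axis=1)).max() < 1e-12

    @pytest.mark.parametrize("kappa,omega", RANDOM_PARAMS)
    def test_detailed_balance(self, kappa, omega):
        pi = biased_frequencies(0.65)
        Q = build_rate_matrix(kappa, omega, pi)
        flow = pi[:, None] * Q
        assert np.abs(flow - flow.T).max() < 1e-14

    def test_unit_substitution_rate_after_scaling(self):
        pi = biased_frequencies(0.75)
        Q = build_rate_matrix(3.0, 0.1, pi)
        assert -(pi * np.diag(Q)).sum() == pytest.approx(1.0)

    def test_neutral_equal_frequency_limit_is_codon_adjacency(self):
        pi = equal_frequencies()
        Q = build_rate_matrix(1.0, 1.0, pi)
        off = Q.copy()
        np.fill_diagonal(off, 0.0)
        nz = off[off > 0]
        # all allowed single-step changes share one rate
        assert np.allclose(nz, nz[0])

    def test_negative_parameters_rejected(self):
        pi = equal_frequencies()
        with pytest.raises(ValueError):
            build_rate_matrix(-1.0, 0.5, pi)
        with pytest.raises(ValueError):
            build_rate_matrix(2.0, -0.5, pi)


class TestTransitionProbabilities:
    def test_zero_time_is_identity(self):
        Q = build_rate_matrix(2.0, 0.2, equal_frequencies())
        assert np.allclose(transition_probabilities(Q, 0.0), np.eye(N_CODONS))

    def test_rows_are_distributions(self):
        Q = build_rate_matrix(2.0, 0.2, biased_frequencies(0.7))
        P = transition_probabilities(Q, 0.7)
        assert np.abs(P.sum(axis=1) - 1.0).max() < 1e-10
        assert P.min() >= 0.0

    def test_long_time_reaches_stationarity(self):
        pi = biased_frequencies(0.7)
        Q = build_rate_matrix(2.0, 0.2, pi)
        P = transition_probabilities(Q, 100.0)
        assert np.abs(P - pi[None, :]).max() < 1e-6

    def test_chapman_kolmogorov(self):
        pi = biased_frequencies(0.6)
        eig = _eigen_decompose(1.5, 0.4, pi)
        s, t = 0.3, 0.9
        assert np.abs(eig.P(s) @ eig.P(t) - eig.P(s + t)).max() < 1e-8

    def test_invalid_time_rejected(self):
        Q = build_rate_matrix(2.0, 0.2, equal_frequencies())
        with pytest.raises(ValueError):
            transition_probabilities(Q, float("nan"))
        with pytest.raises(ValueError):
            transition_probabilities(Q, -0.1)


class TestFrequencies:
    def test_f3x4_and_empirical_are_simplices(self, sim_small):
        _, aln, _ = sim_small
        for pi in (f3x4_frequencies(aln), empirical_codon_frequencies(aln)):
            assert pi.shape == (61,)
            assert pi.sum() == pytest.approx(1.0, abs=1e-12)
            assert pi.min() > 0


class TestLogLikelihood:
    def test_single_taxon_is_log_stationary(self):
        aln = CodonAlignment(names=["A"], sequences=["ATGTTTCCC"])
        tree = LabeledTree.from_newick("A:0.0;")
        model = d.CodonModel(aln, tree, freq_mode="equal")
        lnL = model.log_likelihood(kappa=2.0, omega=0.5)
        expected = sum(
            np.log(model.pi[CODON_INDEX[c]]) for c in ("ATG", "TTT", "CCC")
        )
        assert lnL == pytest.approx(expected, abs=1e-10)

    def test_three_taxon_brute_force_oracle(self, tiny_aln):
        tree = LabeledTree.from_newick("(A:0.2,B:0.1,C:0.3);")
        model = d.CodonModel(tiny_aln, tree, freq_mode="equal")
        kappa, omega = 2.0, 0.3
        lnL = model.log_likelihood(kappa=kappa, omega=omega)
        eig = _eigen_decompose(kappa, omega, model.pi)
        P = {b.name: eig.P(b.length) for b in tree.branches()}
        states = {
            nm: [CODON_INDEX[tiny_aln.sequence(nm)[i : i + 3]]
                 for i in range(0, 15, 3)]
            for nm in "ABC"
        }
        brute = 0.0
        for h in range(5):
            site = sum(
                model.pi[r]
                * P["A"][r, states["A"][h]]
                * P["B"][r, states["B"][h]]
                * P["C"][r, states["C"][h]]
                for r in range(61)
            )
            brute += np.log(site)
        assert lnL == pytest.approx(brute, abs=1e-10)

    def test_likelihood_invariant_under_rerooting(self, sim_small):
        """Pulley principle: reversible-model lnL ignores root placement."""
        _, aln, _ = sim_small
        sub = aln.subset(aln.names[:6])
        t1 = LabeledTree.from_newick(
            "((A:0.1,B:0.2):0.05,(C:0.15,D:0.1):0.07,(E:0.2,F:0.1):0.03);"
            .replace("A", sub.names[0]).replace("B", sub.names[1])
            .replace("C", sub.names[2]).replace("D", sub.names[3])
            .replace("E", sub.names[4]).replace("F", sub.names[5])
        )
        # same unrooted shape, rooted on the E,F cherry instead
        t2 = LabeledTree.from_newick(
            "(((A:0.1,B:0.2):0.05,(C:0.15,D:0.1):0.07):0.03,E:0.2,F:0.1);"
            .replace("A", sub.names[0]).replace("B", sub.names[1])
            .replace("C", sub.names[2]).replace("D", sub.names[3])
            .replace("E", sub.names[4]).replace("F", sub.names[5])
        )
        pi = f3x4_frequencies(sub)
        l1 = d.CodonModel(sub, t1, pi=pi).log_likelihood(kappa=2.0, omega=0.2)
        l2 = d.CodonModel(sub, t2, pi=pi).log_likelihood(kappa=2.0, omega=0.2)
        assert l1 == pytest.approx(l2, abs=1e-8)

    def test_invariant_under_site_and_taxon_order(self, sim_small):
        spec, aln, _ = sim_small
        tree = spec.tree.copy()
        model = d.CodonModel(aln, tree, freq_mode="equal")
        base = model.log_likelihood(kappa=2.0, omega=0.1)
        # permute codon columns
        rng = np.random.default_rng(0)
        perm = rng.permutation(aln.codon_columns)
        shuffled = CodonAlignment(
            names=list(aln.names),
            sequences=[
                "".join(s[3 * j : 3 * j + 3] for j in perm)
                for s in aln.sequences
            ],
        )
        m2 = d.CodonModel(shuffled, tree, freq_mode="equal")
        assert m2.log_likelihood(kappa=2.0, omega=0.1) == pytest.approx(
            base, abs=1e-8
        )
        # permute taxon rows
        order = list(reversed(range(aln.n_sequences)))
        reordered = CodonAlignment(
            names=[aln.names[i] for i in order],
            sequences=[aln.sequences[i] for i in order],
        )
        m3 = d.CodonModel(reordered, tree, freq_mode="equal")
        assert m3.log_likelihood(kappa=2.0, omega=0.1) == pytest.approx(
            base, abs=1e-8
        )

    def test_missing_taxon_rejected(self, tiny_aln):
        tree = LabeledTree.from_newick("(A:0.1,B:0.1,Z:0.1);")
        with pytest.raises(ValueError, match="missing"):
            d.CodonModel(tiny_aln, tree)

    def test_all_gap_column_contributes_nothing(self):
        aln1 = CodonAlignment(names=["A", "B", "C"],
                              sequences=["ATGTTT", "ATGTTC", "ATGTTT"])
        aln2 = CodonAlignment(names=["A", "B", "C"],
                              sequences=["ATGTTT---", "ATGTTC---",
                                         "ATGTTT---"])
        tree = LabeledTree.from_newick("(A:0.1,B:0.1,C:0.1);")
        l1 = d.CodonModel(aln1, tree, freq_mode="equal").log_likelihood(
            kappa=2.0, omega=0.5
        )
        l2 = d.CodonModel(aln2, tree, freq_mode="equal").log_likelihood(
            kappa=2.0, omega=0.5
        )
        assert l1 == pytest.approx(l2, abs=1e-10)


class TestBranchGradient:
    def test_matches_central_differences(self, sim_small):
        spec, aln, _ = sim_small
        tree = spec.tree.copy()
        model = d.CodonModel(aln, tree)
        bl = np.asarray(tree.get_lengths())
        _, grad = model._loglik_branch(bl, 2.0, np.array([0.1]),
                                       want_grad=True)
        h = 1e-6
        for k in (0, len(bl) // 2, len(bl) - 1):
            up, dn = bl.copy(), bl.copy()
            up[k] += h
            dn[k] -= h
            fd = (
                model._loglik_branch(up, 2.0, np.array([0.1]))[0]
                - model._loglik_branch(dn, 2.0, np.array([0.1]))[0]
            ) / (2 * h)
            assert grad[k] == pytest.approx(fd, rel=1e-5, abs=1e-6)


class TestFit:
    def test_m0_recovers_generating_omega(self, m0_fit_small):
        _, res = m0_fit_small
        omega = next(v for k, v in res.params.items()
                     if k.startswith("omega"))
        assert omega == pytest.approx(0.055, abs=0.02)
        assert res.converged
        assert res.n_params == 1

    def test_refit_is_deterministic(self, sim_small, m0_fit_small):
        spec, aln, _ = sim_small
        model2 = d.CodonModel(aln, spec.tree.copy())
        res2 = model2.fit(starts=(0.05,))
        _, res1 = m0_fit_small
        assert res2.lnL == pytest.approx(res1.lnL, abs=1e-6)

    def test_loglik_at_fitted_params_reproduces_lnl(self, m0_fit_small):
        model, res = m0_fit_small
        omega = next(v for k, v in res.params.items()
                     if k.startswith("omega"))
        lnL = model.log_likelihood(
            kappa=res.kappa, branch_lengths=res.branch_lengths, omega=omega
        )
        assert lnL == pytest.approx(res.lnL, abs=1e-6)

    def test_branch_ladder_nesting(self, sim_three_ratio, tmp_path):
        """Each more general model fits at least as well as its special
        case (shared branch lengths and kappa)."""
        spec, aln, _ = sim_three_ratio
        m0 = d.CodonModel(aln, spec.tree.copy())
        r0 = m0.fit(starts=(0.05,))
        tree = r0.tree
        lnls = {"M0": r0.lnL}
        for ctor in (BranchModelSpec.M2r, BranchModelSpec.M3r,
                     BranchModelSpec.M4r, BranchModelSpec.M5r,
                     BranchModelSpec.Mf):
            spec_m = ctor()
            res = d.CodonModel(aln, tree, spec=spec_m).fit(
                kappa=r0.kappa, starts=(0.05,)
            )
            lnls[spec_m.name] = res.lnL
        # true nestings of the ladder; the three- and four-ratio models
        # are NOT nested in each other (one equates the stems with their
        # crowns, the other equates the two stems), so both are compared
        # against their common special and general cases instead
        for null, alt in [("M0", "M2r"), ("M2r", "M3r"), ("M2r", "M4r"),
                          ("M3r", "M5r"), ("M4r", "M5r"), ("M0", "Mf")]:
            assert lnls[alt] >= lnls[null] - 1e-6

    def test_site_model_nesting(self, sim_small):
        spec, aln, _ = sim_small
        m0 = d.CodonModel(aln, spec.tree.copy())
        r0 = m0.fit(starts=(0.05,))
        tree = r0.tree
        lnls = {"M0": r0.lnL}
        for ctor in (SiteModelSpec.M1, SiteModelSpec.M2, SiteModelSpec.M3,
                     SiteModelSpec.M7, SiteModelSpec.M8):
            sm = ctor()
            res = d.CodonModel(aln, tree, spec=sm).fit(
                kappa=r0.kappa, starts=(0.5,)
            )
            lnls[sm.name] = res.lnL
        assert lnls["M2"] >= lnls["M1"] - 1e-6
        assert lnls["M3"] >= lnls["M0"] - 1e-6
        assert lnls["M8"] >= lnls["M7"] - 1e-6

    def test_branch_site_nesting_and_foreground_validation(self,
                                                           sim_small):
        spec, aln, _ = sim_small
        m0 = d.CodonModel(aln, spec.tree.copy())
        r0 = m0.fit(starts=(0.05,))
        tree = r0.tree
        r1 = d.CodonModel(aln, tree, spec=SiteModelSpec.M1()).fit(
            kappa=r0.kappa, starts=(0.05,)
        )
        rA = d.CodonModel(
            aln, tree, spec=SiteModelSpec.bsA(("stem_g1", "g1"))
        ).fit(kappa=r0.kappa, starts=(0.05,))
        assert rA.lnL >= r1.lnL - 1e-6
        with pytest.raises(ValueError, match="foreground"):
            d.CodonModel(aln, tree,
                         spec=SiteModelSpec.bsA(("nonexistent",)))


class TestSitePosteriors:
    def test_posteriors_sum_to_one_and_no_flags_without_positive_class(
        self, sim_small
    ):
        spec, aln, _ = sim_small
        r0 = d.CodonModel(aln, spec.tree.copy()).fit(starts=(0.05,))
        r1 = d.CodonModel(aln, r0.tree, spec=SiteModelSpec.M1()).fit(
            kappa=r0.kappa, starts=(0.05,)
        )
        post = r1.site_posteriors()
        assert post.method == "NEB"
        assert np.abs(post.posteriors.sum(axis=1) - 1.0).max() < 1e-12
        assert not post.positive_classes.any()
        assert post.flagged_sites == []

    def test_branch_model_has_no_site_posteriors(self, m0_fit_small):
        _, res = m0_fit_small
        with pytest.raises(ValueError):
            res.site_posteriors()
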