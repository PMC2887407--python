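"""NG86 counting, JC distances, sliding windows and NJ classification."""

import itertools
import math
import random

import numpy as np
import pytest

import dupsel as d
from dupsel.divergence import SaturationError, jc_correct, pairwise_table
from dupsel.genetics import STANDARD_CODE, CodonAlignment

SENSE = STANDARD_CODE.sense_codons


# --- independent oracle: straightforward recursive pathway enumeration ----


def oracle_sites(codon):
    aa = STANDARD_CODE.translate(codon)
    syn = 0.0
    for pos in range(3):
        changes = []
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            mut = codon[:pos] + nt + codon[pos + 1 :]
            if not STANDARD_CODE.is_stop(mut):
                changes.append(STANDARD_CODE.translate(mut) == aa)
        if changes:
            syn += sum(changes) / len(changes)
    return syn, 3.0 - syn


def oracle_pathways(a, b):
    """All orderings of the differing positions, skipping stop codons."""
    diffs = [k for k in range(3) if a[k] != b[k]]
    results = []

    def walk(cur, remaining, sd, nd):
        if not remaining:
            results.append((sd, nd))
            return
        for pos in remaining:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if STANDARD_CODE.is_stop(nxt):
                continue
            step_syn = STANDARD_CODE.translate(nxt) == STANDARD_CODE.translate(cur)
            walk(nxt, [p for p in remaining if p != pos],
                 sd + step_syn, nd + (not step_syn))

    walk(a, diffs, 0, 0)
    if not results:
        return None
    return (
        sum(r[0] for r in results) / len(results),
        sum(r[1] for r in results) / len(results),
    )


class TestNG86Sites:
    def test_phe_third_position(self):
        s, n = d.ng86_sites("TTT")
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(8 / 3)

    def test_trp_is_fully_nonsynonymous(self):
        s, n = d.ng86_sites("TGG")
        assert s == 0.0 and n == 3.0

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            d.ng86_sites("TAA")

    def test_sites_sum_to_three_for_every_sense_codon(self):
        for codon in SENSE:
            s, n = d.ng86_sites(codon)
            assert s + n == pytest.approx(3.0, abs=1e-12)

    def test_agrees_with_enumeration_oracle_on_all_codons(self):
        for codon in SENSE:
            assert d.ng86_sites(codon) == pytest.approx(oracle_sites(codon),
                                                        abs=1e-12)


class TestNG86Pair:
    def test_identical_sequences(self):
        s = "ATGTTTCCCAAAGGGTGCACT"
        p = d.ng86_pair(s, s)
        assert p.dN == 0.0 and p.dS == 0.0 and p.omega is None

    def test_single_synonymous_change(self):
        a = "ATGTTTCCCAAAGGGTGCACTGAACATCTA"
        b = a[:5] + "C" + a[6:]  # TTT -> TTC, synonymous
        p = d.ng86_pair(a, b)
        assert p.Nd == 0.0
        assert p.Sd == pytest.approx(1.0)
        assert p.dN == 0.0
        assert p.dS > 0

    def test_site_counts_total_three_per_codon(self):
        rng = random.Random(1)
        a = "".join(rng.choice(SENSE) for _ in range(40))
        b = "".join(rng.choice(SENSE) for _ in range(40))
        p = d.ng86_pair(a, b)
        assert p.S_sites + p.N_sites == pytest.approx(3 * p.n_codons,
                                                      abs=1e-9)

    def test_symmetry(self):
        rng = random.Random(2)
        for _ in range(5):
            a = "".join(rng.choice(SENSE) for _ in range(30))
            b = "".join(rng.choice(SENSE) for _ in range(30))
            pa = d.ng86_pair(a, b)
            pb = d.ng86_pair(b, a)
            assert pa.Sd == pytest.approx(pb.Sd)
            assert pa.Nd == pytest.approx(pb.Nd)
            assert pa.dN == pytest.approx(pb.dN, nan_ok=True)

    def test_agrees_with_pathway_oracle_on_random_codon_pairs(self):
        rng = random.Random(3)
        checked = 0
        while checked < 50:
            ca, cb = rng.choice(SENSE), rng.choice(SENSE)
            expect = oracle_pathways(ca, cb)
            if expect is None:
                continue
            # pad with an identical anchor codon so sites stay comparable
            p = d.ng86_pair("ATG" + ca, "ATG" + cb)
            assert p.Sd == pytest.approx(expect[0], abs=1e-12)
            assert p.Nd == pytest.approx(expect[1], abs=1e-12)
            checked += 1

    def test_gapped_codons_dropped_pairwise(self):
        a = "ATGTTT---"
        b = "ATGTTCAAA"
        p = d.ng86_pair(a, b)
        assert p.n_codons == 2

    def test_concatenation_adds_difference_counts(self):
        rng = random.Random(4)
        a1 = "".join(rng.choice(SENSE) for _ in range(20))
        b1 = "".join(rng.choice(SENSE) for _ in range(20))
        a2 = "".join(rng.choice(SENSE) for _ in range(15))
        b2 = "".join(rng.choice(SENSE) for _ in range(15))
        p1, p2 = d.ng86_pair(a1, b1), d.ng86_pair(a2, b2)
        p12 = d.ng86_pair(a1 + a2, b1 + b2)
        assert p12.Sd == pytest.approx(p1.Sd + p2.Sd, abs=1e-9)
        assert p12.Nd == pytest.approx(p1.Nd + p2.Nd, abs=1e-9)

    def test_neutral_simulation_recovers_omega_one(self):
        """NG86 omega on data generated with omega = 1, equal frequencies."""
        from dupsel.simulate import SimulationSpec
        from dupsel.trees import LabeledTree, TreeNode

        pi = np.full(61, 1 / 61)
        omegas = []
        for rep in range(100):
            tree = LabeledTree(
                TreeNode(children=[TreeNode(name="a", length=0.15),
                                   TreeNode(name="b", length=0.15)])
            )
            spec = SimulationSpec(tree=tree, kappa=1.0, pi=pi,
                                  omega_by_class={"0": 1.0},
                                  n_codons=10_000, seed=100 + rep)
            aln, _ = d.simulate(spec)
            p = d.ng86_pair(aln.sequences[0], aln.sequences[1])
            omegas.append(p.omega)
        assert 0.9 <= float(np.mean(omegas)) <= 1.1


class TestJCDistance:
    def test_zero_for_identical(self):
        assert d.jc_distance("ACGTAC", "ACGTAC") == 0.0

    def test_closed_form_at_p_ten_percent(self):
        assert jc_correct(0.1) == pytest.approx(0.10732, abs=1e-5)

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            jc_correct(0.8)

    def test_symmetric_and_gap_aware(self):
        a, b = "ACGT-CGGNA", "ACTTACGGTA"
        assert d.jc_distance(a, b) == d.jc_distance(b, a)
        # 8 comparable sites (positions with '-' or 'N' dropped), 1 mismatch
        p = 1 / 8
        assert d.jc_distance(a, b) == pytest.approx(jc_correct(p))


class TestSlidingWindow:
    def test_identical_sequences_flat_zero(self):
        s = "ATGTTTCCCAAAGGGTGCACTGAACATCTAATGTTTCCC"[:36]
        aln = CodonAlignment(names=["a", "b"], sequences=[s, s])
        prof = d.sliding_window(aln, [("a", "b")], 12, 6)
        assert all(k == 0 for k in prof.K_series)
        assert all(dn == 0 for dn in prof.dN_series)
        # dS = 0 everywhere: ratio must be missing, never zero
        assert all(math.isnan(r) for r in prof.ratio_series)

    def test_window_count_matches_closed_form(self, sim_small):
        _, aln, _ = sim_small
        # 318-nt window geometry: floor((L - w)/s) + 1 windows
        sub = aln.window(0, 318)
        prof = d.sliding_window(sub, [(aln.names[0], aln.names[1])], 30, 9)
        assert len(prof.starts) == (318 - 30) // 9 + 1 == 33
        assert prof.starts[0] == 0 and prof.starts[-1] == 288

    def test_divergent_block_elevates_only_overlapping_windows(self):
        rng = random.Random(7)
        base = "".join(rng.choice(SENSE) for _ in range(60))
        # perturb half the codons in nt block [60, 90)
        mutated = list(base)
        for c in range(20, 30, 2):
            mutated[3 * c : 3 * c + 3] = rng.choice(SENSE)
        b = "".join(mutated)
        aln = CodonAlignment(names=["a", "b"], sequences=[base, b])
        prof = d.sliding_window(aln, [("a", "b")], 12, 6)
        inside = [k for s, k in zip(prof.starts, prof.K_series)
                  if 60 <= s and s + 12 <= 90]
        outside = [k for s, k in zip(prof.starts, prof.K_series)
                   if s + 12 <= 60 or s >= 90]
        assert inside and outside
        assert min(inside) > max(outside)

    def test_empty_pair_set_rejected(self, tiny_aln):
        with pytest.raises(ValueError):
            d.sliding_window(tiny_aln, [], 6, 3)


class TestMeanDivergence:
    @pytest.mark.parametrize(
        "dn,ds,expected",
        [(0.033, 0.155, 0.213), (0.011, 0.131, 0.084)],
    )
    def test_overall_omega_from_printed_means(self, dn, ds, expected):
        """The ratio of mean dN to mean dS reproduces reported overall
        omega values for the two paralog groups."""
        assert dn / ds == pytest.approx(expected, abs=5e-4)

    def test_identical_pair_undefined_omega(self):
        s = "ATGTTTCCCAAAGGG"
        aln = CodonAlignment(names=["a", "b"], sequences=[s, s])
        g = d.mean_divergence(aln, ["a", "b"])
        assert g.mean_dN == 0 and g.mean_dS == 0
        assert g.overall_omega is None

    def test_group_mean_is_pair_average(self, sim_small):
        _, aln, _ = sim_small
        g1 = [n for n in aln.names if n.startswith("g1")][:4]
        g = d.mean_divergence(aln, g1)
        pairs = pairwise_table(aln.subset(g1))
        assert g.mean_dN == pytest.approx(
            np.mean([p.dN for _, _, p in pairs])
        )
        assert g.mean_dS == pytest.approx(
            np.mean([p.dS for _, _, p in pairs])
        )


class TestNJClassify:
    def test_simulated_paralogs_classified_perfectly(self, sim_three_ratio):
        _, aln, _ = sim_three_ratio
        g1 = [n for n in aln.names if n.startswith("g1")]
        g5 = [n for n in aln.names if n.startswith("g5")]
        refs = {g1[0]: "gamma1", g1[1]: "gamma1",
                g5[0]: "gamma5", g5[1]: "gamma5"}
        queries = g1[2:] + g5[2:]
        got = d.nj_classify(aln, refs, queries)
        for q in queries:
            expected = "gamma1" if q.startswith("g1") else "gamma5"
            assert got[q] == expected

    def test_query_identical_to_reference(self, sim_three_ratio):
        _, aln, _ = sim_three_ratio
        g1 = [n for n in aln.names if n.startswith("g1")]
        g5 = [n for n in aln.names if n.startswith("g5")]
        dup = CodonAlignment(
            names=aln.names + ["query"],
            sequences=aln.sequences + [aln.sequence(g1[0])],
        )
        refs = {g1[0]: "one", g1[1]: "one", g5[0]: "five", g5[1]: "five"}
        assert d.nj_classify(dup, refs, ["query"])["query"] == "one"

    def test_swapping_labels_swaps_assignments(self, sim_three_ratio):
        _, aln, _ = sim_three_ratio
        g1 = [n for n in aln.names if n.startswith("g1")]
        g5 = [n for n in aln.names if n.startswith("g5")]
        refs = {g1[0]: "X", g1[1]: "X", g5[0]: "Y", g5[1]: "Y"}
        swapped = {k: ("Y" if v == "X" else "X") for k, v in refs.items()}
        queries = [g1[2], g5[2]]
        a = d.nj_classify(aln, refs, queries)
        b = d.nj_classify(aln, swapped, queries)
        for q in queries:
            assert {a[q], b[q]} == {"X", "Y"}

    def test_low_overlap_query_excluded(self, sim_three_ratio):
        _, aln, _ = sim_three_ratio
        g1 = [n for n in aln.names if n.startswith("g1")]
        g5 = [n for n in aln.names if n.startswith("g5")]
        gap = "-" * (aln.length_nt - 3) + aln.sequence(g1[0])[-3:]
        dup = CodonAlignment(names=aln.names + ["stub"],
                             sequences=aln.sequences + [gap])
        refs = {g1[0]: "one", g1[1]: "one", g5[0]: "five", g5[1]: "five"}
        with pytest.warns(UserWarning, match="overlap"):
            got = d.nj_classify(dup, refs, ["stub"])
        assert got["stub"] == "excluded"
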