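"""Codon-model machinery: rate matrix, pruning likelihood against
enumeration, model fitting and the counting-based dN/dS."""

import numpy as np
import pytest
from scipy.linalg import expm

from selconv import io_formats as io
from selconv import phylo_selection as ph
from selconv import synthetic_data as sd


UNIFORM = np.full(ph.N_CODONS, 1.0 / ph.N_CODONS)


class TestRateMatrix:
    def test_neutral_uniform_entries_equal(self):
        q = ph.gy94_rate_matrix(UNIFORM, kappa=1.0, omega=1.0, scale=False)
        vals = q[ph.SINGLE_STEP]
        assert np.allclose(vals, vals[0])

    def test_omega_zero_kills_nonsynonymous(self):
        q = ph.gy94_rate_matrix(UNIFORM, kappa=2.0, omega=0.0)
        assert np.all(q[ph.IS_NONSYN] == 0.0)
        assert np.any(q[ph.SINGLE_STEP & ~ph.IS_NONSYN] > 0.0)

    def test_rows_sum_to_zero_and_unit_mean_rate(self):
        pi = ph.f1x4_frequencies([0.3, 0.2, 0.3, 0.2])
        q = ph.gy94_rate_matrix(pi, kappa=3.0, omega=0.4)
        assert np.allclose(q.sum(axis=1), 0.0, atol=1e-12)
        assert np.isclose(-(pi * np.diag(q)).sum(), 1.0)

    def test_pmat_matches_series_expansion(self):
        pi = ph.f1x4_frequencies([0.3, 0.2, 0.3, 0.2])
        model = ph.CodonModel(pi)
        q = ph.gy94_rate_matrix(pi, kappa=2.0, omega=0.3)
        p_spec = model.pmat(0.05, 2.0, 0.3)
        # independent scaled Taylor-series oracle
        p_series = np.eye(ph.N_CODONS)
        term = np.eye(ph.N_CODONS)
        for k in range(1, 30):
            term = term @ (q * 0.05) / k
            p_series = p_series + term
        assert np.abs(p_spec - p_series).max() < 1e-8
        assert np.abs(p_spec - expm(q * 0.05)).max() < 1e-10

    def test_pmat_rows_are_distributions(self):
        model = ph.CodonModel(UNIFORM)
        p = model.pmat(0.3, 2.0, 0.5)
        assert np.all(p >= 0)
        assert np.allclose(p.sum(axis=1), 1.0)


class TestLogLikelihood:
    def test_identical_sequences_zero_lengths_closed_form(self):
        tree = io.parse_tree("(A:0.0,B:0.0);")
        aln = io.Alignment(ids=["A", "B"], seqs=["ATG", "ATG"], kind="codon")
        pi = ph.f1x4_frequencies([0.25] * 4)
        lnl = ph.log_likelihood(tree, aln, kappa=2.0, omega=0.5,
                                codon_freqs=pi)
        expected = np.log(pi[ph.CODON_INDEX["ATG"]])
        assert np.isclose(lnl, expected, atol=1e-10)

    def test_root_invariance(self):
        # same unrooted tree, two rootings: reversibility makes lnL equal
        t1 = io.parse_tree("((A:0.1,B:0.2):0.05,C:0.25);")
        t2 = io.parse_tree("((A:0.1,B:0.2):0.02,C:0.28);")
        aln = io.Alignment(ids=["A", "B", "C"],
                           seqs=["ATGAAATTT", "ATGAAGTTC", "ATGCAATTT"],
                           kind="codon")
        pi = ph.f1x4_frequencies([0.25] * 4)
        l1 = ph.log_likelihood(t1, aln, 2.0, 0.4, codon_freqs=pi)
        l2 = ph.log_likelihood(t2, aln, 2.0, 0.4, codon_freqs=pi)
        assert np.isclose(l1, l2, atol=1e-9)

    def test_leaf_order_invariance(self):
        tree = io.parse_tree("((A:0.1,B:0.2):0.05,C:0.25);")
        aln1 = io.Alignment(ids=["A", "B", "C"],
                            seqs=["ATGAAA", "ATGAAG", "ATGCAA"], kind="codon")
        aln2 = io.Alignment(ids=["C", "A", "B"],
                            seqs=["ATGCAA", "ATGAAA", "ATGAAG"], kind="codon")
        pi = ph.f1x4_frequencies([0.25] * 4)
        assert np.isclose(ph.log_likelihood(tree, aln1, 2.0, 0.4, codon_freqs=pi),
                          ph.log_likelihood(tree, aln2, 2.0, 0.4, codon_freqs=pi))

    def test_three_taxon_enumeration_oracle(self):
        """Pruning equals brute-force summation over all 61^2 internal-state
        combinations on a 3-taxon, 2-codon alignment."""
        tree = io.parse_tree("((A:0.1,B:0.15):0.07,C:0.2);")
        aln = io.Alignment(ids=["A", "B", "C"],
                           seqs=["ATGAAA", "ACGAAG", "ATGCAT"], kind="codon")
        pi = ph.f1x4_frequencies([0.3, 0.2, 0.3, 0.2])
        kappa, omega = 2.0, 0.4
        model = ph.CodonModel(pi)
        pa = model.pmat(0.1, kappa, omega)
        pb = model.pmat(0.15, kappa, omega)
        pn = model.pmat(0.07, kappa, omega)
        pc = model.pmat(0.2, kappa, omega)
        states = ph.encode_codon_alignment(aln)
        lnl_oracle = 0.0
        for k in range(2):
            sa, sb, sc = states[0, k], states[1, k], states[2, k]
            total = 0.0
            for root in range(ph.N_CODONS):
                for mid in range(ph.N_CODONS):
                    total += (pi[root] * pc[root, sc] * pn[root, mid]
                              * pa[mid, sa] * pb[mid, sb])
            lnl_oracle += np.log(total)
        lnl = ph.log_likelihood(tree, aln, kappa, omega, codon_freqs=pi)
        assert np.isclose(lnl, lnl_oracle, atol=1e-8)

    def test_incomplete_columns_dropped(self, six_taxon_tree):
        alns, _ = sd.simulate_codon_data(six_taxon_tree, 1, 10, seed=0)
        aln = alns["gene0001"]
        aln.seqs[0] = "---" + aln.seqs[0][3:]
        _, patterns, weights, dropped = ph.prepare_patterns(six_taxon_tree, aln)
        assert dropped == 1
        assert weights.sum() == 9


class TestFitModel:
    def test_one_ratio_recovery(self, six_taxon_tree):
        alns, _ = sd.simulate_codon_data(six_taxon_tree, 1, 2000,
                                         kappa=2.0, base_omega=0.2, seed=7)
        fit = ph.fit_model(six_taxon_tree, alns["gene0001"], "one_ratio")
        assert 0.15 <= fit.params["omega"] <= 0.25
        assert 1.5 <= fit.kappa <= 2.5

    def test_two_ratio_nests_one_ratio(self, six_taxon_tree):
        alns, _ = sd.simulate_codon_data(six_taxon_tree, 1, 300, seed=8)
        aln = alns["gene0001"]
        one = ph.fit_model(six_taxon_tree, aln, "one_ratio")
        fg = six_taxon_tree.branch_for("A")
        two = ph.fit_model(six_taxon_tree, aln, "two_ratio", foreground=fg)
        assert two.lnL >= one.lnL - 1e-4

    def test_branch_site_alt_nests_null(self, six_taxon_tree):
        alns, _ = sd.simulate_codon_data(six_taxon_tree, 1, 200, seed=9)
        aln = alns["gene0001"]
        fg = six_taxon_tree.branch_for("A")
        null = ph.fit_model(six_taxon_tree, aln, "branch_site_null",
                            foreground=fg)
        # the alternative is seeded from the null optimum, as in the LRT
        alt = ph.fit_model(six_taxon_tree, aln, "branch_site_alt",
                           foreground=fg,
                           init={**null.params, "kappa": null.kappa,
                                 "omega2": 2.0})
        assert alt.lnL >= null.lnL - 1e-3
        p = alt.params
        assert 0 <= p["p0"] <= 1 and 0 <= p["p1"] <= 1
        assert p["p0"] + p["p1"] <= 1 + 1e-9
        assert 0 < p["omega0"] < 1 and p["omega2"] >= 1.0

    def test_free_ratio_star_recovery(self):
        tree = io.parse_tree("(A:0.25,B:0.25,C:0.25);")
        alns, _ = sd.simulate_codon_data(tree, 1, 3000, base_omega=0.5,
                                         seed=10)
        fit = ph.fit_model(tree, alns["gene0001"], "free_ratio")
        for v, om in fit.params["omega_by_branch"].items():
            assert 0.5 * 0.7 <= om <= 0.5 * 1.3

    def test_unknown_model_rejected(self, six_taxon_tree):
        alns, _ = sd.simulate_codon_data(six_taxon_tree, 1, 30, seed=1)
        with pytest.raises(io.ConfigError):
            ph.fit_model(six_taxon_tree, alns["gene0001"], "site_model_m8")


class TestLRT:
    def test_statistic_zero_when_constrained_equal(self):
        stat, p = ph._lrt(-100.0, -100.0, 1)
        assert stat == 0.0 and p == 1.0

    def test_negative_statistic_clamped(self):
        stat, p = ph._lrt(-100.0, -100.0001, 1)
        assert stat == 0.0 and p == 1.0

    def test_branch_test_verdict_requires_elevation(self, six_taxon_tree):
        """A foreground omega *drop* must not be called rapidly evolving,
        however significant the rate difference."""
        fg = six_taxon_tree.branch_for("A")
        alns, _ = sd.simulate_codon_data(
            six_taxon_tree, 1, 1500, base_omega=0.8,
            foreground_branches=(fg,), foreground_omega=0.05, seed=11)
        r = ph.branch_model_test("g", six_taxon_tree, alns["gene0001"], fg)
        assert not r.elevated
        assert not r.verdict
        assert r.p_value < 0.05  # the difference itself is detectable

    def test_branch_test_detects_planted_shift(self, six_taxon_tree):
        fg = six_taxon_tree.branch_for("A")
        alns, _ = sd.simulate_codon_data(
            six_taxon_tree, 1, 1500, base_omega=0.2,
            foreground_branches=(fg,), foreground_omega=0.8, seed=12)
        r = ph.branch_model_test("g", six_taxon_tree, alns["gene0001"], fg)
        assert r.verdict and r.elevated
        assert r.foreground_omega_hat > r.background_omega_hat

    def test_q_values_monotone_in_p(self, six_taxon_tree):
        fg = six_taxon_tree.branch_for("A")
        alns, _ = sd.simulate_codon_data(six_taxon_tree, 6, 100, seed=13)
        results = [ph.branch_model_test(g, six_taxon_tree, a, fg)
                   for g, a in alns.items()]
        ph.attach_q_values(results)
        ordered = sorted(results, key=lambda r: r.p_value)
        qs = [r.q_value for r in ordered]
        assert all(q2 >= q1 - 1e-12 for q1, q2 in zip(qs, qs[1:]))
        assert all(r.q_value >= r.p_value - 1e-12 for r in results)


class TestCountingOmega:
    def test_identical_endpoints_flagged(self, quartet_tree):
        alns, truth = sd.simulate_codon_data(quartet_tree, 1, 50, seed=14)
        states = truth.node_states["gene0001"]
        frozen = np.tile(states[quartet_tree.root], (quartet_tree.n_nodes, 1))
        aln = io.Alignment(
            ids=[quartet_tree.names[v] for v in quartet_tree.leaves],
            seqs=["".join(ph.CODONS[c] for c in frozen[0])] * 4, kind="codon")
        res = ph.counting_omega_per_branch(quartet_tree, aln, frozen)
        for v, row in res.items():
            assert row["undefined"]
            assert row["n_syn_subs"] == 0 and row["n_nonsyn_subs"] == 0

    def test_single_synonymous_change(self):
        tree = io.parse_tree("(A:0.1,B:0.1);")
        # CTT -> CTC is synonymous (Leu)
        aln = io.Alignment(ids=["A", "B"], seqs=["CTTAAA", "CTCAAA"],
                           kind="codon")
        anc = np.full((3, 2), -1, dtype=int)
        anc[2] = [ph.CODON_INDEX["CTT"], ph.CODON_INDEX["AAA"]]
        res = ph.counting_omega_per_branch(tree, aln, anc)
        b_branch = tree.leaf_index("B")
        assert res[b_branch]["n_syn_subs"] == 1
        assert res[b_branch]["n_nonsyn_subs"] == 0
        assert res[b_branch]["omega"] == 0.0

    def test_counting_concordant_with_likelihood(self, six_taxon_tree):
        """Counting on the true ancestral states agrees with the ML
        one-ratio estimate within 20% at 2000 codons."""
        alns, truth = sd.simulate_codon_data(six_taxon_tree, 1, 2000,
                                             base_omega=0.5, seed=15)
        fit = ph.fit_model(six_taxon_tree, alns["gene0001"], "one_ratio")
        res = ph.counting_omega_per_branch(
            six_taxon_tree, alns["gene0001"], truth.node_states["gene0001"])
        total_n = sum(r["n_nonsyn_subs"] for r in res.values())
        total_s = sum(r["n_syn_subs"] for r in res.values())
        n_sites = s_sites = 0.0
        for c in truth.node_states["gene0001"][six_taxon_tree.root]:
            s, n = ph._ng86_site_counts(int(c))
            s_sites += s
            n_sites += n
        omega_count = (total_n / n_sites) / (total_s / s_sites)
        assert abs(omega_count - fit.params["omega"]) \
            <= 0.2 * fit.params["omega"]
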