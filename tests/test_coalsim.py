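"""Coalescent simulator, HKY sequence model, and summary statistics.

Distributional checks run at reduced replicate counts here; the
full-scale calibration lives in the acceptance suite.
"""

import numpy as np
import pytest
from scipy.stats import chisquare, ks_2samp

from postglacial.coalsim import (
    Genealogy,
    MutationModel,
    SimulationError,
    simulate_dataset,
    simulate_genealogy,
    simulate_sequences,
    summarize,
)
from postglacial.scenarios import (
    DemographicEvent,
    DemographicScenario,
    PopulationSpec,
    Prior,
    sample_parameters,
)

from conftest import single_population


def draw_for(scenario, rng):
    return sample_parameters(scenario, rng)


def divergence_scenario(t, ne=1000, n=5, ancient_age=0):
    return DemographicScenario(
        id="div",
        populations=[
            PopulationSpec("A", Prior.of(ne), n),
            PopulationSpec("B", Prior.of(ne), n, sampling_age=ancient_age),
        ],
        events=[DemographicEvent("divergence", "split", ("B", "A"), time=Prior.of(t))],
    )


class TestGenealogy:
    def test_mean_t2_matches_haploid_expectation(self, rng):
        sc = single_population(1000, 2)
        t = np.array(
            [simulate_genealogy(sc, draw_for(sc, rng), rng).tmrca for _ in range(4000)]
        )
        se = t.std() / np.sqrt(t.size)
        assert abs(t.mean() - 1000) < 3 * se

    def test_cross_population_coalescence_after_divergence(self, rng):
        sc = divergence_scenario(500.0, n=3)
        for _ in range(200):
            g = simulate_genealogy(sc, draw_for(sc, rng), rng)
            for i in range(3):
                for j in range(3, 6):
                    assert g.pairwise_tmrca(i, j) >= 500.0

    def test_serial_lineage_never_coalesces_before_its_age(self, rng):
        sc = divergence_scenario((600, 1600), n=3, ancient_age=502)
        for _ in range(300):
            g = simulate_genealogy(sc, draw_for(sc, rng), rng)
            ancient = [i for i, a in enumerate(g.leaf_ages) if a == 502]
            for i in ancient:
                assert g.time[g.parent[i]] >= 502.0

    def test_matches_wright_fisher_oracle(self, rng):
        # discrete-generation WF oracle at N=100, n=6
        N, n, reps = 100, 6, 2000
        sc = single_population(N, n)
        sim = np.array(
            [simulate_genealogy(sc, draw_for(sc, rng), rng).tmrca for _ in range(reps)]
        )
        wf = np.empty(reps)
        for r in range(reps):
            k, t = n, 0
            while k > 1:
                k = len(np.unique(rng.integers(0, N, size=k)))
                t += 1
            wf[r] = t
        assert ks_2samp(sim, wf).pvalue > 0.01

    def test_matches_msprime_oracle(self, rng):
        msprime = pytest.importorskip("msprime")
        N, n, reps = 1000, 8, 1500
        sc = single_population(N, n)
        ours = np.array(
            [simulate_genealogy(sc, draw_for(sc, rng), rng).tmrca for _ in range(reps)]
        )
        ts_iter = msprime.sim_ancestry(
            # n/2 diploids = n haploid lineages; diploid size N/2 = haploid N
            samples=n // 2, population_size=N / 2, ploidy=2,
            num_replicates=reps, random_seed=99,
        )
        theirs = np.array([next(t.trees()).time(t.first().root) for t in ts_iter])
        assert ks_2samp(ours, theirs).pvalue > 0.01

    def test_admixture_moves_lineages(self, rng):
        # r=1 admixture at t=10 moves every recipient lineage to the donor;
        # with the donor merging into the recipient's ORIGINAL pop much later,
        # coalescence before the divergence proves the lineages moved
        sc = DemographicScenario(
            id="adm",
            populations=[
                PopulationSpec("A", Prior.of(100), 3),
                PopulationSpec("B", Prior.of(100), 3),
            ],
            events=[
                DemographicEvent("admixture", "pulse", ("B", "A"),
                                 time=Prior.of(10.0), rate=Prior.of(1.0)),
                DemographicEvent("divergence", "split", ("B", "A"),
                                 time=Prior.of(100_000.0)),
            ],
        )
        g = simulate_genealogy(sc, draw_for(sc, rng), rng)
        assert g.tmrca < 100_000.0

    def test_bottleneck_accelerates_coalescence(self, rng):
        def scenario(with_bn):
            events = [DemographicEvent("divergence", "split", ("B", "A"),
                                       time=Prior.of(1000.0))]
            if with_bn:
                events.append(DemographicEvent("bottleneck", "bn", ("B",),
                                               nb=Prior.of(5.0),
                                               duration=Prior.of(200.0)))
            return DemographicScenario(
                id=f"bn{with_bn}",
                populations=[
                    PopulationSpec("A", Prior.of(10_000), 2),
                    PopulationSpec("B", Prior.of(10_000), 4),
                ],
                events=events,
            )

        reps = 400
        with_bn = np.array([
            simulate_genealogy(scenario(True), draw_for(scenario(True), rng), rng).tmrca
            for _ in range(reps)
        ])
        without = np.array([
            simulate_genealogy(scenario(False), draw_for(scenario(False), rng), rng).tmrca
            for _ in range(reps)
        ])
        assert with_bn.mean() < without.mean()

    def test_never_coalescing_scenario_guarded(self, rng):
        sc = DemographicScenario(
            id="forest",
            populations=[PopulationSpec("A", Prior.of(100), 2),
                         PopulationSpec("B", Prior.of(100), 2)],
            events=[],  # no divergence: B and A never merge
        )
        with pytest.raises(SimulationError, match="never coalesces"):
            simulate_genealogy(sc, draw_for(sc, rng), rng)

    def test_newick_export_parses(self, rng):
        sc = single_population(100, 4)
        g = simulate_genealogy(sc, draw_for(sc, rng), rng)
        from io import StringIO

        from Bio import Phylo

        tree = Phylo.read(StringIO(g.to_newick()), "newick")
        assert tree.count_terminals() == 4


class TestSequences:
    def _two_leaf_tree(self, t):
        return Genealogy(
            parent=np.array([2, 2, -1]),
            time=np.array([0.0, 0.0, t]),
            leaf_pops=["A", "A"],
            leaf_ages=np.zeros(2),
        )

    def test_mu_zero_monomorphic(self, rng):
        sc = single_population(1000, 6)
        g = simulate_genealogy(sc, draw_for(sc, rng), rng)
        aln = simulate_sequences(g, MutationModel(mu=0.0), 50, rng)
        assert np.all(aln.seqs == aln.seqs[0])

    def test_long_branch_converges_to_stationary_frequencies(self, rng):
        pi = (0.4, 0.3, 0.2, 0.1)
        model = MutationModel(mu=1.0, kappa=5.0, pi=pi)
        g = self._two_leaf_tree(50.0)  # mu*t >> 1
        aln = simulate_sequences(g, model, 20_000, rng)
        counts = np.bincount(aln.seqs[0], minlength=4)
        assert chisquare(counts, 20_000 * np.array(pi)).pvalue > 0.01

    def test_low_theta_segregating_sites_match_poisson_expectation(self, rng):
        # expected mutations = mu * L * total tree length * (1 - p_inv);
        # multiple hits negligible at this theta
        mu, L, p_inv = 1e-6, 500, 0.4
        model = MutationModel(mu=mu, kappa=3.0, alpha=1.0, p_inv=p_inv)
        sc = single_population(200, 6)
        total_exp = 0.0
        total_S = 0
        for _ in range(400):
            g = simulate_genealogy(sc, draw_for(sc, rng), rng)
            total_exp += mu * L * g.total_branch_length * (1 - p_inv)
            aln = simulate_sequences(g, model, L, rng)
            total_S += int(((aln.seqs != aln.seqs[0]).any(axis=0)).sum())
        # Poisson-count oracle: 3-sigma band
        assert abs(total_S - total_exp) < 3 * np.sqrt(total_exp)

    def test_equal_rates_when_alpha_infinite(self, rng):
        model = MutationModel(mu=1e-5, alpha=np.inf, p_inv=0.0)
        rates = model.site_rates(1000, rng)
        assert np.all(rates == 1.0)

    def test_transition_bias(self, rng):
        # high kappa: transitions (A<->G) dominate over transversions
        model = MutationModel(mu=0.02, kappa=50.0)
        g = self._two_leaf_tree(1.0)
        aln = simulate_sequences(g, model, 50_000, rng)
        a, b = aln.seqs
        changed = a != b
        transitions = changed & (((a == 0) & (b == 2)) | ((a == 2) & (b == 0))
                                 | ((a == 1) & (b == 3)) | ((a == 3) & (b == 1)))
        assert transitions.sum() > 5 * (changed.sum() - transitions.sum())


class TestSummarize:
    def test_worked_four_sequence_example(self, worked_alignment):
        sv = summarize(worked_alignment)
        d = dict(zip(sv.names, sv.values))
        # exhaustive pair enumeration: s0-s1: 1, s0-s2: 1, s0-s3: 3,
        # s1-s2: 2, s1-s3: 2, s2-s3: 2
        # within P1: {1}; within P2: {2}; between: 1,3,2,2
        assert d["pi_P1"] == 1.0
        assert d["pi_P2"] == 2.0
        assert d["dxy_P1_P2"] == pytest.approx((1 + 3 + 2 + 2) / 4)
        assert d["S_P1"] == 1.0  # only site 8 varies within P1
        assert d["S_P2"] == 2.0  # sites 1 and 8 vary within P2
        assert d["fst_P1_P2"] == pytest.approx(1 - 0.5 * (1 + 2) / 2.0)

    def test_monomorphic_two_populations_masked(self):
        from conftest import alignment_from_strings

        aln = alignment_from_strings(["ACGT"] * 4, pops=["P1", "P1", "P2", "P2"])
        sv = summarize(aln)
        d = dict(zip(sv.names, sv.values))
        m = dict(zip(sv.names, sv.mask))
        assert d["pi_P1"] == 0.0 and d["fst_P1_P2"] == 0.0
        assert m["fst_P1_P2"] == 1.0  # masked, encoded as 0 + mask bit
        assert m["tajD_P1"] == 1.0

    def test_identical_alignment_identical_vector(self, worked_alignment):
        a = summarize(worked_alignment)
        b = summarize(worked_alignment)
        assert a.names == b.names
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.mask, b.mask)

    def test_fst_increases_with_divergence_depth(self, rng):
        def mean_fst(t, reps=150):
            sc = divergence_scenario(float(t), ne=1000, n=6)
            out = []
            for _ in range(reps):
                d = draw_for(sc, rng)
                aln = simulate_dataset(sc, d, 200, rng,
                                       mutation=MutationModel(mu=2e-5))
                sv = summarize(aln)
                out.append(dict(zip(sv.names, sv.values))["fst_A_B"])
            return np.mean(out)

        assert mean_fst(10_000) > mean_fst(100)

    def test_tajimas_d_reference_value(self):
        # spot-check the statistic against dendropy's implementation
        dendropy = pytest.importorskip("dendropy")
        from dendropy.calculate import popgenstat

        seqs = ["ACGTACGTAA", "ACGTACGTAT", "ACCTACGAAA", "ACGTACCTAA"]
        mat = dendropy.DnaCharacterMatrix.from_dict(
            {f"t{i}": s for i, s in enumerate(seqs)}
        )
        expected = popgenstat.tajimas_d(mat)
        from conftest import alignment_from_strings

        sv = summarize(alignment_from_strings(seqs))
        got = dict(zip(sv.names, sv.values))["tajD_P"]
        assert got == pytest.approx(expected, abs=1e-9)
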