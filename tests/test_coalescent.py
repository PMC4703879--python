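"""Coalescent engine: closed forms, folding, haplotype path, msprime oracle."""

import math

import numpy as np
import pytest

from yakpop._kernel import branch_length_matrix
from yakpop.coalescent import (
    DemographicModel,
    JointSFS,
    LocusResult,
    SampleConfig,
    SizeEpoch,
    domestication_scenario,
    expected_sfs,
    joint_sfs,
    mutation_rate_from_divergence,
    sample_sfs,
    simulate_locus,
    years_to_generations,
)


def single_pop_model(n=10_000):
    return DemographicModel(
        wild_epochs=(SizeEpoch(0, n),),
        dom_epochs=(SizeEpoch(0, n),),
        t_div=1e-9,
        n_anc=n,
    )


class TestConversions:
    def test_years_to_generations(self):
        assert years_to_generations(7_300) == pytest.approx(2433.3333333)
        assert years_to_generations(0) == 0.0
        assert years_to_generations(2 * 7_300) == 2 * years_to_generations(7_300)

    def test_mutation_rate_formula(self):
        assert mutation_rate_from_divergence(0.0, 3, 4.7e6) == 0.0
        mu1 = mutation_rate_from_divergence(0.01, 3, 4.7e6)
        assert mutation_rate_from_divergence(0.02, 3, 4.7e6) == pytest.approx(2 * mu1)
        # the study's printed value: D*g/(2T) with g=3 yr, T=4.7 Myr
        assert mutation_rate_from_divergence(0.0183, 3, 4.7e6) == pytest.approx(
            5.84e-9, abs=5e-12
        )


class TestModelValidation:
    def test_epoch_ordering_enforced(self):
        with pytest.raises(ValueError, match="strictly increase"):
            DemographicModel(
                wild_epochs=(SizeEpoch(0, 100), SizeEpoch(0, 200)),
                dom_epochs=(SizeEpoch(0, 100),),
                t_div=10,
                n_anc=100,
            )

    def test_positive_sizes_required(self):
        with pytest.raises(ValueError, match="positive"):
            DemographicModel(
                wild_epochs=(SizeEpoch(0, -5),),
                dom_epochs=(SizeEpoch(0, 100),),
                t_div=10,
                n_anc=100,
            )

    def test_scenario_factory_converts_years(self):
        m = domestication_scenario()
        assert m.t_div == pytest.approx(7300 / 3)
        assert m.dom_epochs[1].start == pytest.approx(3600 / 3)
        assert m.wild_epochs[1].start == pytest.approx(500 / 3)
        assert m.n_anc == 21_200

    def test_runaway_event_count_errors(self):
        # enormous sizes with frantic migration: the event budget trips
        # before any realistic coalescence can happen
        model = DemographicModel(
            wild_epochs=(SizeEpoch(0, 1e12),),
            dom_epochs=(SizeEpoch(0, 1e12),),
            t_div=1e17,
            n_anc=1e12,
            m_wd=1e3,
            m_dw=1e3,
        )
        with pytest.raises(RuntimeError, match="event budget"):
            branch_length_matrix(1, 5, 2, 2, model.to_kernel_arrays())


_N_CONST = 10_000
_N_TREES = 8_000


@pytest.fixture(scope="module")
def lengths():
    return branch_length_matrix(
        42, _N_TREES, 10, 0, single_pop_model(_N_CONST).to_kernel_arrays()
    )


class TestKernelClosedForms:
    N = _N_CONST
    N_TREES = _N_TREES

    def test_total_length_matches_harmonic_expectation(self, lengths):
        a1 = sum(1.0 / i for i in range(1, 10))
        expected = 4 * self.N * a1
        # Var(T_total) = (4N)^2 * sum 1/i^2 per tree
        sd = 4 * self.N * math.sqrt(sum(1.0 / i**2 for i in range(1, 10)))
        se = sd / math.sqrt(self.N_TREES)
        assert abs(lengths.sum() / self.N_TREES - expected) < 3 * se

    def test_unfolded_marginal_proportional_to_one_over_i(self, lengths):
        marginal = lengths.sum(axis=1)[1:10] / self.N_TREES
        expected = 4 * self.N / np.arange(1, 10)
        assert np.all(np.abs(marginal / expected - 1) < 0.05)

    def test_seeded_runs_bit_reproducible(self):
        arrays = single_pop_model(1000).to_kernel_arrays()
        a = branch_length_matrix(7, 200, 4, 4, arrays)
        b = branch_length_matrix(7, 200, 4, 4, arrays)
        c = branch_length_matrix(8, 200, 4, 4, arrays)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_complete_lineage_sorting_gives_fst_near_one(self):
        model = DemographicModel(
            wild_epochs=(SizeEpoch(0, 1000),),
            dom_epochs=(SizeEpoch(0, 1000),),
            t_div=200_000,  # 100 x 2N: complete sorting
            n_anc=1000,
        )
        sfs = sample_sfs(model, SampleConfig(6, 6), 400, 1000, 1e-7, seed=9, folded=False)
        i = np.arange(7)[:, None] / 6
        j = np.arange(7)[None, :] / 6
        num = (i - j) ** 2 - i * (1 - i) / 5 - j * (1 - j) / 5
        den = i * (1 - j) + j * (1 - i)
        mask = sfs.polymorphic_mask()
        fst = (num * sfs.matrix)[mask].sum() / (den * sfs.matrix)[mask].sum()
        assert fst > 0.95


class TestJointSFS:
    def test_single_wild_singleton_cell(self):
        hap = np.zeros((1, 4), dtype=np.int8)
        hap[0, 0] = 1  # derived in one of two wild haplotypes
        locus = LocusResult(hap, np.array([5]), np.array([1]), np.array([0]), 100)
        sfs = joint_sfs([locus], SampleConfig(2, 2), folded=False)
        assert sfs.matrix[1, 0] == 1
        assert sfs.matrix.sum() == 1

    def test_folding_preserves_polymorphic_total(self, rng):
        m = rng.poisson(3.0, size=(7, 9)).astype(float)
        sfs = JointSFS(m, 6, 8, folded=False)
        folded = sfs.fold()
        assert folded.matrix.sum() == pytest.approx(m.sum())
        assert folded.total_polymorphic() == pytest.approx(sfs.total_polymorphic())

    def test_fold_matches_brute_force_oracle(self, rng):
        n_w, n_d = 4, 6
        m = rng.poisson(2.0, size=(n_w + 1, n_d + 1)).astype(float)
        folded = JointSFS(m, n_w, n_d, folded=False).fold().matrix
        oracle = np.zeros_like(m)
        for i in range(n_w + 1):
            for j in range(n_d + 1):
                ci, cj = n_w - i, n_d - j
                if 2 * (i + j) < n_w + n_d:
                    oracle[i, j] += m[i, j]
                elif 2 * (i + j) > n_w + n_d:
                    oracle[ci, cj] += m[i, j]
                else:
                    oracle[min((i, j), (ci, cj))] += m[i, j]
        assert np.array_equal(folded, oracle)

    def test_folded_mask_excludes_noncanonical_and_monomorphic(self):
        sfs = JointSFS(np.zeros((3, 3)), 2, 2, folded=True)
        mask = sfs.polymorphic_mask()
        assert not mask[0, 0]
        assert not mask[2, 2]
        assert mask[1, 0] and mask[0, 1]
        # (1,1) is the half-total canonical cell; (2,0) pairs with (0,2)
        assert mask[1, 1]
        assert mask[0, 2] != mask[2, 0]

    def test_tsv_round_trip(self, tmp_path, rng):
        m = rng.poisson(2.0, size=(5, 7)).astype(float)
        sfs = JointSFS(m, 4, 6, folded=True)
        path = tmp_path / "sfs.tsv"
        sfs.to_tsv(path)
        back = JointSFS.from_tsv(path)
        assert back.folded and (back.n_w, back.n_d) == (4, 6)
        assert np.array_equal(back.matrix, m)


class TestSimulateLocus:
    def test_pairwise_diversity_matches_4Nmu(self):
        # n=2: E[pi] = 4N*mu per bp; 3 Monte-Carlo SE tolerance
        n, mu, L, n_loci = 5_000, 1e-7, 2_000, 1_500
        model = single_pop_model(n)
        rng = np.random.default_rng(11)
        diffs = np.array(
            [
                (simulate_locus(model, SampleConfig(2, 0), L, mu, rng).haplotypes.sum(axis=1) == 1).sum()
                for _ in range(n_loci)
            ]
        )
        expected = 4 * n * mu * L
        se = diffs.std(ddof=1) / math.sqrt(n_loci)
        assert abs(diffs.mean() - expected) < 3 * se

    def test_segregating_sites_match_watterson_expectation(self):
        n, mu, L, n_loci = 5_000, 1e-7, 1_000, 1_200
        model = single_pop_model(n)
        rng = np.random.default_rng(13)
        s = np.array(
            [
                simulate_locus(model, SampleConfig(10, 0), L, mu, rng).haplotypes.shape[0]
                for _ in range(n_loci)
            ]
        )
        a1 = sum(1.0 / i for i in range(1, 10))
        expected = 4 * n * mu * L * a1
        se = s.std(ddof=1) / math.sqrt(n_loci)
        assert abs(s.mean() - expected) < 3 * se

    def test_haplotype_and_branch_paths_agree_on_sfs(self):
        # same model, two independent simulation routes
        model = domestication_scenario(m_wd=3e-4, m_dw=3e-4)
        sc = SampleConfig(6, 10)
        rng = np.random.default_rng(17)
        n_loci, mu, L = 1_500, 1e-7, 1_000
        loci = [simulate_locus(model, sc, L, mu, rng) for _ in range(n_loci)]
        hap_sfs = joint_sfs(loci, sc, folded=False).matrix
        lengths = branch_length_matrix(23, n_loci, 6, 10, model.to_kernel_arrays())
        branch_expected = mu * L * lengths
        # aggregate to marginal pooled frequency classes for a stable contrast
        def pooled(m):
            out = np.zeros(17)
            for i in range(7):
                for j in range(11):
                    out[i + j] += m[i, j]
            return out[1:16]
        obs, exp = pooled(hap_sfs), pooled(branch_expected)
        se = np.sqrt(exp + 1)
        assert np.all(np.abs(obs - exp) < 5 * se)

    def test_counts_are_consistent_with_haplotypes(self, rng):
        model = single_pop_model(500)
        locus = simulate_locus(model, SampleConfig(4, 6), 1_000, 1e-6, rng)
        assert np.array_equal(locus.counts_w, locus.haplotypes[:, :4].sum(axis=1))
        assert np.array_equal(locus.counts_d, locus.haplotypes[:, 4:].sum(axis=1))
        assert len(np.unique(locus.positions)) == len(locus.positions)


class TestExpectedSfs:
    def test_probabilities_sum_to_one(self):
        sfs = expected_sfs(domestication_scenario(), SampleConfig(6, 8), 500, 1000, 1e-8, seed=3)
        assert sfs.matrix[sfs.polymorphic_mask()].sum() == pytest.approx(1.0)

    def test_floor_keeps_all_polymorphic_cells_positive(self):
        sfs = expected_sfs(single_pop_model(100), SampleConfig(4, 4), 50, 1000, 1e-8, seed=4)
        assert np.all(sfs.matrix[sfs.polymorphic_mask()] > 0)

    def test_two_pop_reduction_to_panmixia(self):
        # t_div ~ 0 and equal sizes: pooled spectrum must match single-pop 1/i
        n = 2_000
        sfs = expected_sfs(single_pop_model(n), SampleConfig(6, 6), 6_000, 1000, 1e-8, seed=5, folded=False)
        pooled = np.zeros(13)
        for i in range(7):
            for j in range(7):
                pooled[i + j] += sfs.matrix[i, j]
        shape = pooled[1:12] * np.arange(1, 12)
        assert np.all(np.abs(shape / shape.mean() - 1) < 0.1)


class TestMsprimeOracle:
    """The same demography in an independent, established simulator."""

    @staticmethod
    def msprime_branch_sfs(n_w, n_d, n_reps, seed):
        import msprime

        g = 3.0
        dem = msprime.Demography()
        dem.add_population(name="W", initial_size=1_700)
        dem.add_population(name="D", initial_size=6_500)
        dem.add_population(name="ANC", initial_size=21_200)
        dem.add_population_parameters_change(time=500 / g, population="W", initial_size=21_200)
        dem.add_population_parameters_change(time=3_600 / g, population="D", initial_size=1_100)
        # backwards lineage movement W->D / D->W at rate m
        m = 5e-4
        dem.set_migration_rate(source="W", dest="D", rate=m)
        dem.set_migration_rate(source="D", dest="W", rate=m)
        dem.add_population_split(time=7_300 / g, derived=["W", "D"], ancestral="ANC")
        out = np.zeros((n_w + 1, n_d + 1))
        reps = msprime.sim_ancestry(
            samples={"W": n_w // 2, "D": n_d // 2},
            demography=dem,
            sequence_length=1,
            ploidy=2,
            num_replicates=n_reps,
            random_seed=seed,
        )
        for ts in reps:
            afs = ts.allele_frequency_spectrum(
                sample_sets=[
                    ts.samples(population=0),
                    ts.samples(population=1),
                ],
                mode="branch",
                polarised=True,
                span_normalise=False,
            )
            out += afs
        return out / n_reps

    def test_branch_sfs_statistically_indistinguishable(self):
        n_w, n_d, n_reps = 8, 12, 4_000
        ours = (
            branch_length_matrix(
                101,
                n_reps,
                n_w,
                n_d,
                domestication_scenario(m_wd=5e-4, m_dw=5e-4).to_kernel_arrays(),
            )
            / n_reps
        )
        ref = self.msprime_branch_sfs(n_w, n_d, n_reps, seed=202)
        # compare total tree length and pooled marginals at ~4 MC sigma
        assert ours.sum() == pytest.approx(ref.sum(), rel=0.05)
        pooled_ours = np.array([ours.diagonal(k).sum() for k in range(-n_w + 1, n_d)])
        pooled_ref = np.array([ref.diagonal(k).sum() for k in range(-n_w + 1, n_d)])
        big = pooled_ref > pooled_ref.sum() * 0.02
        assert np.all(np.abs(pooled_ours[big] / pooled_ref[big] - 1) < 0.15)
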