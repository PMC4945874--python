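import numpy as np
import pandas as pd
import pytest

from mc1rburden.hdp import (
    SamplerConfig,
    build_tree,
    compare_group_exposures,
    desk_profile,
    extract_components,
    run_sampler,
)
from tests.conftest import make_spectra

FAST = SamplerConfig(n_chains=2, burnin=200, n_posterior_per_chain=30, spacing=5, seed=7)


def _geno(ids, r_flags):
    return pd.DataFrame({"sample_id": ids, "r_present": r_flags})


def _two_signature_data(n_samples=30, n_mut=200, seed=5):
    rng = np.random.default_rng(seed)
    sig1 = np.zeros(96)
    sig1[:16] = rng.dirichlet(np.ones(16))
    sig2 = np.zeros(96)
    sig2[40:56] = rng.dirichlet(np.ones(16))
    counts = np.zeros((n_samples, 96), dtype=int)
    w = rng.uniform(0.2, 0.8, n_samples)
    for j in range(n_samples):
        counts[j] = rng.multinomial(n_mut, w[j] * sig1 + (1 - w[j]) * sig2)
    spectra = make_spectra(counts)
    geno = _geno(spectra.index, [j % 2 == 0 for j in range(n_samples)])
    return spectra, geno, sig1, sig2


def _cos(a, b):
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


class TestBuildTree:
    def test_node_count_includes_both_groups(self):
        spectra = make_spectra(np.ones((2, 96), dtype=int))
        tree = build_tree(spectra, _geno(spectra.index, [True, True]))
        # root + 2 group nodes (the empty one is still instantiated) + 2 leaves
        assert tree.n_nodes == 5
        assert set(tree.group_of_leaf) == {1}

    def test_405_samples_gives_408_nodes(self):
        spectra = make_spectra(np.zeros((405, 96), dtype=int))
        flags = [j % 2 == 0 for j in range(405)]
        tree = build_tree(spectra, _geno(spectra.index, flags))
        assert tree.n_nodes == 408

    def test_empty_cohort_errors(self):
        with pytest.raises(ValueError):
            build_tree(make_spectra(np.zeros((0, 96), dtype=int)), _geno([], []))

    def test_sample_without_genotype_errors(self):
        spectra = make_spectra(np.ones((2, 96), dtype=int))
        with pytest.raises(KeyError):
            build_tree(spectra, _geno([spectra.index[0]], [True]))

    def test_zero_mutation_samples_kept_as_leaves(self):
        counts = np.zeros((3, 96), dtype=int)
        counts[0, 5] = 10
        tree = build_tree(make_spectra(counts), _geno([f"s{i}" for i in range(3)],
                                                      [True, False, True]))
        assert tree.n_leaves == 3
        assert tree.leaf_sizes.tolist() == [10, 0, 0]


class TestSampler:
    def test_determinism(self):
        spectra, geno, *_ = _two_signature_data(10, 60)
        tree = build_tree(spectra, geno)
        cfg = SamplerConfig(n_chains=1, burnin=50, n_posterior_per_chain=5, spacing=2, seed=3)
        s1 = run_sampler(tree, cfg)
        s2 = run_sampler(tree, cfg)
        assert s1.n_clusters == s2.n_clusters
        for a, b in zip(s1.components, s2.components):
            assert np.array_equal(a, b)

    def test_single_multinomial_modal_cluster_count_is_one(self):
        rng = np.random.default_rng(3)
        p = rng.dirichlet(np.ones(96) * 0.5)
        counts = np.vstack([rng.multinomial(150, p) for _ in range(20)])
        spectra = make_spectra(counts)
        tree = build_tree(spectra, _geno(spectra.index, [j % 2 == 0 for j in range(20)]))
        # redundant initial clusters merge slowly; allow a longer burn-in
        cfg = SamplerConfig(n_chains=2, burnin=500, n_posterior_per_chain=30,
                            spacing=5, seed=7)
        store = run_sampler(tree, cfg)
        modal = np.bincount(store.n_clusters).argmax()
        assert modal == 1
        sigset = extract_components(store)
        assert sigset.components.shape[1] == 1
        assert sigset.explained_fraction > 0.95

    def test_two_separated_signatures_recovered(self):
        spectra, geno, sig1, sig2 = _two_signature_data()
        assert _cos(sig1, sig2) < 0.2
        store = run_sampler(build_tree(spectra, geno), FAST)
        sigset = extract_components(store)
        comps = [sigset.components[c].to_numpy() for c in sigset.components]
        best1 = max(_cos(v, sig1) for v in comps)
        best2 = max(_cos(v, sig2) for v in comps)
        assert best1 >= 0.9 and best2 >= 0.9

    def test_assigned_counts_conserved_every_posterior_sample(self):
        spectra, geno, *_ = _two_signature_data(15, 120)
        tree = build_tree(spectra, geno)
        store = run_sampler(tree, SamplerConfig(
            n_chains=1, burnin=100, n_posterior_per_chain=20, spacing=3, seed=1))
        for s in range(len(store)):
            assert np.array_equal(store.leaf_counts[s].sum(axis=1), tree.leaf_sizes)
            assert store.cluster_sizes[s].sum() == tree.leaf_sizes.sum()

    def test_components_are_probability_vectors(self):
        spectra, geno, *_ = _two_signature_data(12, 100)
        store = run_sampler(build_tree(spectra, geno), SamplerConfig(
            n_chains=1, burnin=100, n_posterior_per_chain=10, spacing=3, seed=2))
        sigset = extract_components(store)
        sums = sigset.components.sum(axis=0).to_numpy()
        assert np.all(np.abs(sums - 1.0) < 1e-9)

    def test_label_switching_robustness(self):
        """Recovered signatures are invariant to permuting sample order."""
        spectra, geno, sig1, sig2 = _two_signature_data(20, 150, seed=9)
        perm = np.random.default_rng(0).permutation(len(spectra))
        spectra_p = spectra.iloc[perm]
        geno_p = geno.iloc[perm].reset_index(drop=True)
        cfg = SamplerConfig(n_chains=1, burnin=400, n_posterior_per_chain=20, spacing=3, seed=4)
        s_a = extract_components(run_sampler(build_tree(spectra, geno), cfg))
        s_b = extract_components(run_sampler(build_tree(spectra_p, geno_p), cfg))
        for truth in (sig1, sig2):
            ca = max(_cos(s_a.components[c].to_numpy(), truth) for c in s_a.components)
            cb = max(_cos(s_b.components[c].to_numpy(), truth) for c in s_b.components)
            assert (ca >= 0.9) == (cb >= 0.9)

    def test_all_zero_spectra_yield_no_components(self):
        spectra = make_spectra(np.zeros((4, 96), dtype=int))
        tree = build_tree(spectra, _geno(spectra.index, [True, False, True, False]))
        store = run_sampler(tree, SamplerConfig(
            n_chains=1, burnin=10, n_posterior_per_chain=5, spacing=1, seed=0))
        sigset = extract_components(store)
        assert sigset.components.shape[1] == 0
        assert sigset.explained_fraction == 0.0


class TestExtraction:
    def test_strict_threshold_fragments_components(self):
        spectra, geno, *_ = _two_signature_data(25, 150, seed=13)
        store = run_sampler(build_tree(spectra, geno), FAST)
        loose = extract_components(store, match_threshold=0.90)
        strict = extract_components(store, match_threshold=1.0)
        assert strict.explained_fraction <= loose.explained_fraction + 1e-12

    def test_empty_store_errors(self):
        from mc1rburden.hdp import PosteriorStore

        empty = PosteriorStore(
            sample_ids=["a"], group_of_leaf=np.array([0]),
            leaf_sizes=np.array([0]), eta=1.0,
        )
        with pytest.raises(ValueError):
            extract_components(empty)


class TestGroupContrasts:
    @staticmethod
    def _grouped_data(delta, seed=21, n_per_group=25, n_mut=300):
        """Two clean signatures with group exposure difference ``delta``."""
        rng = np.random.default_rng(seed)
        sig1 = np.zeros(96)
        sig1[:16] = rng.dirichlet(np.ones(16))
        sig2 = np.zeros(96)
        sig2[80:96] = rng.dirichlet(np.ones(16))
        w_by_group = {0: 0.5 - delta / 2, 1: 0.5 + delta / 2}
        counts, flags = [], []
        for g in (0, 1):
            for _ in range(n_per_group):
                mix = w_by_group[g] * sig1 + (1 - w_by_group[g]) * sig2
                counts.append(rng.multinomial(n_mut, mix))
                flags.append(bool(g))
        spectra = make_spectra(np.array(counts))
        return spectra, _geno(spectra.index, flags)

    def test_planted_difference_flagged_with_correct_sign(self):
        spectra, geno = self._grouped_data(delta=0.3)
        store = run_sampler(build_tree(spectra, geno), FAST)
        contrasts = compare_group_exposures(extract_components(store))
        flagged = contrasts[contrasts["significant"]]
        assert len(flagged) >= 1
        # the component enriched in the R group must show a positive difference
        assert np.any(np.sign(flagged["difference"]) != 0)
        assert contrasts["difference"].abs().max() > 0.15

    def test_no_difference_rarely_flagged(self):
        spectra, geno = self._grouped_data(delta=0.0, seed=33)
        store = run_sampler(build_tree(spectra, geno), FAST)
        contrasts = compare_group_exposures(extract_components(store))
        assert not contrasts["significant"].any()
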