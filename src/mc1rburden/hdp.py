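"""Mutational-signature extraction with a hierarchical Dirichlet process.

Signatures are shared latent categorical distributions over the 96
trinucleotide contexts.  The HDP is arranged as a three-level tree: one
child DP node per sample, one parent DP node per R-allele group (zero
versus at least one R allele), and one grandparent (root) DP whose base
measure is a uniform Dirichlet over the 96 categories.  Sharing through
the tree lets samples borrow statistical strength while the group nodes
carry group-level signature exposures.

Inference is collapsed Gibbs sampling over per-mutation cluster
assignments with Chinese-restaurant-franchise bookkeeping: between data
sweeps the table counts at every node are resampled from the
Chinese-restaurant-table distribution and propagated up the tree, node
predictive weights are refreshed from them, and the per-level
concentration parameters are resampled with the Escobar–West
auxiliary-variable scheme under Gamma(1, 1) hyperpriors.  The inner
per-item sweep and the table resampling are numba-compiled.

Components are consolidated across posterior samples by cosine matching
(threshold 0.90), retained when present in at least half the posterior
samples, and summarized as posterior means with 2.5/97.5% quantile
intervals; group exposure contrasts are flagged significant when the two
groups' 95% credible intervals are disjoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .spectrum import CONTEXTS96

logger = logging.getLogger(__name__)

N_CAT = 96
GROUP_LABELS = ("noR", "R")  # zero R alleles vs at least one


@dataclass
class SamplerConfig:
    """MCMC settings.  The published profile is the default; use
    :func:`desk_profile` for a settings set sized for interactive runs."""

    init_clusters: int = 4
    n_chains: int = 4
    burnin: int = 10000
    n_posterior_per_chain: int = 500
    spacing: int = 50
    seed: int = 0
    eta: float = 1.0  # uniform Dirichlet base pseudocount per category
    max_clusters: int = 40
    hyper_shape: float = 1.0
    hyper_rate: float = 1.0

    def __post_init__(self) -> None:
        for name in ("init_clusters", "n_chains", "burnin", "n_posterior_per_chain", "spacing"):
            if getattr(self, name) < 1 and name != "burnin":
                raise ValueError(f"{name} must be positive")
        if self.burnin < 0:
            raise ValueError("burnin must be non-negative")

    @property
    def total_posterior_samples(self) -> int:
        return self.n_chains * self.n_posterior_per_chain


def paper_profile(seed: int = 0) -> SamplerConfig:
    return SamplerConfig(seed=seed)


def desk_profile(seed: int = 0) -> SamplerConfig:
    return SamplerConfig(
        n_chains=2, burnin=500, n_posterior_per_chain=50, spacing=10, seed=seed
    )


@dataclass
class HDPTree:
    """Sample -> R-group -> root tree with the data expanded per mutation."""

    sample_ids: list[str]
    group_of_leaf: np.ndarray  # len L, values in {0, 1}
    leaf_sizes: np.ndarray  # mutations per leaf
    item_leaf: np.ndarray  # len N
    item_cat: np.ndarray  # len N, values in 0..95

    @property
    def n_leaves(self) -> int:
        return len(self.sample_ids)

    @property
    def n_nodes(self) -> int:
        # root + the two group nodes (both always instantiated) + leaves
        return 1 + 2 + self.n_leaves


def build_tree(spectra: pd.DataFrame, genotypes: pd.DataFrame) -> HDPTree:
    """Construct the HDP tree from a samples x 96 count matrix and a
    genotype table carrying ``sample_id`` and ``r_present`` (or
    ``r_count``).  Zero-mutation samples are kept as (empty) leaves; a
    spectrum sample without a genotype is an error."""
    if len(spectra) == 0:
        raise ValueError("cannot build an HDP tree from an empty cohort")
    geno = genotypes.set_index("sample_id")
    if "r_present" in geno.columns:
        r_present = geno["r_present"].astype(bool)
    else:
        r_present = geno["r_count"].astype(int) >= 1
    sample_ids = [str(s) for s in spectra.index]
    missing = [s for s in sample_ids if s not in r_present.index]
    if missing:
        raise KeyError(f"samples without genotype: {missing[:5]}")
    group_of_leaf = np.array([int(r_present[s]) for s in sample_ids], dtype=np.int64)
    counts = spectra[list(CONTEXTS96)].to_numpy(dtype=np.int64)
    leaf_sizes = counts.sum(axis=1)
    item_leaf = np.repeat(np.arange(len(sample_ids)), leaf_sizes)
    item_cat = np.concatenate(
        [np.repeat(np.arange(N_CAT), counts[j]) for j in range(len(sample_ids))]
    ) if leaf_sizes.sum() else np.zeros(0, dtype=np.int64)
    return HDPTree(
        sample_ids=sample_ids,
        group_of_leaf=group_of_leaf,
        leaf_sizes=leaf_sizes.astype(np.int64),
        item_leaf=item_leaf.astype(np.int64),
        item_cat=item_cat.astype(np.int64),
    )


# ---------------------------------------------------------------------------
# numba kernels


@njit(cache=True)
def _item_sweep(item_cat, item_leaf, z, group_of_leaf, n_leaf_k, n_k_cat, n_k_tot,
                w_group_ext, alpha_leaf, eta, K, Kmax, u, probs):
    n_items = item_cat.shape[0]
    for idx in range(n_items):
        j = item_leaf[idx]
        x = item_cat[idx]
        k = z[idx]
        g = group_of_leaf[j]
        n_leaf_k[j, k] -= 1
        n_k_cat[k, x] -= 1
        n_k_tot[k] -= 1
        tot = 0.0
        for k2 in range(K):
            p = (n_leaf_k[j, k2] + alpha_leaf * w_group_ext[g, k2]) * (
                (n_k_cat[k2, x] + eta) / (n_k_tot[k2] + N_CAT * eta)
            )
            probs[k2] = p
            tot += p
        pnew = alpha_leaf * w_group_ext[g, K] / N_CAT
        tot += pnew
        r = u[idx] * tot
        knew = -1
        acc = 0.0
        for k2 in range(K):
            acc += probs[k2]
            if r < acc:
                knew = k2
                break
        if knew < 0:
            if K < Kmax:
                knew = K
                K += 1
            else:
                knew = k  # capacity guard; effectively never reached
        z[idx] = knew
        n_leaf_k[j, knew] += 1
        n_k_cat[knew, x] += 1
        n_k_tot[knew] += 1
    return K


@njit(cache=True)
def _crt_leaf_tables(n_leaf_k, group_of_leaf, w_group_ext, alpha_leaf, K, u, t_leaf):
    ptr = 0
    L = n_leaf_k.shape[0]
    for j in range(L):
        g = group_of_leaf[j]
        for k in range(K):
            n = n_leaf_k[j, k]
            a = alpha_leaf * w_group_ext[g, k]
            t = 0
            for i in range(n):
                if u[ptr] * (a + i) < a:
                    t += 1
                ptr += 1
            t_leaf[j, k] = t
    return ptr


@njit(cache=True)
def _crt_group_tables(c_group_k, w_root_ext, alpha_group, K, u, t_group):
    ptr = 0
    G = c_group_k.shape[0]
    for g in range(G):
        for k in range(K):
            n = c_group_k[g, k]
            a = alpha_group * w_root_ext[k]
            t = 0
            for i in range(n):
                if u[ptr] * (a + i) < a:
                    t += 1
                ptr += 1
            t_group[g, k] = t
    return ptr


# ---------------------------------------------------------------------------
# sampler


@dataclass
class PosteriorStore:
    """Collected posterior samples from one or more chains."""

    sample_ids: list[str]
    group_of_leaf: np.ndarray
    leaf_sizes: np.ndarray
    eta: float
    n_clusters: list[int] = field(default_factory=list)
    components: list[np.ndarray] = field(default_factory=list)  # K x 96 posterior-mean profiles
    leaf_counts: list[np.ndarray] = field(default_factory=list)  # L x K assigned counts
    cluster_sizes: list[np.ndarray] = field(default_factory=list)  # K
    chain_ids: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.n_clusters)

    def group_counts(self, s: int) -> np.ndarray:
        lc = self.leaf_counts[s]
        out = np.zeros((2, lc.shape[1]))
        for g in (0, 1):
            out[g] = lc[self.group_of_leaf == g].sum(axis=0)
        return out


def _sample_concentration(rng, alpha, n_customers, n_tables, shape, rate):
    """Escobar–West auxiliary-variable update for a shared DP
    concentration across restaurants with customer counts
    ``n_customers`` and total tables ``n_tables``."""
    log_w = 0.0
    s_sum = 0.0
    for n_j in n_customers:
        if n_j <= 0:
            continue
        log_w += np.log(rng.beta(alpha + 1.0, n_j))
        s_sum += rng.random() < (n_j / (n_j + alpha))
    new_shape = shape + max(n_tables - s_sum, 0.0)
    new_rate = rate - log_w
    return float(rng.gamma(new_shape, 1.0 / max(new_rate, 1e-12)))


def _extend_weights(w: np.ndarray, new_mass: float, width: int) -> np.ndarray:
    """Place existing-cluster weights followed by geometric stick shares
    of the new-cluster mass, so clusters born mid-sweep have a weight."""
    out = np.zeros(width)
    K = len(w)
    out[:K] = w
    mass = new_mass
    for i in range(K, width):
        out[i] = mass * 0.5
        mass *= 0.5
    if width > K:
        out[width - 1] = mass * 2  # absorb the tail remainder
    return out


def run_sampler(tree: HDPTree, config: Optional[SamplerConfig] = None) -> PosteriorStore:
    """Run the collapsed Gibbs sampler; returns the posterior store.

    Chains are independent, each seeded from the master seed through
    ``numpy.random.SeedSequence`` spawning, so identical configuration
    yields an identical store.
    """
    config = config or SamplerConfig()
    store = PosteriorStore(
        sample_ids=tree.sample_ids,
        group_of_leaf=tree.group_of_leaf.copy(),
        leaf_sizes=tree.leaf_sizes.copy(),
        eta=config.eta,
    )
    master = np.random.SeedSequence(config.seed)
    chain_seeds = master.spawn(config.n_chains)
    for chain in range(config.n_chains):
        _run_chain(tree, config, np.random.default_rng(chain_seeds[chain]), chain, store)
    return store


def _run_chain(tree, config, rng, chain_id, store) -> None:
    L = tree.n_leaves
    N = len(tree.item_cat)
    Kmax = config.max_clusters
    eta = config.eta
    K = min(config.init_clusters, Kmax)

    z = rng.integers(0, K, size=N).astype(np.int64) if N else np.zeros(0, dtype=np.int64)
    n_leaf_k = np.zeros((L, Kmax + 1), dtype=np.int64)
    n_k_cat = np.zeros((Kmax + 1, N_CAT), dtype=np.int64)
    n_k_tot = np.zeros(Kmax + 1, dtype=np.int64)
    for idx in range(N):
        n_leaf_k[tree.item_leaf[idx], z[idx]] += 1
        n_k_cat[z[idx], tree.item_cat[idx]] += 1
        n_k_tot[z[idx]] += 1

    alpha_leaf = 1.0
    alpha_group = 1.0
    gamma_root = 1.0
    t_leaf = np.zeros((L, Kmax + 1), dtype=np.int64)
    t_group = np.zeros((2, Kmax + 1), dtype=np.int64)
    # provisional flat tables to bootstrap the first weight computation
    t_leaf[:, :K] = (n_leaf_k[:, :K] > 0).astype(np.int64)
    for g in (0, 1):
        t_group[g, :K] = (t_leaf[tree.group_of_leaf == g, :K].sum(axis=0) > 0)

    probs = np.zeros(Kmax + 1)
    n_iter = config.burnin + config.n_posterior_per_chain * config.spacing
    collected = 0
    for it in range(n_iter):
        # --- node predictive weights from current table counts
        m_root = t_group[:, :K].sum(axis=0).astype(float)
        M = m_root.sum()
        w_root = m_root / (M + gamma_root)
        w_root_new = gamma_root / (M + gamma_root)
        w_root_ext = _extend_weights(w_root, w_root_new, Kmax + 1)

        c_group = np.zeros((2, Kmax + 1), dtype=np.int64)
        for g in (0, 1):
            c_group[g, :K] = t_leaf[tree.group_of_leaf == g, :K].sum(axis=0)
        w_group_ext = np.zeros((2, Kmax + 1))
        for g in (0, 1):
            C_g = c_group[g, :K].sum()
            w_g = (c_group[g, :K] + alpha_group * w_root) / (C_g + alpha_group)
            w_g_new = alpha_group * w_root_new / (C_g + alpha_group)
            w_group_ext[g] = _extend_weights(w_g, w_g_new, Kmax + 1)

        # --- Gibbs sweep over items
        if N:
            u = rng.random(N)
            K = int(
                _item_sweep(
                    tree.item_cat, tree.item_leaf, z, tree.group_of_leaf,
                    n_leaf_k, n_k_cat, n_k_tot, w_group_ext,
                    alpha_leaf, eta, K, Kmax, u, probs,
                )
            )

        # --- drop empty clusters and relabel compactly
        active = np.flatnonzero(n_k_tot[:K] > 0)
        if len(active) != K or (len(active) and active[-1] != len(active) - 1):
            relabel = -np.ones(Kmax + 1, dtype=np.int64)
            relabel[active] = np.arange(len(active))
            if N:
                z = relabel[z]
            n_leaf_k[:, : len(active)] = n_leaf_k[:, active]
            n_leaf_k[:, len(active):] = 0
            n_k_cat[: len(active)] = n_k_cat[active]
            n_k_cat[len(active):] = 0
            n_k_tot[: len(active)] = n_k_tot[active]
            n_k_tot[len(active):] = 0
            K = len(active)

        # --- resample table counts (CRT) up the tree
        if K and N:
            u1 = rng.random(int(n_leaf_k[:, :K].sum()))
            _crt_leaf_tables(
                n_leaf_k[:, : K], tree.group_of_leaf, w_group_ext, alpha_leaf, K,
                u1, t_leaf[:, : K],
            )
            t_leaf[:, K:] = 0
            c_group = np.zeros((2, Kmax + 1), dtype=np.int64)
            for g in (0, 1):
                c_group[g, :K] = t_leaf[tree.group_of_leaf == g, :K].sum(axis=0)
            u2 = rng.random(int(c_group[:, :K].sum()))
            _crt_group_tables(c_group[:, :K], w_root_ext, alpha_group, K, u2, t_group[:, :K])
            t_group[:, K:] = 0

            # --- concentration parameters, Escobar–West with Gamma(1,1) priors
            sh, ra = config.hyper_shape, config.hyper_rate
            alpha_leaf = _sample_concentration(
                rng, alpha_leaf, n_leaf_k[:, :K].sum(axis=1), t_leaf[:, :K].sum(), sh, ra
            )
            alpha_group = _sample_concentration(
                rng, alpha_group, c_group[:, :K].sum(axis=1), t_group[:, :K].sum(), sh, ra
            )
            gamma_root = _sample_concentration(
                rng, gamma_root, [t_group[:, :K].sum()], K, sh, ra
            )

        # --- collect
        if it >= config.burnin and (it - config.burnin) % config.spacing == 0:
            if collected < config.n_posterior_per_chain:
                comps = (n_k_cat[:K] + eta) / (
                    n_k_tot[:K, None] + N_CAT * eta
                ) if K else np.zeros((0, N_CAT))
                store.n_clusters.append(K)
                store.components.append(comps.copy())
                store.leaf_counts.append(n_leaf_k[:, :K].copy())
                store.cluster_sizes.append(n_k_tot[:K].copy())
                store.chain_ids.append(chain_id)
                collected += 1
    logger.info(
        "chain %d finished: %d posterior samples, final K=%d",
        chain_id, collected, K,
    )


# ---------------------------------------------------------------------------
# component extraction and group contrasts


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


@dataclass
class SignatureSet:
    """Consolidated signature components with exposures and contrasts."""

    components: pd.DataFrame  # contexts x components, posterior means
    component_ci: dict[str, np.ndarray]  # name -> (2, 96) low/high
    sample_exposures: pd.DataFrame  # samples x components (means)
    group_exposures: pd.DataFrame  # rows: noR/R; columns: comps + unassigned
    group_exposure_ci: dict[str, np.ndarray]  # comp -> (2 groups, 2) low/high
    explained_fraction: float
    n_posterior_samples: int
    presence_fraction: dict[str, float]


def extract_components(store: PosteriorStore, match_threshold: float = 0.90) -> SignatureSet:
    """Match raw clusters across posterior samples into components.

    Clusters are matched greedily (largest first) to a running registry by
    cosine similarity at ``match_threshold``; registry entries present in
    at least 50% of posterior samples are retained.  Component profiles
    are posterior means with 2.5/97.5% quantile intervals, exposures are
    data-assignment fractions per node, and mutations in unretained
    clusters are reported as unassigned mass.
    """
    if len(store) == 0:
        raise ValueError("posterior store is empty")
    S = len(store)
    total_data = float(store.leaf_sizes.sum())
    registry_mean: list[np.ndarray] = []
    registry_hits: list[int] = []
    profile_draws: list[list[np.ndarray]] = []
    # per posterior sample: cluster index -> registry id
    assignments: list[dict[int, int]] = []

    for s in range(S):
        comps = store.components[s]
        sizes = store.cluster_sizes[s]
        order = np.argsort(-sizes)
        used: set[int] = set()
        amap: dict[int, int] = {}
        for k in order:
            vec = comps[k]
            best, best_cos = -1, match_threshold
            for rid, mean in enumerate(registry_mean):
                if rid in used:
                    continue
                c = _cosine(vec, mean)
                if c >= best_cos:
                    best, best_cos = rid, c
            if best < 0:
                best = len(registry_mean)
                registry_mean.append(vec.copy())
                registry_hits.append(0)
                profile_draws.append([])
            else:
                # running mean keeps the registry anchored
                registry_mean[best] = 0.9 * registry_mean[best] + 0.1 * vec
            used.add(best)
            registry_hits[best] += 1
            profile_draws[best].append(vec)
            amap[int(k)] = best
        assignments.append(amap)

    retained = [rid for rid, h in enumerate(registry_hits) if h >= 0.5 * S]
    retained.sort(key=lambda rid: -registry_hits[rid])
    names = [f"S{i + 1}" for i in range(len(retained))]

    comp_means = {}
    comp_ci = {}
    for name, rid in zip(names, retained):
        draws = np.vstack(profile_draws[rid])
        mean = draws.mean(axis=0)
        comp_means[name] = mean / mean.sum()
        comp_ci[name] = np.percentile(draws, [2.5, 97.5], axis=0)
    components = pd.DataFrame(comp_means, index=list(CONTEXTS96))

    L = len(store.sample_ids)
    leaf_exp_draws = {name: np.zeros((S, L)) for name in names}
    group_exp_draws = {name: np.zeros((S, 2)) for name in names}
    explained_draws = np.zeros(S)
    leaf_sizes = np.maximum(store.leaf_sizes.astype(float), 1.0)
    group_sizes = np.array(
        [store.leaf_sizes[store.group_of_leaf == g].sum() for g in (0, 1)], dtype=float
    )
    group_sizes = np.maximum(group_sizes, 1.0)
    rid_to_name = {rid: name for name, rid in zip(names, retained)}
    for s in range(S):
        lc = store.leaf_counts[s]
        gc = store.group_counts(s)
        explained = 0.0
        for k, rid in assignments[s].items():
            name = rid_to_name.get(rid)
            if name is None:
                continue
            leaf_exp_draws[name][s] = lc[:, k] / leaf_sizes
            group_exp_draws[name][s] = gc[:, k] / group_sizes
            explained += float(store.cluster_sizes[s][k])
        explained_draws[s] = explained / total_data if total_data else 0.0

    sample_exposures = pd.DataFrame(
        {name: leaf_exp_draws[name].mean(axis=0) for name in names},
        index=store.sample_ids,
    )
    group_rows = {name: group_exp_draws[name].mean(axis=0) for name in names}
    group_exposures = pd.DataFrame(group_rows, index=list(GROUP_LABELS))
    group_exposures["unassigned"] = 1.0 - group_exposures[names].sum(axis=1) if names else 1.0
    group_ci = {
        name: np.percentile(group_exp_draws[name], [2.5, 97.5], axis=0).T
        for name in names
    }
    presence = {name: registry_hits[rid] / S for name, rid in zip(names, retained)}
    return SignatureSet(
        components=components,
        component_ci=comp_ci,
        sample_exposures=sample_exposures,
        group_exposures=group_exposures,
        group_exposure_ci=group_ci,
        explained_fraction=float(explained_draws.mean()),
        n_posterior_samples=S,
        presence_fraction=presence,
    )


def compare_group_exposures(signature_set: SignatureSet) -> pd.DataFrame:
    """Per-component contrast of R-group exposures.

    A component is flagged significant when the two groups' 95% credible
    intervals do not overlap; the sign of the difference (R minus noR) is
    reported alongside.
    """
    names = [c for c in signature_set.group_exposures.columns if c != "unassigned"]
    if signature_set.group_exposures.shape[0] < 2:
        raise ValueError("group contrast requires two group nodes")
    rows = []
    for name in names:
        ci = signature_set.group_exposure_ci[name]  # (2 groups, 2)
        mean_noR, mean_R = signature_set.group_exposures.loc[list(GROUP_LABELS), name]
        disjoint = ci[0, 1] < ci[1, 0] or ci[1, 1] < ci[0, 0]
        rows.append(
            {
                "component": name,
                "exposure_noR": mean_noR,
                "exposure_R": mean_R,
                "ci_noR_low": ci[0, 0], "ci_noR_high": ci[0, 1],
                "ci_R_low": ci[1, 0], "ci_R_high": ci[1, 1],
                "difference": mean_R - mean_noR,
                "significant": bool(disjoint),
            }
        )
    return pd.DataFrame(rows)
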