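import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import haplomix as hx

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_panel():
    """20 haplotypes x 60 markers over 2 chromosomes, known 3-cluster truth."""
    panel, gen = hx.simulate_panel(20, 60, 3, seed=7, n_chromosomes=2)
    return panel, gen


@pytest.fixture(scope="session")
def small_model(small_panel):
    panel, _ = small_panel
    return hx.fit_cluster_model(panel, K=3, n_starts=1, max_iter=25, seed=3)[0]


@pytest.fixture(scope="session")
def tiny_model():
    """K=2 model over 5 markers for brute-force comparisons."""
    panel, _ = hx.simulate_panel(10, 5, 2, seed=3)
    return hx.fit_cluster_model(panel, K=2, max_iter=10, seed=2)[0]


def random_table(model, seed=0):
    """Uninformative random observations aligned with a cluster model."""
    rng = np.random.default_rng(seed)
    df = model.marker_map.copy()
    df["baf"] = rng.uniform(0, 1, model.n_markers)
    df["lrr"] = rng.normal(0, 0.3, model.n_markers)
    return hx.call_genotypes(hx.MarkerTable(df))


def brute_force_joint(table, model, params, space, tpm, pi, use_lrr=True):
    """Exhaustive-enumeration posterior marginals of the aberration state.

    Independent oracle for the factorized forward-backward: enumerates every
    (aberration path, haplotype-pair path) combination.  Only feasible for a
    handful of markers and small K.
    """
    from itertools import product

    from haplomix.emission import marker_emission

    M = len(table)
    K = model.K
    L = len(space)
    g, b, r = table.genotype, table.baf, table.lrr
    E = np.empty((M, L, K, K))
    for m in range(M):
        for l, st in enumerate(space.states):
            for z1 in range(K):
                for z2 in range(K):
                    z = (z1, z2)
                    E[m, l, z1, z2] = hx.genotype_prob(model, m, z, int(g[m])) * \
                        marker_emission(b[m], r[m], int(g[m]), st, z, model,
                                        params, m, use_lrr=use_lrr)
    lp = np.array(list(product(range(L), repeat=M)))
    zp = np.array(list(product(range(K), repeat=M)))

    def chain_prior(paths, init, trans):
        p = init[paths[:, 0]].astype(float).copy()
        for m in range(1, M):
            p = p * trans(m, paths[:, m - 1], paths[:, m])
        return p

    pl = chain_prior(lp, pi, lambda m, a, c: tpm[a, c])
    pz = chain_prior(
        zp, model.alpha[0],
        lambda m, a, c: (1 - model.rho[m - 1]) * (a == c)
        + model.rho[m - 1] * model.alpha[m, c],
    )
    A = np.ones((len(lp), len(zp), len(zp)))
    for m in range(M):
        A *= E[m][lp[:, m]][:, zp[:, m], :][:, :, zp[:, m]]
    A *= pl[:, None, None] * pz[None, :, None] * pz[None, None, :]
    tot = A.sum()
    marg_l = np.zeros((M, L))
    w_l = A.sum(axis=(1, 2))
    for m in range(M):
        for l in range(L):
            marg_l[m, l] = w_l[lp[:, m] == l].sum()
    return marg_l / tot, np.log(tot)
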