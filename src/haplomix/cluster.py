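"""Haplotype-cluster HMM for germline linkage disequilibrium.

Haplotypes are modelled as mosaics of K latent clusters ("ancestral
haplotypes").  Cluster k at marker m emits the B allele with frequency
theta[m, k]; cluster membership follows a Markov chain that, between markers
m and m+1, jumps with probability rho[m] to a cluster drawn from the weights
alpha[m+1] and otherwise stays put.  Jump probabilities are distance-aware,
rho = 1 - exp(-gamma_rate * d) for inter-marker distance d in bp, with a
single fitted rate; chromosome boundaries are encoded as rho = 1, which
restarts the chain from alpha.

An individual's two haplotypes are a priori independent draws from this
chain; the *ordered* pair z = (k1, k2) of their cluster memberships is what
the joint aberration model conditions on, since ordering is what lets an
allelic-imbalance state point at a specific haplotype.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from ._kernels import hap_fb_stats
from .panel import ReferencePanel, chrom_bounds

__all__ = [
    "ClusterModel",
    "PairTransition",
    "fit_cluster_model",
    "genotype_prob",
    "config_prob",
    "pair_transition",
    "sample_diploid",
    "hap_posterior",
]

THETA_FLOOR = 1e-4  # keeps heterozygote emissions away from exact zero
MODEL_FORMAT_VERSION = 1


@dataclass
class ClusterModel:
    """A fitted haplotype-cluster HMM.

    Arrays are global over all chromosomes (concatenated in map order);
    ``rho`` has one entry per inter-marker interval and is exactly 1.0 at
    chromosome boundaries.
    """

    K: int
    theta: np.ndarray  # (M, K) cluster B-allele frequencies
    alpha: np.ndarray  # (M, K) cluster weights, rows sum to 1
    rho: np.ndarray  # (M-1,) inter-marker jump probabilities
    marker_map: pd.DataFrame  # marker_id, chrom, pos
    gamma_rate: float = float("nan")  # fitted jump rate per bp
    loglik: float = float("nan")
    loglik_trace: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.theta = np.ascontiguousarray(self.theta, dtype=np.float64)
        self.alpha = np.ascontiguousarray(self.alpha, dtype=np.float64)
        self.rho = np.ascontiguousarray(self.rho, dtype=np.float64)
        M = self.theta.shape[0]
        if self.theta.shape != (M, self.K) or self.alpha.shape != (M, self.K):
            raise ValueError("theta/alpha shapes inconsistent with K and marker count")
        if self.rho.shape != (max(M - 1, 0),):
            raise ValueError("rho must have one entry per inter-marker interval")
        if np.any((self.theta < 0) | (self.theta > 1)):
            raise ValueError("theta outside [0, 1]")
        if np.any((self.rho < 0) | (self.rho > 1)):
            raise ValueError("rho outside [0, 1]")
        if not np.allclose(self.alpha.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("alpha rows must sum to 1")
        if len(self.marker_map) != M:
            raise ValueError("marker map length does not match arrays")

    @property
    def n_markers(self) -> int:
        return self.theta.shape[0]

    @property
    def marker_ids(self) -> np.ndarray:
        return self.marker_map["marker_id"].to_numpy()

    def chrom_bounds(self) -> list[tuple[int, int]]:
        return chrom_bounds(self.marker_map["chrom"].to_numpy())

    def cluster_marginals(self) -> np.ndarray:
        """Marginal cluster-membership distribution of the chain at each marker.

        Unlike ``alpha`` (the jump-destination weights), this is the actual
        occupancy: mu[m+1] = (1 - rho[m]) mu[m] + rho[m] alpha[m+1].
        """
        mu = np.empty_like(self.alpha)
        mu[0] = self.alpha[0]
        for m in range(1, self.n_markers):
            r = self.rho[m - 1]
            mu[m] = (1.0 - r) * mu[m - 1] + r * self.alpha[m]
        return mu

    def subset(self, idx: np.ndarray) -> "ClusterModel":
        """Restrict to a sorted subset of marker indices.

        The jump probability between retained neighbours accumulates over the
        removed intervals: a jump occurs if at least one intervening interval
        jumped, so stay-probabilities multiply.
        """
        idx = np.asarray(idx)
        if len(idx) < 2:
            raise ValueError("need at least 2 markers")
        if np.any(np.diff(idx) <= 0):
            raise ValueError("subset indices must be strictly increasing")
        log_stay = np.concatenate(
            [[0.0], np.cumsum(np.log1p(-np.minimum(self.rho, 1.0 - 1e-15)))]
        )
        new_rho = 1.0 - np.exp(log_stay[idx[1:]] - log_stay[idx[:-1]])
        # re-impose exact restarts across chromosome boundaries
        new_map = self.marker_map.iloc[idx].reset_index(drop=True)
        chrom = new_map["chrom"].to_numpy()
        new_rho[np.nonzero(chrom[1:] != chrom[:-1])[0]] = 1.0
        return ClusterModel(
            K=self.K,
            theta=self.theta[idx],
            alpha=self.alpha[idx],
            rho=np.clip(new_rho, 0.0, 1.0),
            marker_map=new_map,
            gamma_rate=self.gamma_rate,
            loglik=float("nan"),
        )

    def save(self, path) -> None:
        payload = {
            "format_version": MODEL_FORMAT_VERSION,
            "K": self.K,
            "n_markers": self.n_markers,
            "gamma_rate": self.gamma_rate,
            "loglik": self.loglik,
            "theta": np.round(self.theta, 10).tolist(),
            "alpha": np.round(self.alpha, 10).tolist(),
            "rho": np.round(self.rho, 12).tolist(),
            "marker_id": [str(x) for x in self.marker_map["marker_id"]],
            "chrom": [str(x) for x in self.marker_map["chrom"]],
            "pos": [int(x) for x in self.marker_map["pos"]],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "ClusterModel":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format version {payload.get('format_version')!r}"
            )
        marker_map = pd.DataFrame(
            {
                "marker_id": payload["marker_id"],
                "chrom": payload["chrom"],
                "pos": payload["pos"],
            }
        )
        alpha = np.array(payload["alpha"])
        alpha /= alpha.sum(axis=1, keepdims=True)
        return cls(
            K=payload["K"],
            theta=np.array(payload["theta"]),
            alpha=alpha,
            rho=np.array(payload["rho"]),
            marker_map=marker_map,
            gamma_rate=payload["gamma_rate"],
            loglik=payload["loglik"],
        )


def _distances_and_boundaries(marker_map: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    pos = marker_map["pos"].to_numpy(dtype=np.float64)
    chrom = marker_map["chrom"].to_numpy()
    d = np.diff(pos)
    boundary = chrom[1:] != chrom[:-1]
    d[boundary] = 0.0
    return d, boundary


def _jump_probs(gamma_rate: float, d: np.ndarray, boundary: np.ndarray) -> np.ndarray:
    rho = 1.0 - np.exp(-gamma_rate * d)
    rho[boundary] = 1.0
    return rho


def _update_gamma_rate(
    gamma_rate: float, jump_mass: np.ndarray, n_hap: int,
    d: np.ndarray, boundary: np.ndarray,
) -> float:
    """1-D maximization of the expected jump log-likelihood over the rate.

    Generalized EM step: the candidate is kept only if it does not decrease
    the objective at the current expected jump counts.
    """
    keep = ~boundary & (d > 0)
    if not np.any(keep):
        return gamma_rate
    J = jump_mass[keep]
    dk = d[keep]

    def neg_q(log_g: float) -> float:
        g = np.exp(log_g)
        rho = -np.expm1(-g * dk)
        rho = np.clip(rho, 1e-300, 1.0 - 1e-15)
        return -float(np.sum(J * np.log(rho) - (n_hap - J) * g * dk))

    res = minimize_scalar(neg_q, bounds=(np.log(1e-10), np.log(1e-2)),
                          method="bounded", options={"xatol": 1e-4})
    if res.success and neg_q(res.x) <= neg_q(np.log(gamma_rate)):
        return float(np.exp(res.x))
    return gamma_rate


def fit_cluster_model(
    panel: ReferencePanel,
    K: int,
    n_starts: int = 1,
    max_iter: int = 50,
    seed: int = 0,
    tol: float = 1e-6,
    init_gamma_rate: float = 1e-5,
) -> list[ClusterModel]:
    """Fit the cluster HMM to a phased panel by EM, one model per random start.

    The E-step runs independent scaled forward-backward recursions per panel
    haplotype; M-step updates are exact (weighted allele fractions for theta,
    normalized expected jump landings for alpha) except for the jump rate,
    which is a guarded 1-D numerical maximization.  The panel log-likelihood
    is non-decreasing over iterations and recorded in ``loglik_trace``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if panel.n_haplotypes < 2 or panel.n_markers < 2:
        raise ValueError("panel must have at least 2 haplotypes and 2 markers")
    if K > panel.n_haplotypes:
        warnings.warn(
            f"K={K} exceeds the panel haplotype count {panel.n_haplotypes}; "
            "fitting anyway", stacklevel=2,
        )
    haps = np.ascontiguousarray(panel.alleles)
    H, M = haps.shape
    freq = panel.allele_frequencies()
    d, boundary = _distances_and_boundaries(panel.marker_map)

    models: list[ClusterModel] = []
    for s in range(n_starts):
        rng = np.random.default_rng(seed + s)
        # seed clusters from distinct panel haplotypes (softened toward the
        # panel frequency): starts them well separated, which EM preserves
        pick = rng.choice(H, size=K, replace=K > H)
        theta = np.clip(
            0.82 * haps[pick].T + 0.12 * freq[:, None]
            + rng.uniform(0.0, 0.06, size=(M, K)),
            THETA_FLOOR, 1.0 - THETA_FLOOR,
        )
        alpha = rng.dirichlet(np.full(K, 5.0), size=M)
        gamma_rate = init_gamma_rate
        rho = _jump_probs(gamma_rate, d, boundary)
        trace: list[float] = []
        for _ in range(max_iter):
            ll, occ, occ_b, land, jump_mass = hap_fb_stats(haps, theta, alpha, rho)
            if trace and ll < trace[-1] - 1e-6 * abs(trace[-1]):
                warnings.warn("EM log-likelihood decreased; stopping", stacklevel=2)
                break
            converged = bool(trace) and (ll - trace[-1]) < tol * abs(ll)
            trace.append(ll)
            if converged:
                break
            theta = np.clip(
                occ_b / np.maximum(occ, 1e-12), THETA_FLOOR, 1.0 - THETA_FLOOR
            )
            land_tot = land.sum(axis=1)
            upd = land_tot > 1e-10
            alpha[upd] = land[upd] / land_tot[upd, None]
            gamma_rate = _update_gamma_rate(gamma_rate, jump_mass, H, d, boundary)
            rho = _jump_probs(gamma_rate, d, boundary)
        final_ll, *_ = hap_fb_stats(haps, theta, alpha, rho)
        trace.append(final_ll)
        models.append(
            ClusterModel(
                K=K, theta=theta, alpha=alpha, rho=rho,
                marker_map=panel.marker_map.copy(),
                gamma_rate=gamma_rate, loglik=final_ll, loglik_trace=trace,
            )
        )
    return models


def genotype_prob(model: ClusterModel, m: int, z: tuple[int, int], g: int) -> float:
    """P(genotype g | ordered cluster pair z) at marker m.

    Each haplotype draws its allele independently from its cluster's
    frequency, so the genotype is the sum of two Bernoulli draws.
    """
    t1 = model.theta[m, z[0]]
    t2 = model.theta[m, z[1]]
    if g == 0:
        return (1.0 - t1) * (1.0 - t2)
    if g == 1:
        return t1 * (1.0 - t2) + (1.0 - t1) * t2
    if g == 2:
        return t1 * t2
    raise ValueError(f"genotype must be 0, 1 or 2, got {g!r}")


def config_prob(model: ClusterModel, m: int, z: tuple[int, int]) -> float:
    """P(haplotype 1 carries the B allele | heterozygous genotype, z).

    Degenerate cluster pairs (both frequencies exactly 0 or exactly 1, so a
    heterozygote is impossible) fall back to the uninformative value 0.5.
    """
    t1 = model.theta[m, z[0]]
    t2 = model.theta[m, z[1]]
    den = t1 * (1.0 - t2) + (1.0 - t1) * t2
    if den == 0.0:
        return 0.5
    return t1 * (1.0 - t2) / den


@dataclass
class PairTransition:
    """Factorized transition of the ordered cluster-pair chain over one interval.

    Each haplotype independently stays with probability ``1 - rho`` or jumps
    to a cluster drawn from ``alpha_next``; the pair chain is the product of
    the two single-haplotype chains and is never stored densely.
    """

    rho: float
    alpha_next: np.ndarray

    def single_matrix(self) -> np.ndarray:
        K = len(self.alpha_next)
        return (1.0 - self.rho) * np.eye(K) + self.rho * np.tile(
            self.alpha_next, (K, 1)
        )

    def pair_matrix(self) -> np.ndarray:
        """Dense K^2 x K^2 matrix, for inspection and testing only."""
        T = self.single_matrix()
        return np.kron(T, T)


def pair_transition(model: ClusterModel, m: int) -> PairTransition:
    """Transition description for (z_m -> z_{m+1}); ``m`` is the interval index."""
    if not 0 <= m < model.n_markers - 1:
        raise IndexError("interval index out of range")
    return PairTransition(rho=float(model.rho[m]), alpha_next=model.alpha[m + 1].copy())


def sample_diploid(
    model: ClusterModel, seed: int | None = None, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw two independent haplotypes (alleles and latent cluster paths).

    Returns ``(haps, paths)`` with shapes (2, M); deterministic given seed.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    M, K = model.theta.shape
    haps = np.empty((2, M), dtype=np.int8)
    paths = np.empty((2, M), dtype=np.int64)
    idx = np.arange(M)
    for a in range(2):
        jumps = rng.random(M - 1) < model.rho
        draw_at = np.concatenate([[0], np.nonzero(jumps)[0] + 1])
        u = rng.random(len(draw_at))
        cum = np.cumsum(model.alpha[draw_at], axis=1)
        ks = (u[:, None] > cum).sum(axis=1).clip(max=K - 1)
        paths[a] = np.repeat(ks, np.diff(np.concatenate([draw_at, [M]])))
        haps[a] = (rng.random(M) < model.theta[idx, paths[a]]).astype(np.int8)
    return haps, paths


def hap_posterior(model: ClusterModel, hap: np.ndarray) -> tuple[np.ndarray, float]:
    """Posterior cluster memberships of one haplotype, plus its log-likelihood."""
    hap = np.ascontiguousarray(hap, dtype=np.int8)[None, :]
    ll, occ, *_ = hap_fb_stats(hap, model.theta, model.alpha, model.rho)
    return occ, ll
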