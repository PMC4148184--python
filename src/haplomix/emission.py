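"""BAF and LRR emission model under tumor-normal admixture.

At a germline heterozygous marker the expected BAF is a copy-number-weighted
average of the contributions of normal cells (one B of two copies) and
aberrant cells (``c_B`` copies of the B-carrying haplotype out of
``c1 + c2``), where ``w`` is the aberrant-cell proportion:

    mu_b = [(1 - w) + w c_B] / [(1 - w) 2 + w (c1 + c2)]

The LRR mean follows the admixed total copy number on the log2 scale with a
sample-specific scale coefficient ``q``, a baseline offset ``o`` and an
optional linear GC-content correction.  Both channels are modelled as normal
around these means and are conditionally independent given the aberration
state and haplotype configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

from .states import AberrationState

__all__ = ["TumorParams", "baf_mean", "lrr_mean", "marker_emission"]

_SQRT2PI = math.sqrt(2.0 * math.pi)


def _normpdf(x: float, mu: float, sigma: float) -> float:
    z = (x - mu) / sigma
    return math.exp(-0.5 * z * z) / (sigma * _SQRT2PI)


@dataclass
class TumorParams:
    """Sample-level emission parameters.

    w
        Aberrant-cell (tumor) proportion of the DNA mixture, in [0, 1).
    sigma_b
        Standard deviation of BAF at heterozygous markers.
    sigma_r
        Standard deviation of LRR.
    o
        LRR baseline offset (value at normal diploid copy number).
    q
        Sample-specific LRR scale coefficient multiplying log2(copy ratio).
    gc_coef
        Linear coefficient on mean-centered GC content; 0 when no GC track.
    """

    w: float
    sigma_b: float = 0.03
    sigma_r: float = 0.18
    o: float = 0.0
    q: float = 1.0
    gc_coef: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.w < 1.0:
            raise ValueError("tumor proportion w must be in [0, 1)")
        if self.sigma_b <= 0 or self.sigma_r <= 0:
            raise ValueError("sigma_b and sigma_r must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


def baf_mean(state: AberrationState, b_on_hap1: bool, w: float) -> float:
    """Expected BAF at a germline heterozygous marker.

    ``b_on_hap1`` selects which haplotype carries the B allele.  Returns 0.5
    for any balanced state or when ``w = 0``.
    """
    denom = (1.0 - w) * 2.0 + w * state.total
    if denom <= 0.0:
        raise ValueError("undefined BAF mean: no DNA in the mixture")
    c_b = state.c1 if b_on_hap1 else state.c2
    return ((1.0 - w) + w * c_b) / denom


def lrr_mean(state: AberrationState, params: TumorParams, gc_m: float = 0.0) -> float:
    """Expected LRR: ``o + q log2(admixed copy number / 2) + gc_coef * gc``."""
    mix = (1.0 - params.w) * 2.0 + params.w * state.total
    if mix <= 0.0:
        raise ValueError("undefined LRR mean: total admixed copy number is zero")
    return params.o + params.q * math.log2(mix / 2.0) + params.gc_coef * gc_m


def marker_emission(
    b,
    r,
    g,
    state: AberrationState,
    z: tuple[int, int],
    cluster_model,
    params: TumorParams,
    m: int,
    use_lrr: bool = True,
    gc_m: float = 0.0,
) -> float:
    """Joint BAF x LRR emission density at one marker.

    The BAF factor is a two-component normal mixture over the haplotype
    configurations at heterozygous markers, with mixture weights given by the
    configuration probability of the cluster pair ``z``; it is 1 at
    homozygous or genotype-missing markers, where BAF carries no information
    about the aberration state.  Missing channels contribute a factor of 1.
    The germline genotype probability ``P(g | z)`` is a separate factor of
    the haplotype chain and is not included here.
    """
    from .cluster import config_prob

    density = 1.0
    if use_lrr and r is not None and not math.isnan(r):
        density *= _normpdf(r, lrr_mean(state, params, gc_m), params.sigma_r)
    if g == 1 and b is not None and not math.isnan(b):
        p1 = config_prob(cluster_model, m, z)
        mu1 = baf_mean(state, True, params.w)
        mu2 = baf_mean(state, False, params.w)
        density *= p1 * _normpdf(b, mu1, params.sigma_b) + (1.0 - p1) * _normpdf(
            b, mu2, params.sigma_b
        )
    return density
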