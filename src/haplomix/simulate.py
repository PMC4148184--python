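"""Model-matched synthetic data: panels, individuals, aberrations, arrays.

The simulator emulates a low-purity "computational dilution" experiment on a
genome-wide SNP array (370K-like density, one marker per ~9 kb by default):
population haplotypes with linkage disequilibrium are drawn from a random
haplotype-cluster model, a diploid individual is sampled from them, segmental
aberrations (hemizygous deletions and cn-LOH by default) are placed along the
genome, and BAF/LRR observations are drawn from the mixture emission model at
the requested aberrant-cell proportion.  Everything is seeded and
reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cluster import ClusterModel, sample_diploid
from .emission import TumorParams, baf_mean, lrr_mean
from .io import MarkerTable
from .panel import ReferencePanel
from .states import AberrationState

__all__ = [
    "Region",
    "SimulationSpec",
    "simulate_panel",
    "sample_regions",
    "simulate_sample",
]


@dataclass(frozen=True)
class Region:
    """An aberrant segment: marker index range [start, end) on one chromosome."""

    chrom: str
    start: int  # marker index within the chromosome, 0-based
    end: int  # exclusive
    state: AberrationState

    @property
    def n_markers(self) -> int:
        return self.end - self.start


@dataclass
class SimulationSpec:
    """Study design for one synthetic mixed sample.

    Defaults reproduce the low-purity dilution regime: ~80k markers at one
    marker per 9 kb, 10% of the genome aberrant in hemizygous-deletion and
    cn-LOH segments whose lengths follow a truncated log-normal on
    [250, 10720] markers with mean ~2918, BAF dispersion 0.03 and LRR
    dispersion 0.18.
    """

    purity: float = 0.05
    n_chromosomes: int = 6
    markers_per_chrom: int = 13400
    spacing_bp: int = 9000
    aberrant_fraction: float = 0.1
    length_bounds: tuple[int, int] = (250, 10720)
    length_mean: float = 2918.0
    length_log_sd: float = 0.9
    allowed_states: tuple[AberrationState, ...] = (
        AberrationState(1, 0),  # hemizygous deletion
        AberrationState(2, 0),  # cn-LOH
    )
    # target share of aberrant markers per allowed state; the dilution design
    # placed roughly two thirds of aberrant markers in deletions and one
    # third in cn-LOH.  None = uniform random type per region.
    state_marker_share: tuple[float, ...] | None = (0.683, 0.317)
    regions: list[Region] | None = None  # explicit plan overrides sampling
    sigma_b: float = 0.03
    sigma_r: float = 0.18
    hom_sigma_b: float = 0.01
    o: float = 0.0
    q: float = 1.0
    gc_track: bool = False
    gc_coef: float = 0.0
    seed: int = 0

    @property
    def n_markers(self) -> int:
        return self.n_chromosomes * self.markers_per_chrom

    def tumor_params(self) -> TumorParams:
        return TumorParams(
            w=self.purity, sigma_b=self.sigma_b, sigma_r=self.sigma_r,
            o=self.o, q=self.q, gc_coef=self.gc_coef if self.gc_track else 0.0,
        )


def _sample_cluster_path(
    alpha: np.ndarray, rho: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized draw of one cluster path from the jump chain."""
    M = alpha.shape[0]
    jumps = rng.random(M - 1) < rho
    draw_at = np.concatenate([[0], np.nonzero(jumps)[0] + 1])
    u = rng.random(len(draw_at))
    cum = np.cumsum(alpha[draw_at], axis=1)
    ks = (u[:, None] > cum).sum(axis=1).clip(max=alpha.shape[1] - 1)
    seg_len = np.diff(np.concatenate([draw_at, [M]]))
    return np.repeat(ks, seg_len)


def _marker_map(n_chromosomes: int, markers_per_chrom: int, spacing: int) -> pd.DataFrame:
    chroms = np.repeat(
        [f"chr{i + 1}" for i in range(n_chromosomes)], markers_per_chrom
    )
    pos = np.tile(
        (np.arange(markers_per_chrom, dtype=np.int64) + 1) * spacing,
        n_chromosomes,
    )
    ids = np.array(
        [f"m{i + 1}" for i in range(n_chromosomes * markers_per_chrom)], dtype=object
    )
    return pd.DataFrame({"marker_id": ids, "chrom": chroms, "pos": pos})


def random_cluster_model(
    n_markers: int,
    K_true: int,
    seed: int = 0,
    n_chromosomes: int = 1,
    spacing_bp: int = 9000,
    jump_rate: float = 3e-6,
) -> ClusterModel:
    """A random generating cluster model with distance-decaying LD.

    Cluster allele frequencies are Beta-distributed around a random
    per-marker population frequency with small concentration, so clusters
    carry near-fixed alleles and markers are strongly informative about
    cluster identity (as in real haplotype-cluster fits).
    """
    rng = np.random.default_rng(seed)
    if n_markers % n_chromosomes:
        raise ValueError("n_markers must be divisible by n_chromosomes")
    per = n_markers // n_chromosomes
    marker_map = _marker_map(n_chromosomes, per, spacing_bp)
    base = rng.uniform(0.05, 0.95, size=n_markers)
    conc = 0.5
    theta = rng.beta(conc * base[:, None], conc * (1.0 - base[:, None]),
                     size=(n_markers, K_true))
    theta = np.clip(theta, 1e-4, 1.0 - 1e-4)
    alpha = rng.dirichlet(np.full(K_true, 5.0), size=n_markers)
    d = np.diff(marker_map["pos"].to_numpy(dtype=float))
    rho = 1.0 - np.exp(-jump_rate * d)
    boundary = marker_map["chrom"].to_numpy()[1:] != marker_map["chrom"].to_numpy()[:-1]
    rho[boundary] = 1.0
    return ClusterModel(
        K=K_true, theta=theta, alpha=alpha, rho=rho, marker_map=marker_map,
        gamma_rate=jump_rate,
    )


def simulate_panel(
    n_haplotypes: int,
    n_markers: int,
    K_true: int,
    seed: int = 0,
    n_chromosomes: int = 1,
    spacing_bp: int = 9000,
) -> tuple[ReferencePanel, ClusterModel]:
    """Draw a phased reference panel from a random cluster model.

    Returns the panel together with the generating model so that fitting can
    be validated against the truth.
    """
    model = random_cluster_model(
        n_markers, K_true, seed=seed, n_chromosomes=n_chromosomes,
        spacing_bp=spacing_bp,
    )
    rng = np.random.default_rng(seed + 1)
    M, _ = model.theta.shape
    alleles = np.empty((n_haplotypes, M), dtype=np.int8)
    idx = np.arange(M)
    for h in range(n_haplotypes):
        path = _sample_cluster_path(model.alpha, model.rho, rng)
        alleles[h] = (rng.random(M) < model.theta[idx, path]).astype(np.int8)
    panel = ReferencePanel(alleles=alleles, marker_map=model.marker_map.copy())
    return panel, model


def _truncated_lognormal_mu(mean: float, sd_log: float, lo: float, hi: float) -> float:
    """Location parameter so the [lo, hi]-truncated log-normal has the target mean."""
    from scipy.stats import truncnorm

    def trunc_mean(mu):
        a = (np.log(lo) - mu) / sd_log
        b = (np.log(hi) - mu) / sd_log
        # E[exp(X)] for X ~ truncated normal(mu, sd) on [log lo, log hi]
        dist = truncnorm(a, b, loc=mu, scale=sd_log)
        # numerically stable expectation by quadrature on the log scale
        xs = np.linspace(np.log(lo), np.log(hi), 2001)
        pdf = dist.pdf(xs)
        return float(np.trapezoid(np.exp(xs) * pdf, xs) / np.trapezoid(pdf, xs))

    return brentq(
        lambda mu: trunc_mean(mu) - mean, np.log(lo) - 2, np.log(hi) + 2, xtol=1e-6
    )


def sample_region_lengths(
    n: int, rng: np.random.Generator,
    bounds: tuple[int, int] = (250, 10720),
    mean: float = 2918.0, sd_log: float = 0.9,
) -> np.ndarray:
    """Lengths (markers) from a log-normal truncated to ``bounds`` with given mean."""
    lo, hi = bounds
    mu = _truncated_lognormal_mu(mean, sd_log, lo, hi)
    out = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        draw = np.exp(rng.normal(mu, sd_log, size=2 * (n - filled)))
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(ok), n - filled)
        out[filled : filled + take] = np.round(ok[:take]).astype(np.int64)
        filled += take
    return out


def sample_regions(spec: SimulationSpec, seed: int | None = None) -> list[Region]:
    """Sample non-overlapping aberrant regions matching the design fraction.

    Lengths are drawn from the truncated log-normal until the target
    aberrant marker count is covered, aberration types are assigned greedily
    so realized marker shares track ``state_marker_share``, haplotype
    orientation is random, and regions are placed uniformly at random
    without overlap within chromosomes.
    """
    if spec.regions is not None:
        return list(spec.regions)
    if spec.aberrant_fraction == 0:
        return []
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    target = spec.aberrant_fraction * spec.n_markers
    lo, hi = spec.length_bounds
    if lo > spec.markers_per_chrom:
        raise ValueError("minimum region length exceeds chromosome length")
    lengths: list[int] = []
    while sum(lengths) < target:
        remaining = target - sum(lengths)
        ln = None
        for _ in range(50):  # keep the realized fraction near the design value
            cand = int(
                sample_region_lengths(
                    1, rng, spec.length_bounds, spec.length_mean,
                    spec.length_log_sd,
                )[0]
            )
            if cand > spec.markers_per_chrom:
                continue
            if cand <= remaining + 0.3 * target:
                ln = cand
                break
            ln = cand if ln is None else min(ln, cand)
        lengths.append(int(ln))
    # random placement, longest first to ease packing
    lengths.sort(reverse=True)
    # assign states so realized marker shares track the design composition
    if spec.state_marker_share is not None:
        share = np.asarray(spec.state_marker_share, dtype=float)
        if len(share) != len(spec.allowed_states):
            raise ValueError("state_marker_share must align with allowed_states")
        share = share / share.sum()
        assigned = np.zeros(len(share))
        states_for = []
        for ln in lengths:
            deficit = share - assigned / max(assigned.sum() + ln, 1.0)
            j = int(np.argmax(deficit))
            assigned[j] += ln
            states_for.append(spec.allowed_states[j])
    else:
        states_for = [
            spec.allowed_states[rng.integers(len(spec.allowed_states))]
            for _ in lengths
        ]
    free: dict[str, list[tuple[int, int]]] = {
        f"chr{i + 1}": [(0, spec.markers_per_chrom)]
        for i in range(spec.n_chromosomes)
    }
    regions: list[Region] = []
    for ln, state in zip(lengths, states_for):
        placed = False
        for _ in range(1000):
            chrom = f"chr{rng.integers(spec.n_chromosomes) + 1}"
            gaps = [g for g in free[chrom] if g[1] - g[0] >= ln]
            if not gaps:
                continue
            g0, g1 = gaps[rng.integers(len(gaps))]
            start = int(rng.integers(g0, g1 - ln + 1))
            if rng.random() < 0.5:  # random haplotype orientation
                state = state.mirror()
            regions.append(Region(chrom, start, start + ln, state))
            free[chrom].remove((g0, g1))
            if start > g0:
                free[chrom].append((g0, start))
            if start + ln < g1:
                free[chrom].append((start + ln, g1))
            placed = True
            break
        if not placed:
            raise ValueError(
                "could not place all aberrant regions; "
                "aberrant_fraction / length combination infeasible"
            )
    regions.sort(key=lambda r: (int(r.chrom[3:]), r.start))
    return regions


def simulate_sample(
    spec: SimulationSpec,
    cluster_model: ClusterModel,
    seed: int | None = None,
) -> tuple[MarkerTable, pd.DataFrame, list[Region]]:
    """Generate one mixed sample plus its per-marker truth.

    A diploid individual is drawn from the cluster model, aberrant regions
    are assigned, and BAF/LRR are sampled from the emission model: normal
    around the configuration-specific mean at heterozygous markers (clipped
    to [0, 1]), tight bands at 0/1 for homozygous markers, normal LRR
    everywhere.  Returns ``(table, truth, regions)``; the truth table
    records the ordered state, collapsed category, true genotype and the
    over-represented allele at each marker.
    """
    if cluster_model.n_markers != spec.n_markers:
        raise ValueError("cluster model marker count does not match spec")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    haps, _ = sample_diploid(cluster_model, rng=rng)
    regions = sample_regions(spec, seed=int(rng.integers(2**31 - 1)))
    M = spec.n_markers
    mm = cluster_model.marker_map
    chrom_arr = mm["chrom"].to_numpy()
    chrom_start = {c: np.nonzero(chrom_arr == c)[0][0] for c in pd.unique(chrom_arr)}

    c1 = np.ones(M, dtype=np.int64)
    c2 = np.ones(M, dtype=np.int64)
    for reg in regions:
        off = chrom_start[reg.chrom]
        c1[off + reg.start : off + reg.end] = reg.state.c1
        c2[off + reg.start : off + reg.end] = reg.state.c2

    params = spec.tumor_params()
    gt = haps[0] + haps[1]
    het = gt == 1
    b_on_hap1 = haps[0] == 1

    gc = rng.normal(0.0, 1.0, size=M) if spec.gc_track else np.zeros(M)
    w = spec.purity
    den = (1.0 - w) * 2.0 + w * (c1 + c2)
    c_b = np.where(b_on_hap1, c1, c2)
    mu_het = ((1.0 - w) + w * c_b) / den
    # homozygous bands barely move at low purity; model as tight 0/1 bands
    mu_hom = np.where(gt == 0, 0.0, 1.0)
    mu_b = np.where(het, mu_het, mu_hom)
    sd_b = np.where(het, spec.sigma_b, spec.hom_sigma_b)
    baf = np.clip(rng.normal(mu_b, sd_b), 0.0, 1.0)
    mu_r = params.o + params.q * np.log2(den / 2.0) + params.gc_coef * gc
    lrr = rng.normal(mu_r, spec.sigma_r)

    df = mm.copy()
    df["baf"] = baf
    df["lrr"] = lrr
    if spec.gc_track:
        df["gc"] = gc
    table = MarkerTable(df)

    over = np.where(
        c1 == c2, "balanced",
        np.where(
            het,
            np.where((c1 > c2) == b_on_hap1, "B", "A"),
            "balanced",
        ),
    )
    truth = pd.DataFrame(
        {
            "marker_id": mm["marker_id"],
            "chrom": mm["chrom"],
            "pos": mm["pos"],
            "state": [f"{a}-{b}" for a, b in zip(c1, c2)],
            "category": [f"{max(a, b)}-{min(a, b)}" for a, b in zip(c1, c2)],
            "genotype": gt,
            "b_on_hap1": b_on_hap1,
            "over_represented": over,
        }
    )
    return table, truth, regions


def regions_to_bed(regions: list[Region], marker_map: pd.DataFrame) -> pd.DataFrame:
    """Aberrant regions as 0-based half-open BED intervals in bp."""
    rows = []
    for reg in regions:
        block = marker_map[marker_map["chrom"] == reg.chrom]
        pos = block["pos"].to_numpy()
        rows.append(
            {
                "chrom": reg.chrom,
                "start": int(pos[reg.start]) - 1,
                "end": int(pos[reg.end - 1]),
                "category": reg.state.category,
                "n_markers": reg.n_markers,
            }
        )
    return pd.DataFrame(rows)
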