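"""Joint inference on the (aberration x haplotype-pair) chain.

The hidden state at marker m is the pair (l_m, z_m): the aberration state
and the ordered cluster pair.  The two chains are a priori independent;
conditioning on both renders the observed BAF/LRR independent across
markers.  Exact posterior marginals come from scaled forward-backward
recursions per chromosome (chromosomes are independent, each restarting
from the stationary aberration distribution and the cluster weights).

Sample-level emission parameters (tumor proportion w, BAF/LRR dispersions,
LRR baseline/scale, GC coefficient) are estimated by a generalized EM:
the E-step collects posterior-weighted sufficient statistics; the M-step
profiles the LRR regression parameters and both variances in closed form
within a bounded 1-D search over w.  With several cluster-model fits
(random EM restarts of the haplotype model), the engine runs once per fit
and averages the collapsed per-marker posteriors across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from ._kernels import joint_fb, joint_loglik
from .cluster import ClusterModel
from .emission import TumorParams
from .io import MarkerTable
from .panel import chrom_bounds
from .states import (
    AberrationTPMSpec,
    StateSpace,
    build_tpm,
    enumerate_states,
    reduced_state_space,
    stationary_distribution,
)

logger = logging.getLogger("haplomix")

__all__ = [
    "JointPosterior",
    "forward_backward",
    "em_fit",
    "grid_init_w",
    "call_states",
    "overrepresented_posterior",
    "DEFAULT_W_GRID",
]

DEFAULT_W_GRID = np.round(np.arange(0.06, 0.3001, 0.02), 10)
W_BOUNDS = (1e-4, 0.6)


@dataclass
class JointPosterior:
    """Per-marker posteriors over collapsed report categories plus fit summary."""

    marker_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    genotype: np.ndarray
    space: StateSpace
    cat_probs: np.ndarray  # (M, n_categories), averaged over runs
    p_b_over: np.ndarray  # P(B allele over-represented), het markers
    p_a_over: np.ndarray
    cluster_amp: np.ndarray  # (M, K) P(over-represented haplotype from cluster k)
    loglik: float
    params: TumorParams
    n_iterations: int = 0
    converged: bool = True
    run_params: list = field(default_factory=list)
    run_logliks: list = field(default_factory=list)
    run_n_iterations: list = field(default_factory=list)
    run_w_traces: list = field(default_factory=list)
    run_loglik_traces: list = field(default_factory=list)
    run_cat_probs: list = field(default_factory=list)

    def __post_init__(self) -> None:
        sums = self.cat_probs.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-8):
            raise ValueError("category probabilities must sum to 1 per marker")
        if not np.isfinite(self.loglik):
            raise ValueError("log-likelihood must be finite")

    @property
    def p_balanced(self) -> np.ndarray:
        return 1.0 - self.p_b_over - self.p_a_over

    @property
    def p_aberrant(self) -> np.ndarray:
        """1 - P(normal category); used for ROC construction."""
        return 1.0 - self.cat_probs[:, self.space.normal_category_index]

    def modal_category(self) -> np.ndarray:
        """Per-marker modal report category; ties broken toward normal."""
        ni = self.space.normal_category_index
        idx = np.argmax(self.cat_probs, axis=1)
        best = self.cat_probs[np.arange(len(idx)), idx]
        idx[self.cat_probs[:, ni] >= best - 1e-12] = ni
        return np.array(self.space.categories, dtype=object)[idx]

    def to_marker_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "marker_id": self.marker_ids,
                "chrom": self.chrom,
                "pos": self.pos,
                "genotype": self.genotype,
            }
        )
        for j, cat in enumerate(self.space.categories):
            df[f"p_{cat}"] = self.cat_probs[:, j]
        df["p_b_over"] = self.p_b_over
        df["modal_category"] = self.modal_category()
        return df


@dataclass
class _EStep:
    loglik: float
    gamma_l: np.ndarray  # (M, L)
    A: np.ndarray  # (M, L) joint P(state, B on haplotype 1) at het markers
    amp: np.ndarray  # (M, K)
    n_norm: float
    n_ab: float
    n_exit: float
    n_enter: float


def _table_arrays(table: MarkerTable):
    g = np.ascontiguousarray(table.genotype, dtype=np.int8)
    b = np.ascontiguousarray(table.baf, dtype=np.float64)
    r = np.ascontiguousarray(table.lrr, dtype=np.float64)
    gc = np.ascontiguousarray(table.gc, dtype=np.float64)
    return g, b, r, gc


def _check_alignment(table: MarkerTable, model: ClusterModel) -> None:
    if len(table) != model.n_markers or not np.array_equal(
        table.marker_ids, model.marker_ids
    ):
        raise ValueError(
            "sample table and cluster model are not aligned; "
            "run intersect_markers first"
        )


def _resolve_space(space: StateSpace | None, reduced_states: bool) -> StateSpace:
    if space is not None:
        return space
    return reduced_state_space() if reduced_states else enumerate_states(5)


def _e_step(
    table: MarkerTable,
    model: ClusterModel,
    params: TumorParams,
    tpm: np.ndarray,
    pi_l: np.ndarray,
    space: StateSpace,
    use_lrr: bool,
) -> _EStep:
    g, b, r, gc = _table_arrays(table)
    c1, c2 = space.c_arrays()
    M = len(table)
    L = len(space)
    gamma_l = np.empty((M, L))
    A = np.empty((M, L))
    amp = np.empty((M, model.K))
    total_ll = 0.0
    n_norm = n_ab = n_exit = n_enter = 0.0
    for start, stop in chrom_bounds(table.chrom):
        if stop - start < 2:
            logger.warning("skipping chromosome block with < 2 markers")
            gamma_l[start:stop] = pi_l
            A[start:stop] = 0.0
            amp[start:stop] = 0.0
            continue
        ll, gl, a, am, nn, na, ne, nen = joint_fb(
            g[start:stop], b[start:stop], r[start:stop], gc[start:stop],
            model.theta[start:stop], model.alpha[start:stop],
            model.rho[start : stop - 1],
            tpm, pi_l, c1, c2, space.normal_state_index,
            params.w, params.sigma_b, params.sigma_r, params.o, params.q,
            params.gc_coef, use_lrr,
        )
        total_ll += ll
        gamma_l[start:stop] = gl
        A[start:stop] = a
        amp[start:stop] = am
        n_norm += nn
        n_ab += na
        n_exit += ne
        n_enter += nen
    return _EStep(total_ll, gamma_l, A, amp, n_norm, n_ab, n_exit, n_enter)


def _posterior_from_estep(
    table: MarkerTable,
    model: ClusterModel,
    est: _EStep,
    space: StateSpace,
    params: TumorParams,
) -> dict:
    c1, c2 = space.c_arrays()
    cat_probs = space.collapse(est.gamma_l)
    over1 = c1 > c2  # haplotype 1 over-represented
    over2 = c2 > c1
    B = est.gamma_l - est.A
    het = table.genotype == 1
    p_b = np.where(het, est.A @ over1.astype(float) + B @ over2.astype(float), 0.0)
    p_a = np.where(het, est.A @ over2.astype(float) + B @ over1.astype(float), 0.0)
    return {
        "cat_probs": cat_probs,
        "p_b_over": p_b,
        "p_a_over": p_a,
        "cluster_amp": est.amp,
        "loglik": est.loglik,
        "params": params,
    }


def forward_backward(
    table: MarkerTable,
    cluster_model: ClusterModel,
    params: TumorParams,
    tpm_spec: AberrationTPMSpec | None = None,
    *,
    tpm: np.ndarray | None = None,
    space: StateSpace | None = None,
    use_lrr: bool = True,
    reduced_states: bool = False,
) -> JointPosterior:
    """Exact posterior decoding at fixed emission parameters."""
    _check_alignment(table, cluster_model)
    space = _resolve_space(space, reduced_states)
    if tpm_spec is None:
        tpm_spec = AberrationTPMSpec()
    if tpm is None:
        tpm = build_tpm(tpm_spec, space)
    pi_l = stationary_distribution(tpm_spec, space)
    est = _e_step(table, cluster_model, params, tpm, pi_l, space, use_lrr)
    parts = _posterior_from_estep(table, cluster_model, est, space, params)
    return JointPosterior(
        marker_ids=table.marker_ids,
        chrom=table.chrom,
        pos=table.pos,
        genotype=table.genotype,
        space=space,
        **parts,
    )


def grid_init_w(
    table: MarkerTable,
    cluster_model: ClusterModel,
    tpm_spec: AberrationTPMSpec | None = None,
    grid=None,
    *,
    space: StateSpace | None = None,
    use_lrr: bool = True,
    base_params: TumorParams | None = None,
) -> float:
    """Likelihood grid search for the initial tumor proportion.

    Evaluates the observed-data log-likelihood at each grid value with the
    other parameters at defaults and returns the argmax; ties go to the
    smaller proportion.  The default grid is 6% to 30% in steps of 2%.
    """
    _check_alignment(table, cluster_model)
    if grid is None:
        grid = DEFAULT_W_GRID
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("grid must be non-empty")
    space = _resolve_space(space, False) if space is None else space
    if tpm_spec is None:
        tpm_spec = AberrationTPMSpec()
    tpm = build_tpm(tpm_spec, space)
    pi_l = stationary_distribution(tpm_spec, space)
    g, b, r, gc = _table_arrays(table)
    c1, c2 = space.c_arrays()
    defaults = base_params or TumorParams(w=0.0)
    best_w, best_ll = None, -np.inf
    for w in grid:
        ll = 0.0
        for start, stop in chrom_bounds(table.chrom):
            if stop - start < 2:
                continue
            ll += joint_loglik(
                g[start:stop], b[start:stop], r[start:stop], gc[start:stop],
                cluster_model.theta[start:stop], cluster_model.alpha[start:stop],
                cluster_model.rho[start : stop - 1],
                tpm, pi_l, c1, c2,
                float(w), defaults.sigma_b, defaults.sigma_r, defaults.o,
                defaults.q, defaults.gc_coef, use_lrr,
            )
        logger.debug("grid w=%.3f loglik=%.3f", w, ll)
        if ll > best_ll:
            best_w, best_ll = float(w), ll
    return best_w


class _MStepStats:
    """Posterior-weighted sufficient statistics for the emission M-step.

    Aggregated per aberration state (and per haplotype configuration for the
    BAF channel), so the expected complete-data log-likelihood is a cheap
    function of w and the profiled parameters.
    """

    def __init__(self, table, est: _EStep, space: StateSpace, use_lrr, fit_gc):
        self.space = space
        self.use_lrr = use_lrr
        self.fit_gc = fit_gc
        self.c1, self.c2 = space.c_arrays()
        b, r, gc = table.baf, table.lrr, table.gc
        het = (table.genotype == 1) & ~np.isnan(b)
        gl = est.gamma_l
        # BAF: q[m, l, h] with h=1 <-> B on haplotype 1
        A = est.A[het]
        B = gl[het] - A
        bb = b[het]
        self.S_q = np.stack([A.sum(0), B.sum(0)])  # (2, L)
        self.S_qb = np.stack([A.T @ bb, B.T @ bb])
        self.S_qbb = np.stack([A.T @ bb**2, B.T @ bb**2])
        self.n_het = float(het.sum())
        # LRR
        rk = ~np.isnan(r) if use_lrr else np.zeros(len(r), dtype=bool)
        glr = gl[rk]
        rr = r[rk]
        gcr = gc[rk]
        self.S_w = glr.sum(0)  # (L,)
        self.S_r = glr.T @ rr
        self.S_rr = glr.T @ rr**2
        self.S_g = glr.T @ gcr
        self.S_gg = glr.T @ gcr**2
        self.S_rg = glr.T @ (rr * gcr)
        self.n_lrr = float(rk.sum())

    def _baf_fit(self, w):
        """Profiled sigma_b and BAF residual statistics at proportion w."""
        tot = self.c1 + self.c2
        den = (1.0 - w) * 2.0 + w * tot
        mu = np.stack(
            [((1.0 - w) + w * self.c1) / den, ((1.0 - w) + w * self.c2) / den]
        )  # (2, L)
        ss = float(np.sum(self.S_qbb - 2.0 * mu * self.S_qb + mu**2 * self.S_q))
        n = float(self.S_q.sum())
        sigma_b = max(np.sqrt(max(ss, 0.0) / max(n, 1.0)), 1e-4)
        return sigma_b, ss, n

    def _lrr_fit(self, w):
        """Profiled weighted least squares for (o, q[, gc_coef]) and sigma_r."""
        tot = self.c1 + self.c2
        t = np.log2(((1.0 - w) * 2.0 + w * tot) / 2.0)  # (L,)
        n = float(self.S_w.sum())
        if n == 0:
            return 0.0, 1.0, 0.0, 1.0, 0.0, 0.0
        # normal equations over rows (m, l) with weights gamma
        cols = 3 if self.fit_gc else 2
        XtX = np.empty((cols, cols))
        Xty = np.empty(cols)
        XtX[0, 0] = n
        XtX[0, 1] = XtX[1, 0] = float(t @ self.S_w)
        XtX[1, 1] = float((t**2) @ self.S_w)
        Xty[0] = float(self.S_r.sum())
        Xty[1] = float(t @ self.S_r)
        if self.fit_gc:
            XtX[0, 2] = XtX[2, 0] = float(self.S_g.sum())
            XtX[1, 2] = XtX[2, 1] = float(t @ self.S_g)
            XtX[2, 2] = float(self.S_gg.sum())
            Xty[2] = float(self.S_rg.sum())
        try:
            beta = np.linalg.solve(XtX, Xty)
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(XtX, Xty, rcond=None)[0]
        syy = float(self.S_rr.sum())
        ss = max(syy - float(beta @ Xty), 0.0)
        sigma_r = max(np.sqrt(ss / n), 1e-3)
        o, q = float(beta[0]), float(beta[1])
        gc_coef = float(beta[2]) if self.fit_gc else 0.0
        return o, q, gc_coef, sigma_r, ss, n

    def profiled_q(self, w):
        """Expected complete-data log-likelihood with nuisance params profiled."""
        qv = 0.0
        sigma_b, ss_b, n_b = self._baf_fit(w)
        if n_b > 0:
            qv += -0.5 * n_b * (np.log(2.0 * np.pi * sigma_b**2) + ss_b / (n_b * sigma_b**2))
        if self.use_lrr and self.n_lrr > 0:
            _, _, _, sigma_r, ss_r, n_r = self._lrr_fit(w)
            qv += -0.5 * n_r * (np.log(2.0 * np.pi * sigma_r**2) + ss_r / (n_r * sigma_r**2))
        return qv

    def solve(self, w_current: float) -> TumorParams:
        res = minimize_scalar(
            lambda w: -self.profiled_q(w),
            bounds=W_BOUNDS, method="bounded", options={"xatol": 1e-6},
        )
        w_new = float(res.x)
        # guarded ascent: never move to a w with lower profiled objective
        if self.profiled_q(w_new) < self.profiled_q(w_current):
            w_new = w_current
        sigma_b, _, n_b = self._baf_fit(w_new)
        if n_b == 0:
            sigma_b = 0.03
        if self.use_lrr and self.n_lrr > 0:
            o, q, gc_coef, sigma_r, _, _ = self._lrr_fit(w_new)
        else:
            o, q, gc_coef, sigma_r = 0.0, 1.0, 0.0, 0.18
        return TumorParams(
            w=w_new, sigma_b=sigma_b, sigma_r=sigma_r, o=o, q=q, gc_coef=gc_coef
        )


def em_fit(
    table: MarkerTable,
    cluster_models,
    tpm_spec: AberrationTPMSpec | None = None,
    init="grid",
    max_iter: int = 25,
    tol: float = 1e-4,
    seed: int = 0,
    *,
    grid=None,
    use_lrr: bool = True,
    reduced_states: bool = False,
    space: StateSpace | None = None,
    update_tpm: bool = False,
    fit_gc: bool = False,
    init_params: TumorParams | None = None,
) -> JointPosterior:
    """EM estimation of sample emission parameters, then posterior reporting.

    ``init`` is either ``"grid"`` (likelihood grid search over tumor
    proportions 6%..30%) or a number used as a fixed starting proportion
    (the low-purity protocol uses 0.05).  Stopping: ``max_iter`` EM
    iterations or successive change in the proportion estimate below
    ``tol``, whichever comes first.  With several cluster models, the whole
    EM runs once per model and collapsed posteriors are averaged.

    The aberration-chain TPM is fixed by default; ``update_tpm=True``
    re-estimates its mean event length and aberrant fraction each M-step
    from the expected hub transition counts.
    """
    if isinstance(cluster_models, ClusterModel):
        cluster_models = [cluster_models]
    if not cluster_models:
        raise ValueError("need at least one cluster model")
    space = _resolve_space(space, reduced_states)
    if tpm_spec is None:
        tpm_spec = AberrationTPMSpec()

    runs = []
    for model in cluster_models:
        _check_alignment(table, model)
        cur_spec = AberrationTPMSpec(
            tpm_spec.mean_event_markers, tpm_spec.aberrant_fraction
        )
        tpm = build_tpm(cur_spec, space)
        pi_l = stationary_distribution(cur_spec, space)
        if init == "grid":
            w0 = grid_init_w(
                table, model, cur_spec, grid, space=space, use_lrr=use_lrr,
            )
        else:
            w0 = float(init)
        params = init_params or TumorParams(w=w0)
        if init_params is not None:
            params = TumorParams(**{**init_params.to_dict(), "w": w0})
        w_trace = [params.w]
        ll_trace: list[float] = []
        converged = False
        n_done = 0
        est = None
        for it in range(max_iter):
            est = _e_step(table, model, params, tpm, pi_l, space, use_lrr)
            ll_trace.append(est.loglik)
            stats = _MStepStats(table, est, space, use_lrr, fit_gc)
            new_params = stats.solve(params.w)
            if update_tpm and est.n_exit > 0 and est.n_norm > 0:
                mean_len = min(max(est.n_ab / est.n_exit, 2.0), 1e6)
                p_enter = est.n_enter / est.n_norm
                frac = min(max(p_enter * mean_len / (1.0 + p_enter * mean_len),
                               1e-6), 0.9)
                cur_spec = AberrationTPMSpec(mean_len, frac)
                tpm = build_tpm(cur_spec, space)
                pi_l = stationary_distribution(cur_spec, space)
            delta = abs(new_params.w - params.w)
            params = new_params
            w_trace.append(params.w)
            n_done = it + 1
            logger.debug("EM iter %d: w=%.5f loglik=%.2f", n_done, params.w, est.loglik)
            if delta < tol:
                converged = True
                break
        if not converged:
            logger.warning(
                "EM did not converge in %d iterations (last dw above %g)",
                max_iter, tol,
            )
        est = _e_step(table, model, params, tpm, pi_l, space, use_lrr)
        ll_trace.append(est.loglik)
        parts = _posterior_from_estep(table, model, est, space, params)
        parts.update(
            n_iterations=n_done, converged=converged,
            w_trace=w_trace, ll_trace=ll_trace, tpm_spec=cur_spec,
        )
        runs.append(parts)

    best = max(runs, key=lambda p: p["loglik"])
    n_runs = len(runs)
    jp = JointPosterior(
        marker_ids=table.marker_ids,
        chrom=table.chrom,
        pos=table.pos,
        genotype=table.genotype,
        space=space,
        cat_probs=sum(p["cat_probs"] for p in runs) / n_runs,
        p_b_over=sum(p["p_b_over"] for p in runs) / n_runs,
        p_a_over=sum(p["p_a_over"] for p in runs) / n_runs,
        cluster_amp=sum(p["cluster_amp"] for p in runs) / n_runs,
        loglik=best["loglik"],
        params=best["params"],
        n_iterations=best["n_iterations"],
        converged=all(p["converged"] for p in runs),
        run_params=[p["params"] for p in runs],
        run_logliks=[p["loglik"] for p in runs],
        run_n_iterations=[p["n_iterations"] for p in runs],
        run_w_traces=[p["w_trace"] for p in runs],
        run_loglik_traces=[p["ll_trace"] for p in runs],
        run_cat_probs=[p["cat_probs"] for p in runs],
    )
    return jp


def call_states(
    posterior: JointPosterior, min_markers: int = 1
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-marker modal calls and merged same-category segments.

    Segments shorter than ``min_markers`` are relabelled to the normal
    category before merging (default 1, i.e. no filtering).  Returns
    ``(calls, segments)``; segment positions are 1-based inclusive.
    """
    calls = pd.DataFrame(
        {
            "marker_id": posterior.marker_ids,
            "chrom": posterior.chrom,
            "pos": posterior.pos,
            "category": posterior.modal_category(),
        }
    )
    normal = posterior.space.categories[posterior.space.normal_category_index]
    cat = calls["category"].to_numpy(dtype=object)
    chrom = calls["chrom"].to_numpy()
    cat_probs = posterior.cat_probs
    cat_index = {c: i for i, c in enumerate(posterior.space.categories)}

    def _runs(categories):
        runs = []
        start = 0
        for i in range(1, len(categories) + 1):
            if (
                i == len(categories)
                or categories[i] != categories[start]
                or chrom[i] != chrom[start]
            ):
                runs.append((start, i))
                start = i
        return runs

    if min_markers > 1:
        for start, stop in _runs(cat):
            if cat[start] != normal and stop - start < min_markers:
                cat[start:stop] = normal
        calls["category"] = cat

    rows = []
    for start, stop in _runs(cat):
        c = cat[start]
        rows.append(
            {
                "chrom": chrom[start],
                "start": int(posterior.pos[start]),
                "end": int(posterior.pos[stop - 1]),
                "category": c,
                "n_markers": stop - start,
                "mean_posterior": float(
                    cat_probs[start:stop, cat_index[c]].mean()
                ),
            }
        )
    return calls, pd.DataFrame(rows)


def overrepresented_posterior(posterior: JointPosterior) -> pd.DataFrame:
    """Per-marker over-represented-allele and cluster-amplification posteriors.

    At heterozygous markers, P(B over-represented) integrates over the joint
    (state, configuration) posterior: it is the mass on states where the
    B-carrying haplotype has the larger parent-specific copy number.  At
    homozygous markers the call is 'balanced' with probability 1.
    """
    df = pd.DataFrame(
        {
            "marker_id": posterior.marker_ids,
            "chrom": posterior.chrom,
            "pos": posterior.pos,
            "p_a_over": posterior.p_a_over,
            "p_b_over": posterior.p_b_over,
            "p_balanced": posterior.p_balanced,
        }
    )
    for k in range(posterior.cluster_amp.shape[1]):
        df[f"p_cluster{k + 1}_amp"] = posterior.cluster_amp[:, k]
    return df
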