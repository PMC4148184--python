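"""Numba kernels: scaled forward-backward recursions for both chains.

These are the hot loops.  The joint chain over (aberration state l, ordered
cluster pair z = (k1, k2)) is never materialized as a dense product matrix;
transitions are applied in factorized form (aberration step, then one step
per haplotype chain), so the per-marker cost is O(S * (L + K)) for
S = L * K^2 joint states rather than O(S^2).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_SQRT2PI = math.sqrt(2.0 * math.pi)


@njit(cache=True)
def hap_fb_stats(haps, theta, alpha, rho):
    """Forward-backward over independent single-haplotype cluster chains.

    Parameters: haps (H, M) int8 alleles; theta (M, K) cluster allele
    frequencies; alpha (M, K) cluster weights; rho (M-1,) jump probabilities
    (1.0 at chromosome boundaries, which restarts the chain from alpha).

    Returns (loglik, occ, occ_b, land, jump_mass):
      occ[m, k]   expected number of haplotypes in cluster k at marker m
      occ_b[m, k] same, restricted to haplotypes carrying the B allele
      land[0, k]  expected initial occupancy; land[m, k] (m >= 1) expected
                  number of jumps landing in cluster k at marker m
      jump_mass[m] expected number of jumps in interval m (any destination)
    """
    H, M = haps.shape
    K = theta.shape[1]
    loglik = 0.0
    occ = np.zeros((M, K))
    occ_b = np.zeros((M, K))
    land = np.zeros((M, K))
    jump_mass = np.zeros(M - 1)
    f = np.empty((M, K))
    scale = np.empty(M)
    bwd = np.empty(K)
    y = np.empty(K)
    gam = np.empty(K)

    for h in range(H):
        x = haps[h]
        # forward
        c = 0.0
        for k in range(K):
            e = theta[0, k] if x[0] == 1 else 1.0 - theta[0, k]
            f[0, k] = alpha[0, k] * e
            c += f[0, k]
        scale[0] = c
        loglik += math.log(c)
        for k in range(K):
            f[0, k] /= c
        for m in range(1, M):
            r = rho[m - 1]
            c = 0.0
            for k in range(K):
                e = theta[m, k] if x[m] == 1 else 1.0 - theta[m, k]
                v = ((1.0 - r) * f[m - 1, k] + r * alpha[m, k]) * e
                f[m, k] = v
                c += v
            scale[m] = c
            loglik += math.log(c)
            for k in range(K):
                f[m, k] /= c
        # backward with on-the-fly stats
        for k in range(K):
            bwd[k] = 1.0
        s = 0.0
        for k in range(K):
            gam[k] = f[M - 1, k]
            s += gam[k]
        for k in range(K):
            g = gam[k] / s
            occ[M - 1, k] += g
            if x[M - 1] == 1:
                occ_b[M - 1, k] += g
        for m in range(M - 2, -1, -1):
            r = rho[m]
            sy = 0.0
            for k in range(K):
                e = theta[m + 1, k] if x[m + 1] == 1 else 1.0 - theta[m + 1, k]
                y[k] = e * bwd[k] / scale[m + 1]
                sy += alpha[m + 1, k] * y[k]
            jm = 0.0
            for k in range(K):
                jl = r * alpha[m + 1, k] * y[k]
                land[m + 1, k] += jl
                jm += jl
            jump_mass[m] += jm
            s = 0.0
            for k in range(K):
                bwd[k] = (1.0 - r) * y[k] + r * sy
                gam[k] = f[m, k] * bwd[k]
                s += gam[k]
            for k in range(K):
                g = gam[k] / s
                occ[m, k] += g
                if x[m] == 1:
                    occ_b[m, k] += g
                if m == 0:
                    land[0, k] += g
    return loglik, occ, occ_b, land, jump_mass


@njit(cache=True)
def _emission_parts(gm, bm, rm, gcm, mu1, mu2, lrr0, sigma_b, sigma_r,
                    gc_coef, use_lrr, lp, n1, n2):
    """Fill per-state LRR densities and per-state BAF band densities.

    Returns ``het`` (True when the BAF mixture applies at this marker).
    """
    L = lp.shape[0]
    cr = 1.0 / (sigma_r * _SQRT2PI)
    cb = 1.0 / (sigma_b * _SQRT2PI)
    if use_lrr and not math.isnan(rm):
        for l in range(L):
            zr = (rm - lrr0[l] - gc_coef * gcm) / sigma_r
            lp[l] = cr * math.exp(-0.5 * zr * zr)
    else:
        for l in range(L):
            lp[l] = 1.0
    het = gm == 1 and not math.isnan(bm)
    if het:
        for l in range(L):
            z1 = (bm - mu1[l]) / sigma_b
            z2 = (bm - mu2[l]) / sigma_b
            n1[l] = cb * math.exp(-0.5 * z1 * z1)
            n2[l] = cb * math.exp(-0.5 * z2 * z2)
    return het


@njit(cache=True)
def _fill_joint_emission(e, gm, het, th, lp, n1, n2):
    """e[l, k1, k2] = P(g|z) * lrr_part[l] * baf_part[l, z]."""
    L, K, _ = e.shape
    for k1 in range(K):
        t1 = th[k1]
        for k2 in range(K):
            t2 = th[k2]
            if gm == 0:
                pg = (1.0 - t1) * (1.0 - t2)
            elif gm == 1:
                pg = t1 * (1.0 - t2) + (1.0 - t1) * t2
            elif gm == 2:
                pg = t1 * t2
            else:
                pg = 1.0
            if het:
                den = t1 * (1.0 - t2) + (1.0 - t1) * t2
                p1 = t1 * (1.0 - t2) / den if den > 0.0 else 0.5
                for l in range(L):
                    e[l, k1, k2] = pg * lp[l] * (p1 * n1[l] + (1.0 - p1) * n2[l])
            else:
                for l in range(L):
                    e[l, k1, k2] = pg * lp[l]


@njit(cache=True)
def _apply_transition_fwd(fin, out, tpm, alpha_next, r, t1, s1):
    """out = (hap2 step)(hap1 step)(aberration step) fin, factorized."""
    L, K, _ = fin.shape
    # aberration step along l
    for k1 in range(K):
        for k2 in range(K):
            for l2 in range(L):
                acc = 0.0
                for l in range(L):
                    acc += fin[l, k1, k2] * tpm[l, l2]
                t1[l2, k1, k2] = acc
    # haplotype 1 step
    for l in range(L):
        for k2 in range(K):
            sv = 0.0
            for k1 in range(K):
                sv += t1[l, k1, k2]
            s1[k2] = sv
        for k1 in range(K):
            a = alpha_next[k1]
            for k2 in range(K):
                t1[l, k1, k2] = (1.0 - r) * t1[l, k1, k2] + r * a * s1[k2]
    # haplotype 2 step
    for l in range(L):
        for k1 in range(K):
            sv = 0.0
            for k2 in range(K):
                sv += t1[l, k1, k2]
            s1[k1] = sv
        for k1 in range(K):
            sv = s1[k1]
            for k2 in range(K):
                out[l, k1, k2] = (1.0 - r) * t1[l, k1, k2] + r * alpha_next[k2] * sv
    return out


@njit(cache=True)
def _apply_transition_bwd(y, out, tpm, alpha_next, r, t1, s1):
    """out[s] = sum_{s'} T[s, s'] y[s'] for the factorized product chain."""
    L, K, _ = y.shape
    # haplotype 2 backward: (T2 y)[k2] = (1-r) y[k2] + r sum_{k2'} alpha[k2'] y[k2']
    for l in range(L):
        for k1 in range(K):
            sv = 0.0
            for k2 in range(K):
                sv += alpha_next[k2] * y[l, k1, k2]
            s1[k1] = sv
        for k1 in range(K):
            sv = s1[k1]
            for k2 in range(K):
                t1[l, k1, k2] = (1.0 - r) * y[l, k1, k2] + r * sv
    # haplotype 1 backward
    for l in range(L):
        for k2 in range(K):
            sv = 0.0
            for k1 in range(K):
                sv += alpha_next[k1] * t1[l, k1, k2]
            s1[k2] = sv
        for k1 in range(K):
            for k2 in range(K):
                t1[l, k1, k2] = (1.0 - r) * t1[l, k1, k2] + r * s1[k2]
    # aberration backward: out[l] = sum_{l'} tpm[l, l'] t1[l']
    for k1 in range(K):
        for k2 in range(K):
            for l in range(L):
                acc = 0.0
                for l2 in range(L):
                    acc += tpm[l, l2] * t1[l2, k1, k2]
                out[l, k1, k2] = acc
    return out


@njit(cache=True)
def joint_fb(g, b, r, gc, theta, alpha, rho, tpm, pi_l, c1, c2, norm_idx,
             w, sigma_b, sigma_r, o, q, gc_coef, use_lrr):
    """Exact scaled forward-backward on one chromosome of the joint chain.

    Returns (loglik, gamma_l, A, amp, counts) where
      gamma_l[m, l]  posterior of aberration state l at marker m
      A[m, l]        posterior mass on (state l, B allele on haplotype 1) at
                     heterozygous markers (0 elsewhere)
      amp[m, k]      posterior probability that the over-represented
                     haplotype at marker m derives from cluster k
      counts         (n_normal, n_aberrant, n_exit, n_enter) expected
                     occupancies and hub transition counts, for optional
                     re-estimation of the aberration TPM geometry
    """
    M, K = theta.shape
    L = tpm.shape[0]
    mu1 = np.empty(L)
    mu2 = np.empty(L)
    lrr0 = np.empty(L)
    for l in range(L):
        tot = c1[l] + c2[l]
        den = (1.0 - w) * 2.0 + w * tot
        mu1[l] = ((1.0 - w) + w * c1[l]) / den
        mu2[l] = ((1.0 - w) + w * c2[l]) / den
        lrr0[l] = o + q * math.log2(den / 2.0)
    p_exit = tpm[1 - norm_idx if norm_idx == 0 else 0, norm_idx] if L > 1 else 0.0
    p_enter_each = tpm[norm_idx, 1 - norm_idx if norm_idx == 0 else 0] if L > 1 else 0.0

    f = np.empty((M, L, K, K))
    beta = np.empty((M, L, K, K))
    scale = np.empty(M)
    e = np.empty((L, K, K))
    tbuf = np.empty((L, K, K))
    obuf = np.empty((L, K, K))
    sbuf = np.empty(K)
    lp = np.empty(L)
    n1 = np.empty(L)
    n2 = np.empty(L)

    gamma_l = np.zeros((M, L))
    A = np.zeros((M, L))
    amp = np.zeros((M, K))
    n_norm = 0.0
    n_ab = 0.0
    n_exit = 0.0
    n_enter = 0.0
    loglik = 0.0

    # forward
    het = _emission_parts(g[0], b[0], r[0], gc[0], mu1, mu2, lrr0, sigma_b,
                          sigma_r, gc_coef, use_lrr, lp, n1, n2)
    _fill_joint_emission(e, g[0], het, theta[0], lp, n1, n2)
    c = 0.0
    for l in range(L):
        for k1 in range(K):
            for k2 in range(K):
                v = pi_l[l] * alpha[0, k1] * alpha[0, k2] * e[l, k1, k2]
                f[0, l, k1, k2] = v
                c += v
    scale[0] = c
    loglik += math.log(c)
    for l in range(L):
        for k1 in range(K):
            for k2 in range(K):
                f[0, l, k1, k2] /= c
    for m in range(1, M):
        _apply_transition_fwd(f[m - 1], obuf, tpm, alpha[m], rho[m - 1], tbuf, sbuf)
        het = _emission_parts(g[m], b[m], r[m], gc[m], mu1, mu2, lrr0, sigma_b,
                              sigma_r, gc_coef, use_lrr, lp, n1, n2)
        _fill_joint_emission(e, g[m], het, theta[m], lp, n1, n2)
        c = 0.0
        for l in range(L):
            for k1 in range(K):
                for k2 in range(K):
                    v = obuf[l, k1, k2] * e[l, k1, k2]
                    f[m, l, k1, k2] = v
                    c += v
        scale[m] = c
        loglik += math.log(c)
        for l in range(L):
            for k1 in range(K):
                for k2 in range(K):
                    f[m, l, k1, k2] /= c

    # backward (+ hub transition statistics)
    for l in range(L):
        for k1 in range(K):
            for k2 in range(K):
                beta[M - 1, l, k1, k2] = 1.0
    for m in range(M - 2, -1, -1):
        het = _emission_parts(g[m + 1], b[m + 1], r[m + 1], gc[m + 1], mu1, mu2,
                              lrr0, sigma_b, sigma_r, gc_coef, use_lrr, lp, n1, n2)
        _fill_joint_emission(e, g[m + 1], het, theta[m + 1], lp, n1, n2)
        cnext = scale[m + 1]
        for l in range(L):
            for k1 in range(K):
                for k2 in range(K):
                    obuf[l, k1, k2] = e[l, k1, k2] * beta[m + 1, l, k1, k2] / cnext
        # hub statistics: haplotype-transitioned forward vs y = e * beta / c
        _apply_hap_only(f[m], tbuf, alpha[m + 1], rho[m], sbuf)
        ex = 0.0
        en = 0.0
        for k1 in range(K):
            for k2 in range(K):
                u_ab = 0.0
                v_ab = 0.0
                for l in range(L):
                    if l != norm_idx:
                        u_ab += tbuf[l, k1, k2]
                        v_ab += obuf[l, k1, k2]
                ex += u_ab * obuf[norm_idx, k1, k2]
                en += tbuf[norm_idx, k1, k2] * v_ab
        n_exit += p_exit * ex
        n_enter += p_enter_each * en
        _apply_transition_bwd(obuf, beta[m], tpm, alpha[m + 1], rho[m], tbuf, sbuf)

    # posteriors
    for m in range(M):
        het = _emission_parts(g[m], b[m], r[m], gc[m], mu1, mu2, lrr0, sigma_b,
                              sigma_r, gc_coef, use_lrr, lp, n1, n2)
        s = 0.0
        for l in range(L):
            for k1 in range(K):
                for k2 in range(K):
                    s += f[m, l, k1, k2] * beta[m, l, k1, k2]
        for l in range(L):
            gl = 0.0
            al = 0.0
            for k1 in range(K):
                t1 = theta[m, k1]
                for k2 in range(K):
                    gz = f[m, l, k1, k2] * beta[m, l, k1, k2] / s
                    gl += gz
                    if het:
                        t2 = theta[m, k2]
                        den = t1 * (1.0 - t2) + (1.0 - t1) * t2
                        p1 = t1 * (1.0 - t2) / den if den > 0.0 else 0.5
                        mix = p1 * n1[l] + (1.0 - p1) * n2[l]
                        w1 = p1 * n1[l] / mix if mix > 0.0 else p1
                        al += gz * w1
                        # cluster of the over-represented haplotype
                        if c1[l] > c2[l]:
                            amp[m, k1] += gz
                        elif c2[l] > c1[l]:
                            amp[m, k2] += gz
                    else:
                        if c1[l] > c2[l]:
                            amp[m, k1] += gz
                        elif c2[l] > c1[l]:
                            amp[m, k2] += gz
            gamma_l[m, l] = gl
            if het:
                A[m, l] = al
            if l == norm_idx:
                n_norm += gl
            else:
                n_ab += gl
    return loglik, gamma_l, A, amp, n_norm, n_ab, n_exit, n_enter


@njit(cache=True)
def _apply_hap_only(fin, out, alpha_next, r, s1):
    """Apply only the two haplotype-chain steps of the transition to fin."""
    L, K, _ = fin.shape
    for l in range(L):
        for k2 in range(K):
            sv = 0.0
            for k1 in range(K):
                sv += fin[l, k1, k2]
            s1[k2] = sv
        for k1 in range(K):
            a = alpha_next[k1]
            for k2 in range(K):
                out[l, k1, k2] = (1.0 - r) * fin[l, k1, k2] + r * a * s1[k2]
    for l in range(L):
        for k1 in range(K):
            sv = 0.0
            for k2 in range(K):
                sv += out[l, k1, k2]
            s1[k1] = sv
        for k1 in range(K):
            sv = s1[k1]
            for k2 in range(K):
                out[l, k1, k2] = (1.0 - r) * out[l, k1, k2] + r * alpha_next[k2] * sv
    return out


@njit(cache=True)
def joint_loglik(g, b, r, gc, theta, alpha, rho, tpm, pi_l, c1, c2,
                 w, sigma_b, sigma_r, o, q, gc_coef, use_lrr):
    """Forward-only log-likelihood on one chromosome (rolling buffers)."""
    M, K = theta.shape
    L = tpm.shape[0]
    mu1 = np.empty(L)
    mu2 = np.empty(L)
    lrr0 = np.empty(L)
    for l in range(L):
        tot = c1[l] + c2[l]
        den = (1.0 - w) * 2.0 + w * tot
        mu1[l] = ((1.0 - w) + w * c1[l]) / den
        mu2[l] = ((1.0 - w) + w * c2[l]) / den
        lrr0[l] = o + q * math.log2(den / 2.0)
    fprev = np.empty((L, K, K))
    fcur = np.empty((L, K, K))
    e = np.empty((L, K, K))
    tbuf = np.empty((L, K, K))
    sbuf = np.empty(K)
    lp = np.empty(L)
    n1 = np.empty(L)
    n2 = np.empty(L)
    loglik = 0.0

    het = _emission_parts(g[0], b[0], r[0], gc[0], mu1, mu2, lrr0, sigma_b,
                          sigma_r, gc_coef, use_lrr, lp, n1, n2)
    _fill_joint_emission(e, g[0], het, theta[0], lp, n1, n2)
    c = 0.0
    for l in range(L):
        for k1 in range(K):
            for k2 in range(K):
                v = pi_l[l] * alpha[0, k1] * alpha[0, k2] * e[l, k1, k2]
                fprev[l, k1, k2] = v
                c += v
    loglik += math.log(c)
    for l in range(L):
        for k1 in range(K):
            for k2 in range(K):
                fprev[l, k1, k2] /= c
    for m in range(1, M):
        _apply_transition_fwd(fprev, fcur, tpm, alpha[m], rho[m - 1], tbuf, sbuf)
        het = _emission_parts(g[m], b[m], r[m], gc[m], mu1, mu2, lrr0, sigma_b,
                              sigma_r, gc_coef, use_lrr, lp, n1, n2)
        _fill_joint_emission(e, g[m], het, theta[m], lp, n1, n2)
        c = 0.0
        for l in range(L):
            for k1 in range(K):
                for k2 in range(K):
                    v = fcur[l, k1, k2] * e[l, k1, k2]
                    fcur[l, k1, k2] = v
                    c += v
        loglik += math.log(c)
        for l in range(L):
            for k1 in range(K):
                for k2 in range(K):
                    fprev[l, k1, k2] = fcur[l, k1, k2] / c
    return loglik
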