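"""Independent brute-force oracles used by the test suite.

Deliberately simple, loop-based implementations kept separate from the
package so each check compares two code paths written independently.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def nipals_oracle(X, y, A, center=False):
    """Textbook PLS1 NIPALS: returns (T, W, P, q, b) without sign fixing."""
    X = np.array(X, dtype=float)
    y = np.array(y, dtype=float).ravel()
    if center:
        xm, ym = X.mean(0), y.mean()
        X = X - xm
        y = y - ym
    n, p = X.shape
    T = np.zeros((n, A))
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    q = np.zeros(A)
    for a in range(A):
        w = X.T @ y
        w = w / np.sqrt(w @ w)
        t = X @ w
        tt = t @ t
        pa = X.T @ t / tt
        qa = (y @ t) / tt
        X = X - np.outer(t, pa)
        y = y - t * qa
        T[:, a], W[:, a], P[:, a], q[a] = t, w, pa, qa
    b = W @ np.linalg.inv(P.T @ W) @ q
    return T, W, P, q, b


def residual_variance_oracle(X, y, T, P, q, center=False):
    """Per-LV explained variance (%) by re-measuring residual sums of squares."""
    X = np.array(X, dtype=float)
    y = np.array(y, dtype=float).ravel()
    if center:
        X = X - X.mean(0)
        y = y - y.mean()
    ssx0 = (X * X).sum()
    ssy0 = (y * y).sum()
    x_part, y_part = [], []
    ssx_prev, ssy_prev = ssx0, ssy0
    for a in range(T.shape[1]):
        X = X - np.outer(T[:, a], P[:, a])
        y = y - T[:, a] * q[a]
        ssx, ssy = (X * X).sum(), (y * y).sum()
        x_part.append((ssx_prev - ssx) / ssx0 * 100)
        y_part.append((ssy_prev - ssy) / ssy0 * 100)
        ssx_prev, ssy_prev = ssx, ssy
    return np.array(x_part), np.array(y_part)


def vip_oracle(X, y, W, T, q):
    """Assemble VIP from independently recomputed per-component response SS."""
    p = W.shape[0]
    ssy = np.array([(q[a] * T[:, a]) @ (q[a] * T[:, a]) for a in range(W.shape[1])])
    out = np.zeros(p)
    for j in range(p):
        num = sum(
            ssy[a] * (W[j, a] / np.sqrt(W[:, a] @ W[:, a])) ** 2
            for a in range(W.shape[1])
        )
        out[j] = np.sqrt(p * num / ssy.sum())
    return out


def mannwhitney_exact_oracle(x0, x1):
    """Two-sided exact Mann-Whitney p by full enumeration (no ties assumed)."""
    x0, x1 = list(x0), list(x1)
    n0, n1 = len(x0), len(x1)
    pooled = sorted(x0 + x1)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}

    def u_of(first_idx):
        r = sum(ranks[pooled[i - 1]] for i in first_idx)
        return r - n0 * (n0 + 1) / 2

    obs_r = sum(ranks[v] for v in x0)
    u_obs = obs_r - n0 * (n0 + 1) / 2
    mid = n0 * n1 / 2
    dev = abs(u_obs - mid)
    total = 0
    extreme = 0
    for idx in combinations(range(1, n0 + n1 + 1), n0):
        u = u_of(idx)
        total += 1
        if abs(u - mid) >= dev - 1e-12:
            extreme += 1
    return u_obs, extreme / total
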