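"""Independent reference implementations used as oracles in the tests.

These deliberately re-derive the same quantities through naive code paths
(triple loops, explicit matrix solves, flood fill) so that agreement with
the package is evidence of correctness rather than of shared code.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def brute_force_tfce(s, E, H, dh=None, connectivity=26):
    """Triple-loop TFCE: per voxel, per threshold, flood-fill the component size.

    Uses the same threshold ladder convention as the package (100 equal steps
    up to the map maximum when dh is None; comparison guard eps = 1e-9 * dh)
    but shares no code with it.
    """
    s = np.asarray(s, dtype=float)
    s = np.where(np.isnan(s), 0.0, s)
    smax = float(s.max())
    out = np.zeros_like(s)
    if smax <= 0:
        return out
    if dh is None:
        step = smax / 100.0
        heights = [smax * (i / 100.0) for i in range(1, 101)]
    else:
        step = dh
        heights = []
        i = 1
        while dh * i <= smax + 1e-9 * dh:
            heights.append(dh * i)
            i += 1
    eps = step * 1e-9

    if connectivity == 6:
        offs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    else:
        offs = [
            (dx, dy, dz)
            for dx in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dz in (-1, 0, 1)
            if (dx, dy, dz) != (0, 0, 0)
            and (connectivity == 26 or abs(dx) + abs(dy) + abs(dz) <= 2)
        ]

    nx, ny, nz = s.shape
    for h in heights:
        supra = s >= h - eps
        for x in range(nx):
            for y in range(ny):
                for z in range(nz):
                    if not supra[x, y, z]:
                        continue
                    # BFS component size containing (x, y, z)
                    seen = {(x, y, z)}
                    queue = deque([(x, y, z)])
                    while queue:
                        cx, cy, cz = queue.popleft()
                        for dx, dy, dz in offs:
                            p = (cx + dx, cy + dy, cz + dz)
                            if (
                                0 <= p[0] < nx
                                and 0 <= p[1] < ny
                                and 0 <= p[2] < nz
                                and supra[p]
                                and p not in seen
                            ):
                                seen.add(p)
                                queue.append(p)
                    out[x, y, z] += len(seen) ** E * h**H * step
    return out


def naive_ridge(X, y, lam):
    """Explicit centered normal-equation ridge (intercept unpenalized)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    xm = X.mean(axis=0)
    ym = y.mean()
    Xc = X - xm
    A = Xc.T @ Xc + lam * np.eye(X.shape[1])
    coef = np.linalg.solve(A, Xc.T @ (y - ym))
    return float(ym - xm @ coef), coef


def naive_cv_rss(X, y, fold_labels, lambdas):
    """Fold-by-fold CV RSS with per-fold standardization and GCV penalty choice.

    A direct loop with explicit solves and hat-matrix traces; the tie-break
    toward the larger penalty matches the package's stated rule.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    lambdas = np.sort(np.asarray(lambdas, float))
    total = 0.0
    for k in sorted(set(fold_labels)):
        te = np.flatnonzero(fold_labels == k)
        tr = np.flatnonzero(fold_labels != k)
        Xt = X[tr]
        mu, sd = Xt.mean(axis=0), Xt.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
        Xt_s = (Xt - mu) / sd
        Xv_s = (X[te] - mu) / sd
        yt = y[tr]
        ym = yt.mean()
        best = None
        n_tr = len(tr)
        for lam in lambdas:
            A = Xt_s.T @ Xt_s + lam * np.eye(X.shape[1])
            Ainv = np.linalg.pinv(A)
            coef = Ainv @ Xt_s.T @ (yt - ym)
            fitted = Xt_s @ coef + ym
            rss_train = ((yt - fitted) ** 2).sum()
            df = np.trace(Xt_s @ Ainv @ Xt_s.T) + 1.0
            gcv = rss_train / max(1.0 - df / n_tr, 1e-12) ** 2
            if best is None or gcv <= best[0]:  # <= so ties go to the larger lam
                best = (gcv, lam, coef)
        _, _, coef = best
        pred = Xv_s @ coef + ym
        total += ((y[te] - pred) ** 2).sum()
    return total


def bh_stepup(pvals, alpha=0.05):
    """Benjamini-Hochberg step-up by hand: indices of declared discoveries."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p)
    kmax = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= alpha * rank / m:
            kmax = rank
    return set(order[:kmax])
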