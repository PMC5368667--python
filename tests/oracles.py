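"""Independent reference implementations used to cross-check the package.

Each oracle deliberately takes a different computational route from the
implementation it checks (exhaustive search, quaternion algebra, plain
loops, numerical integration) so that agreement is informative.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad
from scipy.optimize import lsq_linear
from scipy.special import gammaln


def grid_isotherm_oracle(conc, signal, n_grid=120, refine_rounds=2):
    """Exhaustive log-grid search over K_D, solving the three linear
    parameters by bounded linear least squares at every grid point, then
    re-gridding around the best point until the spacing is ~0.1%."""
    conc = np.asarray(conc, float)
    signal = np.asarray(signal, float)
    pos = conc[conc > 0]

    def sweep(lo, hi, n):
        best = None
        for kd in np.geomspace(lo, hi, n):
            A = np.column_stack([np.ones_like(conc), conc / (conc + kd), conc])
            res = lsq_linear(A, signal, bounds=([-np.inf, 0.0, 0.0], np.inf))
            mse = float(np.mean((A @ res.x - signal) ** 2))
            if best is None or mse < best[0]:
                best = (mse, kd, res.x)
        return best

    lo, hi = pos.min() / 1000, pos.max() * 1000
    best = sweep(lo, hi, n_grid)
    for _ in range(refine_rounds):
        step = (hi / lo) ** (1.0 / (n_grid - 1))
        lo, hi = best[1] / step**2, best[1] * step**2
        candidate = sweep(lo, hi, 60)
        if candidate[0] <= best[0]:
            best = candidate
    return {"mse": best[0], "kd": best[1], "linear": best[2]}


def quaternion_superpose_rmsd(ref, mob):
    """Optimal-superposition RMSD via the quaternion eigenvalue method
    (largest eigenvalue of the 4x4 key matrix), independent of SVD."""
    ref = np.asarray(ref, float)
    mob = np.asarray(mob, float)
    x = mob - mob.mean(axis=0)
    y = ref - ref.mean(axis=0)
    R = x.T @ y
    S = np.array(
        [
            [R[0, 0] + R[1, 1] + R[2, 2], R[1, 2] - R[2, 1], R[2, 0] - R[0, 2], R[0, 1] - R[1, 0]],
            [R[1, 2] - R[2, 1], R[0, 0] - R[1, 1] - R[2, 2], R[0, 1] + R[1, 0], R[0, 2] + R[2, 0]],
            [R[2, 0] - R[0, 2], R[0, 1] + R[1, 0], -R[0, 0] + R[1, 1] - R[2, 2], R[1, 2] + R[2, 1]],
            [R[0, 1] - R[1, 0], R[0, 2] + R[2, 0], R[1, 2] + R[2, 1], -R[0, 0] - R[1, 1] + R[2, 2]],
        ]
    )
    lam = np.linalg.eigvalsh(S)[-1]
    n = len(ref)
    msd = (np.sum(x**2) + np.sum(y**2) - 2.0 * lam) / n
    return float(np.sqrt(max(msd, 0.0)))


def greedy_cluster_oracle(matrix, cutoff):
    """Plain-list re-statement of the greedy dominant-structure rule."""
    D = np.asarray(matrix, float)
    n = D.shape[0]
    remaining = list(range(n))
    labels = {}
    centers = []
    while remaining:
        best_center, best_members = None, None
        for i in remaining:  # ascending order -> lowest index wins ties
            members = [j for j in remaining if D[i, j] <= cutoff or j == i]
            if best_members is None or len(members) > len(best_members):
                best_center, best_members = i, members
        cid = len(centers)
        centers.append(best_center)
        for j in best_members:
            labels[j] = cid
            remaining.remove(j)
    return np.array([labels[i] for i in range(n)]), centers


def probe_recount_oracle(traj, cutoff):
    """Per-atom probe recount with explicit loops and scalar arithmetic."""
    heavy = np.nonzero(traj.is_heavy)[0]
    probes = np.nonzero(traj.is_probe)[0]
    totals = np.zeros(len(heavy), dtype=np.int64)
    for f in range(traj.n_frames):
        for hi, h in enumerate(heavy):
            for p in probes:
                d = traj.coords[f, h] - traj.coords[f, p]
                if traj.box is not None:
                    d = d - traj.box * np.round(d / traj.box)
                if float(d @ d) <= cutoff**2:
                    totals[hi] += 1
    return totals / traj.n_frames


def t_two_tailed_p_by_quadrature(t_stat, df):
    """Two-tailed p from numerical integration of the t density."""

    def density(x):
        logc = gammaln((df + 1) / 2) - gammaln(df / 2) - 0.5 * np.log(df * np.pi)
        return np.exp(logc - (df + 1) / 2 * np.log1p(x**2 / df))

    tail, _ = quad(density, abs(t_stat), np.inf)
    return 2.0 * tail


def pooled_t_statistic(a, b):
    """Hand formula for the equal-variance two-sample t statistic."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))


def melt_tm_interpolation_oracle(truth):
    """True-midpoint locator: linear interpolation of the noiseless fraction
    folded at 0.5 on a fine grid (no baselines, no regression)."""
    t = np.arange(truth.temp_grid[0], truth.temp_grid[1], 0.01)
    f = truth.fraction_folded(t)
    i = int(np.argmin(np.abs(f - 0.5)))
    lo, hi = max(i - 1, 0), min(i + 1, len(t) - 1)
    return float(np.interp(0.5, f[[hi, lo]], t[[hi, lo]]))
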