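"""Independent reference implementations used to check the package.

Everything here is deliberately brute-force (dense-grid enumeration,
closed forms) and shares no code with the sampler or calibration paths it
validates.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats


def two_piece_normal_cdf(x: np.ndarray, mode: float, s_low: float, s_high: float) -> np.ndarray:
    """CDF of the two-piece normal with spread s_low below the mode, s_high above."""
    x = np.asarray(x, dtype=float)
    norm = s_low + s_high
    below = 2.0 * s_low / norm * stats.norm.cdf(x, loc=mode, scale=s_low)
    above = s_low / norm + 2.0 * s_high / norm * (stats.norm.cdf(x, loc=mode, scale=s_high) - 0.5)
    return np.where(x <= mode, below, above)


def quantile_from_old_brute(grid: np.ndarray, p: np.ndarray, q_from_old: float, refine: int = 10) -> float:
    """From-old quantile by cumulative summation on a ``refine``-times finer grid."""
    h = grid[1] - grid[0]
    fine = np.arange(grid[0] - h / 2, grid[-1] + h / 2, h / refine) + h / (2 * refine)
    # density is piecewise-constant over each coarse cell
    idx = np.clip(np.round((fine - grid[0]) / h).astype(int), 0, len(grid) - 1)
    pf = p[idx]
    pf = pf / pf.sum()
    cdf = np.cumsum(pf)
    target = 1.0 - q_from_old
    i = int(np.searchsorted(cdf, target))
    return float(fine[min(i, len(fine) - 1)])


def phase_grid_oracle(
    densities: Sequence[Tuple[np.ndarray, np.ndarray]],
    span_exponent: Optional[float] = None,
    overall_span_exponent: float = 0.0,
) -> Dict[str, float]:
    """Exhaustive grid integration of a single-phase model with <=2 events.

    ``densities`` are (grid, p) pairs on one shared grid.  The joint over
    (alpha, beta) is enumerated on the same grid; event marginals come from
    2-D prefix/suffix sums.  Returns medians of alpha, beta and each event.
    ``span_exponent`` is the prior exponent e (default n-1).
    """
    n = len(densities)
    if n not in (1, 2):
        raise ValueError("oracle supports 1 or 2 events")
    grid = np.asarray(densities[0][0], dtype=float)
    N = len(grid)
    e = float(n - 1) if span_exponent is None else float(span_exponent)
    c = e - n - overall_span_exponent  # single phase: total span == phase span

    F = []
    Fm1 = []
    for g, p in densities:
        f = np.cumsum(p)
        F.append(f)
        Fm1.append(np.concatenate([[0.0], f[:-1]]))

    span = grid[:, None] - grid[None, :]  # alpha index k rows, beta index l cols
    valid = span > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        W = np.where(valid, np.power(np.where(valid, span, 1.0), c), 0.0)
    masses = []
    for i in range(n):
        m = F[i][:, None] - Fm1[i][None, :]
        masses.append(np.clip(m, 0.0, None))
        W = W * masses[-1]

    alpha_marg = W.sum(axis=1)
    beta_marg = W.sum(axis=0)

    def _median(marg: np.ndarray) -> float:
        cdf = np.cumsum(marg)
        return float(grid[np.searchsorted(cdf, 0.5 * cdf[-1])])

    out = {"alpha_median": _median(alpha_marg), "beta_median": _median(beta_marg)}

    for i in range(n):
        base = np.where(valid, np.power(np.where(valid, span, 1.0), c), 0.0)
        for i2 in range(n):
            if i2 != i:
                base = base * masses[i2]
        # S(m) = sum over alpha >= g_m, beta <= g_m of base
        pref = np.cumsum(base, axis=1)  # over beta
        suff = np.cumsum(pref[::-1, :], axis=0)[::-1, :]  # over alpha from the top
        s_diag = suff[np.arange(N), np.arange(N)]
        p_i = densities[i][1] * s_diag
        out[f"event{i}_median"] = _median(p_i)
    return out


def ks_distance(draws: np.ndarray, grid: np.ndarray, p: np.ndarray) -> float:
    """KS distance between empirical draws and a discrete density on a grid."""
    draws = np.sort(np.asarray(draws, dtype=float))
    cdf_model = np.cumsum(p)
    emp = np.arange(1, len(draws) + 1) / len(draws)
    idx = np.clip(np.searchsorted(grid, draws, side="right") - 1, 0, len(grid) - 1)
    return float(np.max(np.abs(emp - cdf_model[idx])))


def batch_median_mcse(draws: np.ndarray, n_batches: int = 25) -> float:
    """Monte-Carlo standard error of the median via non-overlapping batches."""
    draws = np.asarray(draws, dtype=float)
    m = len(draws) // n_batches
    meds = [np.median(draws[i * m : (i + 1) * m]) for i in range(n_batches)]
    return float(np.std(meds, ddof=1) / np.sqrt(n_batches))


def autocorr_ess(x: np.ndarray) -> float:
    """ESS of a single chain by direct autocorrelation summation."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    xc = x - x.mean()
    var = np.dot(xc, xc) / n
    if var == 0:
        return float(n)
    tau = 1.0
    for t in range(1, n // 2):
        rho = np.dot(xc[:-t], xc[t:]) / ((n - t) * var)
        if rho < 0.05:
            break
        tau += 2.0 * rho
    return n / tau
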