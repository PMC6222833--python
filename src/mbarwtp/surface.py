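"""Free-energy surfaces and the weighted-thermodynamic-perturbation correction.

The low-level surface is the MBAR-weighted 2D histogram

    F_L(eta) = -(1/beta) ln sum_{frames in bin eta} w^0,

anchored to a chosen reference bin. The correction to a high-level Hamiltonian
is the per-bin weighted exponential average of the energy gap
``dU = U_H - U_L`` (weighted TP),

    dF(eta) = -(1/beta) ln [ sum_bin w^0 e^(-beta dU) / sum_bin w^0 ],

and ``F_H = F_L + dF``. All exponential sums are evaluated in log space.

The reliability of each per-bin exponential average is tracked by the
reweighting entropy ``S = -(1/ln n) sum p ln p`` of the normalized
perturbation weights ``p``; ``e^(-S)`` feeds the GPR smoother as a
heteroscedastic noise level, and the effective sample size ``1 / sum p^2``
is reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .data_model import OUT_OF_GRID, Grid2D, SampleSet, Surface2D
from .mbar import MBARSolution

logger = logging.getLogger(__name__)

#: A bin where one frame carries more than this fraction of the perturbation
#: weight is flagged as dominated (the exponential average is then untrustworthy).
DOMINANCE_LIMIT = 0.999


@dataclass
class WTPResult:
    """High-level surface, its correction, and per-bin reliability diagnostics.

    ``f_high.value = f_low.value + delta_f.value`` holds exactly on occupied
    bins (``delta_f`` is the raw, un-anchored per-bin correction; ``f_low``
    carries the anchoring).
    """

    f_low: Surface2D
    delta_f: Surface2D
    f_high: Surface2D
    entropy: np.ndarray
    effective_samples: np.ndarray
    dominated: np.ndarray


def _resolve_anchor(grid: Grid2D, value: np.ndarray, occupied: np.ndarray, anchor):
    """Anchor bin as (i, j); ``None`` selects the occupied bin of minimum value.

    The minimum-value default mirrors the convention of anchoring at the most
    stable (product) basin, which then carries zero free energy.
    """
    if anchor is None:
        masked = np.where(occupied, value, np.inf)
        i, j = np.unravel_index(int(np.argmin(masked)), grid.shape)
        return int(i), int(j)
    i, j = int(anchor[0]), int(anchor[1])
    if not (0 <= i < grid.shape[0] and 0 <= j < grid.shape[1]):
        raise ValueError(f"anchor bin {anchor} outside grid of shape {grid.shape}")
    if not occupied[i, j]:
        raise ValueError(f"anchor bin {anchor} is unoccupied")
    return i, j


def fe_surface_low(
    samples: SampleSet,
    sol: MBARSolution,
    grid: Grid2D,
    anchor: tuple[int, int] | None = None,
    bins: np.ndarray | None = None,
) -> Surface2D:
    """Unbiased low-level free-energy surface on ``grid`` (kcal/mol).

    ``anchor`` is a bin index pair set to zero; by default the occupied bin
    with the lowest free energy. Unoccupied bins are NaN/unoccupied. The
    per-bin variance is the first-order importance-sampling estimate
    ``1 / (beta^2 n_eff)`` with ``n_eff = (sum w)^2 / sum w^2``; frames
    outside the grid are excluded from the surface (they still entered the
    MBAR normalization).
    """
    if not sol.converged:
        raise ValueError("MBAR solution not converged")
    if bins is None:
        bins = grid.assign(samples.rc)
    beta = samples.beta
    lw = sol.log_weights
    shape = grid.shape
    value = np.full(shape, np.nan)
    variance = np.full(shape, np.nan)
    count = np.zeros(shape, dtype=np.int64)
    order = np.argsort(bins, kind="stable")
    sorted_bins = bins[order]
    boundaries = np.flatnonzero(np.diff(sorted_bins)) + 1
    groups = np.split(order, boundaries)
    for grp in groups:
        b = int(bins[grp[0]])
        if b == OUT_OF_GRID:
            continue
        i, j = grid.unravel(b)
        lse = logsumexp(lw[grp])
        value[i, j] = -lse / beta
        count[i, j] = len(grp)
        p = np.exp(lw[grp] - lse)
        n_eff = 1.0 / float((p * p).sum())
        variance[i, j] = 1.0 / (beta * beta * n_eff)
    occupied = count > 0
    ai, aj = _resolve_anchor(grid, value, occupied, anchor)
    value = value - value[ai, aj]
    return Surface2D(grid, value, variance=variance, count=count, occupied=occupied)


def reweighting_entropy(weights) -> float:
    """Normalized Shannon entropy of a bin's perturbation weights, in [0, 1].

    ``S = -(1/ln n) sum_l p_l ln p_l`` with ``p`` the weights normalized to
    sum to 1 and ``n`` the number of frames. Uniform weights give 1; a single
    dominating weight gives 0. ``S = 1`` by convention for ``n = 1``. Values
    near 0 mark bins whose exponential average rests on very few frames.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or len(w) == 0:
        raise ValueError("weights must be a non-empty 1D array")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("at least one weight must be positive")
    n = len(w)
    if n == 1:
        return 1.0
    p = w / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(n))


def _require_u_high(samples: SampleSet, bins: np.ndarray, grid: Grid2D) -> None:
    if samples.u_high is None:
        raise ValueError("high-level energies (u_high) are required but absent")
    missing = ~np.isfinite(samples.u_high)
    bad = missing & (bins != OUT_OF_GRID)
    if np.any(bad):
        first = int(bins[np.flatnonzero(bad)[0]])
        i, j = grid.unravel(first)
        raise ValueError(
            f"bin ({i}, {j}) at eta=({grid.axis1[i]:.3f}, {grid.axis2[j]:.3f}) "
            "contains frames with missing u_high; weighted TP requires every "
            "frame of every occupied bin to carry a high-level energy"
        )


def wtp_correct(
    samples: SampleSet,
    sol: MBARSolution,
    grid: Grid2D,
    anchor: tuple[int, int] | None = None,
) -> WTPResult:
    """Weighted-TP correction of the low-level surface to the high level.

    Per occupied bin the raw correction is the log-space exponential average
    of the energy gap under the MBAR unbiased weights; ``f_high`` follows by
    bin-wise addition to the (anchored) low-level surface. The per-bin
    variance of ``delta_f`` is a first-order delta-method estimate from the
    weighted spread of ``e^(-beta dU)``. Bins where a single frame carries
    more than 99.9% of the perturbation weight are flagged.
    """
    bins = grid.assign(samples.rc)
    _require_u_high(samples, bins, grid)
    f_low = fe_surface_low(samples, sol, grid, anchor=anchor, bins=bins)
    beta = samples.beta
    du = samples.u_high - samples.u_low
    lw = sol.log_weights
    lwp = lw - beta * du  # log perturbation weights  w^0 e^{-beta dU}
    shape = grid.shape
    dvalue = np.full(shape, np.nan)
    dvar = np.full(shape, np.nan)
    entropy = np.full(shape, np.nan)
    n_eff = np.full(shape, np.nan)
    dominated = np.zeros(shape, dtype=bool)
    for b in np.unique(bins):
        if b == OUT_OF_GRID:
            continue
        grp = np.flatnonzero(bins == b)
        i, j = grid.unravel(int(b))
        lse_w = logsumexp(lw[grp])
        lse_p = logsumexp(lwp[grp])
        dvalue[i, j] = -(lse_p - lse_w) / beta
        p = np.exp(lwp[grp] - lse_p)
        n = len(grp)
        entropy[i, j] = 1.0 if n == 1 else float(
            -(p[p > 0] * np.log(p[p > 0])).sum() / np.log(n)
        )
        n_eff[i, j] = 1.0 / float((p * p).sum())
        if n > 1 and p.max() > DOMINANCE_LIMIT:
            dominated[i, j] = True
        # delta method on m = sum q a  with q = w^0 normalized, a = e^{-beta dU}
        q = np.exp(lw[grp] - lse_w)
        a = np.exp(-beta * (du[grp] - du[grp].min()))
        m = float((q * a).sum())
        var_m = float((q * q * (a - m) ** 2).sum())
        dvar[i, j] = var_m / (beta * beta * m * m)
    if np.any(dominated):
        flat = [tuple(map(int, np.unravel_index(k, shape)))
                for k in np.flatnonzero(dominated.ravel())]
        logger.warning(
            "wTP: a single frame carries >%.1f%% of the perturbation weight in bins %s",
            DOMINANCE_LIMIT * 100, flat,
        )
    occupied = f_low.occupied
    delta_f = Surface2D(grid, dvalue, variance=dvar, count=f_low.count,
                        entropy=entropy, occupied=occupied)
    f_high = Surface2D(
        grid,
        f_low.value + dvalue,
        variance=np.where(occupied, f_low.variance + dvar, np.nan),
        count=f_low.count,
        entropy=entropy,
        occupied=occupied,
    )
    return WTPResult(
        f_low=f_low,
        delta_f=delta_f,
        f_high=f_high,
        entropy=entropy,
        effective_samples=n_eff,
        dominated=dominated,
    )


def reweighted_observable(
    samples: SampleSet,
    sol: MBARSolution,
    grid: Grid2D,
    name: str,
    level: str = "high",
) -> tuple[Surface2D, Surface2D]:
    """Per-bin ensemble average and variance of a named observable.

    With ``level="high"`` the average is taken in the high-level ensemble via
    perturbation reweighting (requires ``u_high``); with ``level="low"`` the
    plain MBAR-weighted bin average is returned. When ``U_H = U_L`` the two
    coincide. Returns ``(mean, variance)`` surfaces; the variance is the
    weighted second central moment of the observable within the bin.
    """
    if name not in samples.observables:
        raise ValueError(f"observable {name!r} not present on the samples")
    obs = samples.observables[name]
    bins = grid.assign(samples.rc)
    if level == "high":
        _require_u_high(samples, bins, grid)
        lwp = sol.log_weights - samples.beta * (samples.u_high - samples.u_low)
    elif level == "low":
        lwp = sol.log_weights
    else:
        raise ValueError(f"level must be 'high' or 'low', got {level!r}")
    in_grid = bins != OUT_OF_GRID
    if np.any(~np.isfinite(obs[in_grid])):
        raise ValueError(f"observable {name!r} missing (non-finite) on in-grid frames")
    shape = grid.shape
    mean = np.full(shape, np.nan)
    var = np.full(shape, np.nan)
    count = np.zeros(shape, dtype=np.int64)
    for b in np.unique(bins):
        if b == OUT_OF_GRID:
            continue
        grp = np.flatnonzero(bins == b)
        i, j = grid.unravel(int(b))
        p = np.exp(lwp[grp] - logsumexp(lwp[grp]))
        m = float((p * obs[grp]).sum())
        mean[i, j] = m
        var[i, j] = max(float((p * obs[grp] ** 2).sum()) - m * m, 0.0)
        count[i, j] = len(grp)
    occ = count > 0
    return (
        Surface2D(grid, mean, count=count, occupied=occ),
        Surface2D(grid, var, count=count, occupied=occ),
    )
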