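"""Stationary points and energetics on a smoothed 2D free-energy surface.

The transition state is the stationary point (zero gradient) whose Hessian
has one positive and one negative eigenvalue. Derivatives are taken with the
finite central-difference method on the (smooth) surface function; candidate
points come from a coarse scan for gradient sign changes and are refined by
damped Newton iteration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data_model import Surface2D

logger = logging.getLogger(__name__)

#: Default finite-difference step, Å (half the conventional 0.05 Å bin width).
DEFAULT_STEP = 0.025
#: Convergence threshold on the gradient norm, kcal/mol/Å.
GRAD_TOL = 1e-4
#: Stationary points closer than this (Å) are merged.
MERGE_DISTANCE = 0.02
#: |eigenvalue| below this is treated as numerically zero ("degenerate").
EIG_ZERO = 1e-6


@dataclass(frozen=True)
class StationaryPoint:
    """A classified stationary point of the surface."""

    location: tuple[float, float]
    value: float
    gradient_norm: float
    hessian: np.ndarray
    eigenvalues: tuple[float, float]
    kind: str  # "minimum" | "maximum" | "saddle" | "degenerate"


def _classify(eigenvalues: np.ndarray) -> str:
    if np.any(np.abs(eigenvalues) < EIG_ZERO):
        return "degenerate"
    neg = int((eigenvalues < 0).sum())
    return {0: "minimum", 1: "saddle", 2: "maximum"}[neg]


def grad_hess(func, point, h: float = DEFAULT_STEP, domain=None):
    """Central-difference gradient and (symmetrized) Hessian of ``func`` at ``point``.

    ``func`` maps a length-2 point to a scalar. If ``domain`` is given as
    ``((x_lo, x_hi), (y_lo, y_hi))``, the full stencil (point ± h in each
    dimension, including diagonals) must fit inside it.
    """
    x, y = float(point[0]), float(point[1])
    if domain is not None:
        (xl, xh), (yl, yh) = domain
        if not (xl + h <= x <= xh - h and yl + h <= y <= yh - h):
            raise ValueError(
                f"point ({x:.4f}, {y:.4f}) closer than h={h} to the domain boundary"
            )
    f = lambda a, b: float(func(np.array([a, b])))
    f0 = f(x, y)
    fpx, fmx = f(x + h, y), f(x - h, y)
    fpy, fmy = f(x, y + h), f(x, y - h)
    g = np.array([(fpx - fmx) / (2 * h), (fpy - fmy) / (2 * h)])
    hxx = (fpx - 2 * f0 + fmx) / h**2
    hyy = (fpy - 2 * f0 + fmy) / h**2
    hxy = (f(x + h, y + h) - f(x + h, y - h) - f(x - h, y + h) + f(x - h, y - h)) / (4 * h**2)
    hess = np.array([[hxx, hxy], [hxy, hyy]])
    return g, 0.5 * (hess + hess.T)


def _newton_refine(func, x0, domain, h, max_iter=60):
    (xl, xh), (yl, yh) = domain
    x = np.array(x0, dtype=float)
    max_step = 4 * h
    for _ in range(max_iter):
        g, hess = grad_hess(func, x, h=h, domain=domain)
        gnorm = float(np.linalg.norm(g))
        if gnorm < GRAD_TOL:
            eig = np.linalg.eigvalsh(hess)
            return StationaryPoint(
                location=(float(x[0]), float(x[1])),
                value=float(func(x)),
                gradient_norm=gnorm,
                hessian=hess,
                eigenvalues=(float(eig[0]), float(eig[1])),
                kind=_classify(eig),
            )
        try:
            step = np.linalg.solve(hess, -g)
        except np.linalg.LinAlgError:
            return None
        norm = np.linalg.norm(step)
        if norm > max_step:
            step *= max_step / norm
        x = x + step
        if not (xl + h <= x[0] <= xh - h and yl + h <= x[1] <= yh - h):
            return None
    return None


def find_stationary(func, domain, n_scan: int = 41, h: float = DEFAULT_STEP):
    """Locate and classify all stationary points of ``func`` on ``domain``.

    A coarse ``n_scan`` × ``n_scan`` grid of central-difference gradients is
    scanned for cells whose corners bracket sign changes in *both* gradient
    components; each such cell seeds a Newton refinement (converged when the
    gradient norm drops below ``GRAD_TOL``). Nearby duplicates are merged.
    Returns a list of :class:`StationaryPoint`; if none of them is a saddle a
    warning is logged (an empty or saddle-free list is not an error).
    """
    (xl, xh), (yl, yh) = domain
    xs = np.linspace(xl + 1.5 * h, xh - 1.5 * h, n_scan)
    ys = np.linspace(yl + 1.5 * h, yh - 1.5 * h, n_scan)
    # batch-evaluate the 4 shifted grids for gradient components
    gx = np.empty((n_scan, n_scan))
    gy = np.empty((n_scan, n_scan))
    xg, yg = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([xg.ravel(), yg.ravel()])

    def batch(shift):
        vals = np.asarray(func(pts + shift), dtype=float)
        return vals.reshape(n_scan, n_scan)

    gx[:] = (batch([h, 0.0]) - batch([-h, 0.0])) / (2 * h)
    gy[:] = (batch([0.0, h]) - batch([0.0, -h])) / (2 * h)

    found: list[StationaryPoint] = []
    for i in range(n_scan - 1):
        for j in range(n_scan - 1):
            cx = gx[i : i + 2, j : j + 2]
            cy = gy[i : i + 2, j : j + 2]
            if cx.min() <= 0 <= cx.max() and cy.min() <= 0 <= cy.max():
                seed = (0.5 * (xs[i] + xs[i + 1]), 0.5 * (ys[j] + ys[j + 1]))
                pt = _newton_refine(func, seed, domain, h)
                if pt is None:
                    continue
                dup = next(
                    (
                        k
                        for k, q in enumerate(found)
                        if np.hypot(
                            q.location[0] - pt.location[0], q.location[1] - pt.location[1]
                        )
                        < MERGE_DISTANCE
                    ),
                    None,
                )
                if dup is None:
                    found.append(pt)
                elif pt.gradient_norm < found[dup].gradient_norm:
                    found[dup] = pt
    if not any(p.kind == "saddle" for p in found):
        logger.warning("no saddle point found on the surface (found %d stationary points)",
                       len(found))
    return found


def energetics(
    surface: Surface2D,
    ts: StationaryPoint,
    reactant_bin: tuple[int, int],
    product_bin: tuple[int, int],
) -> dict:
    """Activation and reaction free energies from a surface and its TS.

    ``dG_act = F(TS) - F(reactant)``; ``dG_rxn = F(product) - F(reactant)``.
    Uncertainties combine the per-bin variances (the TS uses the variance of
    the bin containing it) assuming independence. Both differences are
    invariant under anchor shifts of the surface.
    """
    ri, rj = reactant_bin
    pi, pj = product_bin
    f_r = surface.value_at(ri, rj)
    f_p = surface.value_at(pi, pj)
    flat = int(surface.grid.assign(np.array([ts.location]))[0])
    var = surface.variance

    def v(i, j):
        if var is None or not np.isfinite(var[i, j]):
            return 0.0
        return float(var[i, j])

    v_ts = v(*surface.grid.unravel(flat)) if flat >= 0 else 0.0
    return {
        "dg_activation": float(ts.value - f_r),
        "dg_activation_err": float(np.sqrt(v_ts + v(ri, rj))),
        "dg_reaction": float(f_p - f_r),
        "dg_reaction_err": float(np.sqrt(v(pi, pj) + v(ri, rj))),
        "ts_location": list(ts.location),
    }
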