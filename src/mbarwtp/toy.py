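"""Synthetic umbrella-sampling data with exact analytic oracles.

A :class:`ToySystem` pairs an analytic low-level 2D potential (optionally
augmented by one orthogonal harmonic coordinate with position-dependent
stiffness) with an analytic high-level offset ``g(eta)``, so that every
estimator in the pipeline can be checked against quadrature: the marginal
free-energy surface, the window free energies, and the weighted-TP
correction all have deterministic reference values.

Sampling follows the umbrella protocol: windows on a regular RC grid with
identical harmonic restraints, Boltzmann sampling at a fixed temperature by
Metropolis Monte Carlo, frames recorded with a stride after burn-in. The
generated records carry ``u_low`` and ``u_high = u_low + g(eta)``.

Defaults mirror the reference simulation protocol: RC range 1.50-4.00 Å in
0.05 Å increments, T = 298.15 K. The restraint strength (not stated by the
protocol) defaults to 100 kcal/mol/Å², which puts the restrained RC spread
(~0.077 Å at 298.15 K) on the order of the window spacing so neighboring
windows overlap well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from numpy.polynomial.legendre import leggauss

from .data_model import Grid2D, SampleSet, Surface2D, WindowSpec, bias_energy, beta_from_temperature

logger = logging.getLogger(__name__)

DEFAULT_TEMPERATURE = 298.15
DEFAULT_RC_RANGE = (1.50, 4.00)
DEFAULT_SPACING = 0.05
DEFAULT_FORCE_CONSTANT = 100.0


def gaussian_bump(amplitude: float, center, width: float) -> Callable:
    cx, cy = center

    def g(eta):
        eta = np.asarray(eta, dtype=float)
        d2 = (eta[..., 0] - cx) ** 2 + (eta[..., 1] - cy) ** 2
        return amplitude * np.exp(-d2 / (2.0 * width**2))

    return g


@dataclass
class ToySystem:
    """Analytic low/high Hamiltonian pair on a 2D reaction coordinate.

    ``potential(eta)`` is the low-level 2D potential (kcal/mol, vectorized
    over an (..., 2) array). ``high_offset(eta)`` is the perturbation
    ``g = U_H - U_L`` as a function of the RC. If ``ortho_k0`` is set, an
    orthogonal coordinate z with energy ``½ k_z(eta) z²`` and
    ``k_z = k0 (1 + gamma * eta1²)`` is added; its Gaussian marginal is known
    in closed form, making the coupled case an exact oracle too.
    """

    potential: Callable
    high_offset: Callable
    temperature: float = DEFAULT_TEMPERATURE
    seed: int = 0
    name: str = "custom"
    ortho_k0: float | None = None
    ortho_gamma: float = 0.0

    def __post_init__(self) -> None:
        self.beta = beta_from_temperature(self.temperature)

    # -- constructors -------------------------------------------------------

    @classmethod
    def double_well(
        cls,
        barrier: float = 5.0,
        well_position: float = 0.8,
        k_ortho: float = 10.0,
        bump_amplitude: float = 2.0,
        bump_center=(0.0, 0.4),
        bump_width: float = 0.6,
        temperature: float = DEFAULT_TEMPERATURE,
        seed: int = 0,
        **kwargs,
    ) -> "ToySystem":
        """Double well along eta1 with minima at (±well_position, 0), saddle at (0, 0).

        ``U = barrier * ((eta1/a)² - 1)² + ½ k_ortho eta2²`` with
        ``a = well_position``; the low-level barrier height equals ``barrier``
        exactly. The default wells at ±0.8 sit well inside a [-1, 1] window
        range, so all stationary points are interior to the sampled region.
        The high-level offset is a smooth Gaussian bump (default max
        2 kcal/mol) so the two Hamiltonians overlap well.
        """
        a2 = well_position**2

        def u(eta):
            eta = np.asarray(eta, dtype=float)
            return barrier * (eta[..., 0] ** 2 / a2 - 1.0) ** 2 + 0.5 * k_ortho * eta[..., 1] ** 2

        return cls(
            potential=u,
            high_offset=gaussian_bump(bump_amplitude, bump_center, bump_width),
            temperature=temperature,
            seed=seed,
            name="double_well",
            **kwargs,
        )

    @classmethod
    def harmonic(
        cls,
        k=(20.0, 20.0),
        center=(0.0, 0.0),
        offset: Callable | float = 0.0,
        temperature: float = DEFAULT_TEMPERATURE,
        seed: int = 0,
        **kwargs,
    ) -> "ToySystem":
        """Separable harmonic low-level potential; offset may be a constant."""

        def u(eta):
            eta = np.asarray(eta, dtype=float)
            return 0.5 * (
                k[0] * (eta[..., 0] - center[0]) ** 2 + k[1] * (eta[..., 1] - center[1]) ** 2
            )

        if not callable(offset):
            c = float(offset)

            def g(eta):
                eta = np.asarray(eta, dtype=float)
                return np.full(eta.shape[:-1], c)
        else:
            g = offset
        return cls(potential=u, high_offset=g, temperature=temperature, seed=seed,
                   name="harmonic", **kwargs)

    # -- energies -----------------------------------------------------------

    def k_ortho_of(self, eta) -> np.ndarray:
        eta = np.asarray(eta, dtype=float)
        return self.ortho_k0 * (1.0 + self.ortho_gamma * eta[..., 0] ** 2)

    def energy_low(self, coords) -> np.ndarray:
        """U_L at full coordinates: (..., 2) or (..., 3) with the z column last."""
        coords = np.asarray(coords, dtype=float)
        u = self.potential(coords[..., :2])
        if self.ortho_k0 is not None:
            if coords.shape[-1] < 3:
                raise ValueError("system has an orthogonal coordinate; pass (eta1, eta2, z)")
            u = u + 0.5 * self.k_ortho_of(coords[..., :2]) * coords[..., 2] ** 2
        return u

    def marginal_free_energy(self, eta, level: str = "low") -> np.ndarray:
        """Pointwise marginal free energy over z (up to a constant), kcal/mol."""
        eta = np.asarray(eta, dtype=float)
        f = self.potential(eta)
        if self.ortho_k0 is not None:
            # Gaussian integral over z: -(1/beta) ln sqrt(2 pi / (beta k_z))
            f = f + 0.5 / self.beta * np.log(self.beta * self.k_ortho_of(eta) / (2 * np.pi))
        if level == "high":
            f = f + self.high_offset(eta)
        elif level != "low":
            raise ValueError("level must be 'low' or 'high'")
        return f

    @property
    def ndim(self) -> int:
        return 3 if self.ortho_k0 is not None else 2


def make_windows(
    rc_range=DEFAULT_RC_RANGE,
    spacing: float = DEFAULT_SPACING,
    force_constant: float = DEFAULT_FORCE_CONSTANT,
    rc_range2=None,
) -> list[WindowSpec]:
    """Regular 2D grid of umbrella windows with identical force constants.

    Centers run from ``rc_range[0]`` to ``rc_range[1]`` inclusive in steps of
    ``spacing`` on each axis (the second axis may differ via ``rc_range2``).
    Window indices are row-major and deterministic.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    lo, hi = rc_range
    lo2, hi2 = rc_range2 if rc_range2 is not None else rc_range
    n1 = int(round((hi - lo) / spacing)) + 1
    n2 = int(round((hi2 - lo2) / spacing)) + 1
    ax1 = lo + spacing * np.arange(n1)
    ax2 = lo2 + spacing * np.arange(n2)
    windows = []
    for i, c1 in enumerate(ax1):
        for j, c2 in enumerate(ax2):
            windows.append(
                WindowSpec(
                    index=i * n2 + j,
                    center=(float(c1), float(c2)),
                    force_constants=(force_constant, force_constant),
                )
            )
    return windows


def _metropolis(system, windows, n_frames, burn_in, stride, step, rng):
    """Vectorized Metropolis: one chain per window, advanced in lockstep."""
    beta = system.beta
    s = len(windows)
    d = system.ndim
    centers = np.array([w.center for w in windows])
    ks = np.array([w.force_constants for w in windows])
    x = np.zeros((s, d))
    x[:, :2] = centers  # start at the restraint centers

    def energy(pos):
        dx = pos[:, :2] - centers
        bias = 0.5 * (ks * dx * dx).sum(axis=1)
        return system.energy_low(pos) + bias

    e = energy(x)
    out = np.empty((s, n_frames, d))
    accepted = 0
    proposed = 0
    n_sweeps = burn_in + n_frames * stride
    for sweep in range(n_sweeps):
        prop = x + rng.normal(scale=step, size=(s, d))
        ep = energy(prop)
        acc = rng.random(s) < np.exp(np.minimum(0.0, -beta * (ep - e)))
        x[acc] = prop[acc]
        e[acc] = ep[acc]
        accepted += int(acc.sum())
        proposed += s
        k = sweep - burn_in
        if k >= 0 and (k + 1) % stride == 0:
            out[:, (k + 1) // stride - 1] = x
    rate = accepted / proposed
    if not 0.1 <= rate <= 0.9:
        suggestion = step * (0.5 if rate < 0.1 else 2.0)
        logger.warning(
            "Metropolis acceptance rate %.3f outside [0.1, 0.9]; "
            "consider step size ~%.3g Å", rate, suggestion,
        )
    return out, rate


def _default_step(system, force_constant: float) -> float:
    if force_constant > 0:
        return float(1.0 * np.sqrt(1.0 / (system.beta * force_constant)))
    return 0.3


def sample_window(
    system: ToySystem,
    window: WindowSpec,
    n_frames: int,
    burn_in: int = 500,
    stride: int = 5,
    step: float | None = None,
    seed: int | None = None,
):
    """Metropolis samples from one biased window.

    Returns ``(rc, u_low, u_high)`` arrays of length ``n_frames``. The chain
    targets ``exp(-beta (U_L + W_i))``, starts at the window center, discards
    ``burn_in`` sweeps, and records every ``stride``-th sweep thereafter.
    Reproducible given the seed (default: derived from the system seed and
    the window index). The acceptance rate is logged and a warning is issued
    outside [0.1, 0.9].
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if step is None:
        step = _default_step(system, max(window.force_constants))
    if seed is None:
        seed = (system.seed * 100_003 + window.index) % (2**31 - 1)
    rng = np.random.default_rng(seed)
    coords, _ = _metropolis(system, [window], n_frames, burn_in, stride, step, rng)
    coords = coords[0]
    rc = coords[:, :2]
    u_low = system.energy_low(coords)
    u_high = u_low + system.high_offset(rc)
    return rc, u_low, u_high


def sample_windows(
    system: ToySystem,
    windows: list[WindowSpec],
    n_frames: int,
    burn_in: int = 500,
    stride: int = 5,
    step: float | None = None,
    with_high: bool = True,
) -> SampleSet:
    """Sample every window (vectorized, one lockstep chain per window).

    Equivalent in distribution to calling :func:`sample_window` per window;
    all chains share one seeded generator, so the result is deterministic
    given ``system.seed``.
    """
    if step is None:
        step = _default_step(system, max(max(w.force_constants) for w in windows))
    rng = np.random.default_rng(system.seed)
    coords, rate = _metropolis(system, windows, n_frames, burn_in, stride, step, rng)
    logger.info("sampled %d windows x %d frames (acceptance %.3f)", len(windows), n_frames, rate)
    s = len(windows)
    flat = coords.reshape(s * n_frames, system.ndim)
    rc = flat[:, :2]
    u_low = system.energy_low(flat)
    u_high = (u_low + system.high_offset(rc)) if with_high else None
    widx = np.repeat([w.index for w in windows], n_frames)
    return SampleSet(windows, widx, rc, u_low, system.temperature, u_high=u_high)


# ---------------------------------------------------------------------------
# analytic oracles


def _bin_quadrature(fvals_fn, grid: Grid2D, beta: float, order: int = 7) -> np.ndarray:
    """Per-bin -1/beta ln <e^{-beta f}>_bin by tensor Gauss-Legendre quadrature."""
    nodes, weights = leggauss(order)
    w1, w2 = grid.bin_width
    out = np.empty(grid.shape)
    x1 = grid.axis1[:, None] + 0.5 * w1 * nodes[None, :]  # (n1, order)
    x2 = grid.axis2[:, None] + 0.5 * w2 * nodes[None, :]
    for i in range(grid.shape[0]):
        for j in range(grid.shape[1]):
            gx, gy = np.meshgrid(x1[i], x2[j], indexing="ij")
            pts = np.stack([gx, gy], axis=-1)
            f = fvals_fn(pts)
            ww = np.outer(weights, weights) / 4.0  # normalized to the bin area
            m = f.min()
            avg = (ww * np.exp(-beta * (f - m))).sum()
            out[i, j] = m - np.log(avg) / beta
    return out


def analytic_surface(
    system: ToySystem,
    grid: Grid2D,
    level: str = "low",
    anchor: tuple[int, int] | None = None,
    order: int = 7,
) -> Surface2D:
    """Exact binned marginal free-energy surface (quadrature oracle).

    Matches the estimator's convention: each bin's value is the exponential
    (Boltzmann) average of the pointwise marginal free energy over the bin
    area, so the histogram estimator converges to this surface bin by bin.
    Anchored like the estimators (``anchor=None``: minimum-value bin at 0).
    """
    vals = _bin_quadrature(lambda pts: system.marginal_free_energy(pts, level), grid,
                           system.beta, order)
    occupied = np.ones(grid.shape, dtype=bool)
    if anchor is None:
        i, j = np.unravel_index(int(np.argmin(vals)), grid.shape)
    else:
        i, j = anchor
    return Surface2D(grid, vals - vals[i, j], occupied=occupied)


def analytic_wtp_delta(system: ToySystem, grid: Grid2D, order: int = 7) -> np.ndarray:
    """Exact per-bin weighted-TP correction for the toy pair (quadrature).

    ``dF(bin) = -(1/beta) ln < e^{-beta g} >_bin`` with the average taken in
    the unbiased low-level ensemble restricted to the bin.
    """
    f_low = _bin_quadrature(lambda pts: system.marginal_free_energy(pts, "low"),
                            grid, system.beta, order)
    f_high = _bin_quadrature(lambda pts: system.marginal_free_energy(pts, "high"),
                             grid, system.beta, order)
    return f_high - f_low


def window_free_energy_quadrature(
    system: ToySystem, window: WindowSpec, span: float = 6.0, n_points: int = 801
) -> float:
    """Reduced biased free energy ``beta f^(b)`` of one window by quadrature.

    Integrates ``exp(-beta (F_marginal + W))`` over the RC plane on a dense
    trapezoidal grid spanning ``span`` Å around the window center (plus the
    restraint-free marginal's extent). Differences between windows of the
    same system are directly comparable to the MBAR ``f_biased`` values.
    """
    cx, cy = window.center
    xs = np.linspace(cx - span, cx + span, n_points)
    ys = np.linspace(cy - span, cy + span, n_points)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.stack([gx, gy], axis=-1)
    f = system.marginal_free_energy(pts, "low") + bias_energy(window, pts)
    m = f.min()
    val = np.trapezoid(
        np.trapezoid(np.exp(-system.beta * (f - m)), ys, axis=1), xs, axis=0
    )
    return float(system.beta * m - np.log(val))
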