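"""Multistate reweighting (MBAR) for 2D umbrella sampling.

Solves the self-consistent equations for the biased window free energies

    exp(-f_k) = sum_n exp(-u_k(x_n)) / sum_t N_t exp(f_t - u_t(x_n)),

where ``u_k = beta * W_k`` is the reduced bias of window ``k`` (the unbiased
low-level energy cancels between numerator and denominator because every
window shares the same underlying Hamiltonian). From the solution follow the
per-frame unbiased weights, the window overlap matrix, and the free-energy
covariance machinery.

Window sets laid out on a regular 2D grid with per-axis force constants admit
a Kronecker factorization of the bias matrix, ``u[n, (i,j)] = A[n,i] + B[n,j]``,
which turns every O(N·S) sweep into two dense (N × n1) @ (n1 × n2) matrix
products. This makes hundreds of windows with ~10^6 total frames tractable on
one core; irregular window sets fall back to a chunked dense path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .data_model import OUT_OF_GRID, SampleSet

logger = logging.getLogger(__name__)

#: Minimum useful neighbor overlap for reliable multistate reweighting.
OVERLAP_THRESHOLD = 0.03

_CHUNK_ENTRIES = 40_000_000  # max bias-matrix entries held at once (general path)


class MBARConvergenceError(RuntimeError):
    """Raised when the self-consistent iteration fails to reach tolerance."""

    def __init__(self, residual: float, n_iterations: int):
        super().__init__(
            f"MBAR did not converge: residual {residual:.3e} after {n_iterations} iterations"
        )
        self.residual = residual
        self.n_iterations = n_iterations


@dataclass
class MBARSolution:
    """Converged window free energies and per-frame unbiased weights.

    ``f_biased`` are the reduced (dimensionless, units of kT) biased free
    energies ``beta * f_k^(b)``, anchored so the first window is zero.
    ``log_weights`` holds ``ln w^0`` of the unnormalized unbiased
    weights, ``w^0(x_n) = 1 / sum_k N_k exp(f_k - u_k(x_n))``.
    """

    f_biased: np.ndarray
    log_weights: np.ndarray
    converged: bool
    residual: float
    n_iterations: int

    @property
    def weights_unbiased(self) -> np.ndarray:
        """Unnormalized unbiased weights ``w^0`` per frame."""
        return np.exp(self.log_weights)

    @property
    def weights_normalized(self) -> np.ndarray:
        """Unbiased weights normalized to sum to 1 over all frames."""
        shift = self.log_weights.max()
        w = np.exp(self.log_weights - shift)
        return w / w.sum()

    def f_biased_kcal(self, beta: float) -> np.ndarray:
        """Biased free energies in kcal/mol."""
        return self.f_biased / beta


@dataclass
class CovarianceModel:
    """MBAR covariance matrix over the S windows and M bin-restricted states."""

    theta: np.ndarray
    weight_matrix_shape: tuple[int, int]
    n_windows: int
    bin_ids: np.ndarray  # flat grid bin id for each of the M bin columns

    def delta2_f(self, bin_a: int, bin_b: int) -> float:
        """Variance of the free-energy difference between two grid bins.

        ``bin_a``/``bin_b`` are flat grid bin ids; both must be occupied.
        Returns ``Theta_aa - 2 Theta_ab + Theta_bb`` in units of (kT)².
        """
        ids = self.bin_ids.tolist()
        try:
            a = self.n_windows + ids.index(bin_a)
            b = self.n_windows + ids.index(bin_b)
        except ValueError as exc:
            raise ValueError(f"bin not among occupied covariance states: {exc}") from None
        return float(self.theta[a, a] - 2.0 * self.theta[a, b] + self.theta[b, b])


# ---------------------------------------------------------------------------
# bias models


class _DenseBias:
    """General window layout: reduced bias matrix computed in row chunks."""

    def __init__(self, samples: SampleSet):
        self.beta = samples.beta
        self.rc = samples.rc
        self.centers = np.array([w.center for w in samples.windows])
        self.ks = np.array([w.force_constants for w in samples.windows])
        self.counts = samples.frame_counts.astype(float)
        self.n = len(self.rc)
        self.s = len(self.centers)
        self._chunk = max(1, int(_CHUNK_ENTRIES // max(self.s, 1)))

    def _u_chunk(self, sl: slice) -> np.ndarray:
        d1 = self.rc[sl, 0, None] - self.centers[None, :, 0]
        d2 = self.rc[sl, 1, None] - self.centers[None, :, 1]
        return self.beta * 0.5 * (self.ks[None, :, 0] * d1 * d1 + self.ks[None, :, 1] * d2 * d2)

    def pass_through(self, f: np.ndarray):
        """One O(N·S) pass: returns (sum_n ln D_n, c_k = sum_n N_k e^{f_k-u}/D_n,
        ln D_n per frame, and the SCF image -ln sum_n e^{-u_k}/D_n)."""
        logn = np.log(self.counts)
        obj = 0.0
        c = np.zeros(self.s)
        scf = np.zeros(self.s)
        log_d = np.empty(self.n)
        for start in range(0, self.n, self._chunk):
            sl = slice(start, min(start + self._chunk, self.n))
            u = self._u_chunk(sl)
            logits = (f + logn)[None, :] - u
            m = logits.max(axis=1, keepdims=True)
            e = np.exp(logits - m)
            dsum = e.sum(axis=1)
            ld = m[:, 0] + np.log(dsum)
            log_d[sl] = ld
            obj += ld.sum()
            c += (e / dsum[:, None]).sum(axis=0)
            scf += np.exp(-u - ld[:, None]).sum(axis=0)
        with np.errstate(divide="ignore"):
            scf_f = -np.log(scf)
        return obj, c, log_d, scf_f

    def weight_matrix(self, f: np.ndarray, log_d: np.ndarray, sl: slice) -> np.ndarray:
        """Rows ``sl`` of the N×S MBAR weight matrix W_nk = e^{f_k-u_nk}/D_n."""
        return np.exp(f[None, :] - self._u_chunk(sl) - log_d[sl, None])


class _GridBias:
    """Kronecker-factorized bias for windows on a full Cartesian product grid."""

    def __init__(self, samples: SampleSet, i_of, j_of, ax1, ax2, k1, k2):
        beta = samples.beta
        self.n = samples.n_frames
        self.s = len(samples.windows)
        self.shape = (len(ax1), len(ax2))
        self.i_of, self.j_of = i_of, j_of  # window order -> grid position
        counts = samples.frame_counts.astype(float)
        self.counts = counts
        cnt = np.zeros(self.shape)
        cnt[i_of, j_of] = counts
        self.log_cnt = np.where(cnt > 0, np.log(np.maximum(cnt, 1)), -np.inf)
        a = beta * 0.5 * k1[None, :] * (samples.rc[:, 0, None] - ax1[None, :]) ** 2
        b = beta * 0.5 * k2[None, :] * (samples.rc[:, 1, None] - ax2[None, :]) ** 2
        self.sa = a.min(axis=1)
        self.sb = b.min(axis=1)
        self.ea = np.exp(-(a - self.sa[:, None]))
        self.eb = np.exp(-(b - self.sb[:, None]))

    def _fgrid(self, f: np.ndarray) -> np.ndarray:
        fg = np.full(self.shape, -np.inf)
        fg[self.i_of, self.j_of] = f
        return fg

    def pass_through(self, f: np.ndarray):
        fg = self._fgrid(f) + self.log_cnt
        c0 = np.max(fg[np.isfinite(fg)])
        m = np.exp(np.where(np.isfinite(fg), fg - c0, -np.inf))
        t = self.ea @ m  # (N, n2)
        dprime = np.einsum("nj,nj->n", t, self.eb)
        log_d = c0 - self.sa - self.sb + np.log(dprime)
        # sum_n e^{-A-B}/D = e^{-c0} * q  with  D = e^{c0 - sa - sb} * d'
        q = (self.ea / dprime[:, None]).T @ self.eb  # (n1, n2)
        c_grid = m * q
        with np.errstate(divide="ignore"):
            scf_grid = c0 - np.log(q)
        return (
            float(log_d.sum()),
            c_grid[self.i_of, self.j_of],
            log_d,
            scf_grid[self.i_of, self.j_of],
        )

    def weight_matrix(self, f: np.ndarray, log_d: np.ndarray, sl: slice) -> np.ndarray:
        w = np.empty((log_d[sl].shape[0], self.s))
        ea, eb = self.ea[sl], self.eb[sl]
        # e^{-u} = ea * eb * e^{-sa-sb}, so W = e^f * ea * eb * e^{-(log_d+sa+sb)}
        scale = np.exp(-(log_d[sl] + self.sa[sl] + self.sb[sl]))
        for t, (i, j) in enumerate(zip(self.i_of, self.j_of)):
            w[:, t] = np.exp(f[t]) * ea[:, i] * eb[:, j] * scale
        return w


def _make_bias_model(samples: SampleSet):
    """Choose the Kronecker fast path when windows form a full product grid."""
    centers = np.array([w.center for w in samples.windows])
    ks = np.array([w.force_constants for w in samples.windows])
    ax1, i_of = np.unique(centers[:, 0], return_inverse=True)
    ax2, j_of = np.unique(centers[:, 1], return_inverse=True)
    if len(ax1) * len(ax2) == len(centers) and len(centers) > 1:
        keys = set(zip(i_of.tolist(), j_of.tolist()))
        if len(keys) == len(centers):
            k1 = np.zeros(len(ax1))
            k2 = np.zeros(len(ax2))
            ok = True
            for t in range(len(centers)):
                for arr, pos, val in ((k1, i_of[t], ks[t, 0]), (k2, j_of[t], ks[t, 1])):
                    if arr[pos] == 0:
                        arr[pos] = val
                    elif not np.isclose(arr[pos], val):
                        ok = False
            if ok:
                logger.debug("MBAR: using Kronecker-factorized bias (grid windows)")
                return _GridBias(samples, i_of, j_of, ax1, ax2, k1, k2)
    return _DenseBias(samples)


# ---------------------------------------------------------------------------
# solver


def solve_mbar(
    samples: SampleSet,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    solver: str = "hybrid",
) -> MBARSolution:
    """Solve the MBAR equations for the biased window free energies.

    Parameters
    ----------
    samples
        Umbrella-sampling frames; every window must contribute at least one.
    tol
        Convergence tolerance on the maximum absolute change of the reduced
        free energies over one self-consistent sweep.
    max_iter
        Iteration budget (self-consistent sweeps plus optimizer gradient
        evaluations).
    solver
        ``"hybrid"`` (default): a few self-consistent sweeps, then L-BFGS on
        the convex MBAR objective, then self-consistent polish to ``tol``.
        ``"scf"``: pure self-consistent iteration.

    Returns
    -------
    MBARSolution
        With ``f_biased`` anchored at the first window and per-frame
        log-weights. Raises :class:`MBARConvergenceError` on failure.
    """
    counts = samples.frame_counts
    if np.any(counts == 0):
        empty = [w.index for w, c in zip(samples.windows, counts) if c == 0]
        raise ValueError(f"every window needs at least one frame; empty: {empty}")
    s = samples.n_windows
    if s == 1:
        return MBARSolution(
            f_biased=np.zeros(1),
            log_weights=np.full(samples.n_frames, -np.log(float(counts[0]))),
            converged=True,
            residual=0.0,
            n_iterations=1,
        )

    model = _make_bias_model(samples)
    nk = counts.astype(float)
    f = np.zeros(s)
    n_eval = 0

    def sweep(f):
        nonlocal n_eval
        n_eval += 1
        _, _, log_d, scf_f = model.pass_through(f)
        new = scf_f - scf_f[0]
        return new, float(np.abs(new - (f - f[0])).max()), log_d

    residual = np.inf
    log_d = None
    if solver == "hybrid":
        for _ in range(5):
            f, residual, log_d = sweep(f)
            if residual <= tol:
                break
        if residual > tol:
            def objective(x):
                nonlocal n_eval
                n_eval += 1
                obj, c, _, _ = model.pass_through(x)
                return obj - float(nk @ x), c - nk

            res = minimize(
                objective,
                f,
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-9},
            )
            f = res.x - res.x[0]
    elif solver != "scf":
        raise ValueError(f"unknown solver {solver!r}")

    # self-consistent polish; also the sole loop for solver="scf"
    while n_eval < max_iter:
        f, residual, log_d = sweep(f)
        if residual <= tol:
            break
    if residual > tol or log_d is None:
        raise MBARConvergenceError(residual, n_eval)

    return MBARSolution(
        f_biased=f,
        log_weights=-log_d,
        converged=True,
        residual=residual,
        n_iterations=n_eval,
    )


def solution_from_f(samples: SampleSet, f_biased: np.ndarray) -> MBARSolution:
    """Rebuild a solution (with per-frame log-weights) from stored free energies.

    One O(N·S) pass recomputes the weight denominators at the given reduced
    free energies and re-measures the self-consistency residual, so persisted
    solutions stay lightweight (S numbers instead of N).
    """
    f = np.asarray(f_biased, dtype=float)
    f = f - f[0]
    if samples.n_windows == 1:
        return MBARSolution(np.zeros(1), np.full(samples.n_frames,
                            -np.log(float(samples.n_frames))), True, 0.0, 0)
    model = _make_bias_model(samples)
    _, _, log_d, scf_f = model.pass_through(f)
    residual = float(np.abs((scf_f - scf_f[0]) - f).max())
    return MBARSolution(f, -log_d, converged=True, residual=residual, n_iterations=0)


def unbiased_weights(samples: SampleSet, sol: MBARSolution, normalized: bool = False) -> np.ndarray:
    """Per-frame unbiased weights ``w^0`` (optionally normalized to sum to 1).

    ``w^0(x_n) = 1 / sum_k N_k exp(f_k - u_k(x_n))``, evaluated in log space
    during the solve; this is the weight a frame carries in any unbiased
    low-level ensemble average.
    """
    if not sol.converged:
        raise ValueError("MBAR solution not converged")
    return sol.weights_normalized if normalized else sol.weights_unbiased


def _weight_matrix(samples: SampleSet, sol: MBARSolution):
    model = _make_bias_model(samples)
    # recompute log D at the converged f for consistency
    _, _, log_d, _ = model.pass_through(sol.f_biased)
    return model, log_d


def overlap_matrix(samples: SampleSet, sol: MBARSolution) -> np.ndarray:
    """Window-pair phase-space overlap matrix ``O_ij = N_j sum_n W_ni W_nj``.

    Rows sum to 1; entries below :data:`OVERLAP_THRESHOLD` between a window
    and all of its peers indicate insufficient overlap and trigger a warning.
    """
    if not sol.converged:
        raise ValueError("MBAR solution not converged")
    s = samples.n_windows
    if s == 1:
        return np.ones((1, 1))
    model, log_d = _weight_matrix(samples, sol)
    n = samples.n_frames
    chunk = max(1, int(_CHUNK_ENTRIES // s))
    wtw = np.zeros((s, s))
    for start in range(0, n, chunk):
        sl = slice(start, min(start + chunk, n))
        w = model.weight_matrix(sol.f_biased, log_d, sl)
        wtw += w.T @ w
    o = wtw * samples.frame_counts.astype(float)[None, :]
    worst = np.where(np.eye(s, dtype=bool), np.nan, o)
    isolated = np.nanmax(worst, axis=1) < OVERLAP_THRESHOLD
    if np.any(isolated):
        bad = [samples.windows[t].index for t in np.flatnonzero(isolated)]
        logger.warning(
            "overlap below the 0.03 reliability threshold for windows %s; "
            "MBAR estimates bridging these windows are unreliable",
            bad,
        )
    return o


def fe_covariance(samples: SampleSet, sol: MBARSolution, bins: np.ndarray) -> CovarianceModel:
    """Covariance matrix over window states and bin-restricted unbiased states.

    Builds the N×(S+M) weight matrix whose first S columns are the biased
    window states and whose last M columns restrict the unbiased ensemble to
    each occupied grid bin, then evaluates

        Theta = pinv( pinv(W^T W) - N + 1 1^T / N_total )

    with Moore-Penrose pseudo-inverses (relative cutoff 1e-12). The variance
    of a free-energy difference between bins a and b follows as
    ``Theta_aa - 2 Theta_ab + Theta_bb`` (units of (kT)²).

    Unoccupied bins are excluded with a warning. Windows whose frames are all
    identical give a singular contribution; they are flagged as unreliable.
    """
    if not sol.converged:
        raise ValueError("MBAR solution not converged")
    s = samples.n_windows
    n = samples.n_frames
    bins = np.asarray(bins)
    occupied_ids = np.unique(bins[bins != OUT_OF_GRID])
    m = len(occupied_ids)
    if m < 1:
        raise ValueError("need at least one occupied bin")

    for w in samples.windows:
        mask = samples.window_index == w.index
        if mask.sum() > 1 and np.allclose(samples.rc[mask], samples.rc[mask][0]):
            logger.warning(
                "window %d has all-identical frames; its covariance is unreliable", w.index
            )

    model, log_d = _weight_matrix(samples, sol)
    w0 = np.exp(-log_d)
    wmat = np.empty((n, s + m))
    chunk = max(1, int(_CHUNK_ENTRIES // s))
    for start in range(0, n, chunk):
        sl = slice(start, min(start + chunk, n))
        wmat[sl, :s] = model.weight_matrix(sol.f_biased, log_d, sl)
    for col, b in enumerate(occupied_ids):
        ind = bins == b
        wmat[:, s + col] = np.where(ind, w0, 0.0)
        wmat[:, s + col] /= wmat[:, s + col].sum()

    wtw = wmat.T @ wmat
    nhat = np.zeros((s + m, s + m))
    nhat[:s, :s] = np.diag(samples.frame_counts.astype(float))
    ones = np.ones((s + m, 1))
    inner = np.linalg.pinv(wtw, rcond=1e-12) - nhat + (ones @ ones.T) / float(n)
    theta = np.linalg.pinv(inner, rcond=1e-12)
    theta = 0.5 * (theta + theta.T)
    return CovarianceModel(
        theta=theta,
        weight_matrix_shape=(n, s + m),
        n_windows=s,
        bin_ids=occupied_ids,
    )


def diagnostics_report(samples: SampleSet, sol: MBARSolution, overlap: np.ndarray | None = None) -> dict:
    """JSON-serializable convergence and overlap diagnostics."""
    report = {
        "n_windows": samples.n_windows,
        "n_frames": samples.n_frames,
        "temperature_K": samples.temperature,
        "converged": bool(sol.converged),
        "residual": float(sol.residual),
        "n_iterations": int(sol.n_iterations),
        "f_biased_kcal_mol": sol.f_biased_kcal(samples.beta).tolist(),
    }
    if overlap is not None:
        s = len(overlap)
        off = ~np.eye(s, dtype=bool)
        pairs = [
            [samples.windows[a].index, samples.windows[b].index, float(overlap[a, b])]
            for a in range(s)
            for b in range(s)
            if a < b and overlap[a, b] < OVERLAP_THRESHOLD
        ]
        report["overlap_matrix"] = overlap.tolist()
        report["overlap_threshold"] = OVERLAP_THRESHOLD
        report["sub_threshold_pairs"] = pairs
        report["min_off_diagonal_overlap"] = float(overlap[off].min()) if s > 1 else None
    return report
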