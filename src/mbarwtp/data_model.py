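"""Core domain types for 2D umbrella-sampling free-energy analysis.

Unit conventions used throughout the package:

* reaction coordinates (RC) in Å,
* energies in kcal/mol,
* temperatures in K,
* ``beta = 1 / (k_B * T)`` in mol/kcal with ``k_B = 0.0019872041`` kcal/mol/K.

``beta`` is always derived from the temperature, never user-supplied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Boltzmann constant in kcal/mol/K.
KB_KCAL = 0.0019872041

#: Marker returned by :meth:`Grid2D.assign` for frames outside the grid.
OUT_OF_GRID = -1


def beta_from_temperature(temperature: float) -> float:
    """Return ``1/(k_B T)`` in mol/kcal for a temperature in K."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return 1.0 / (KB_KCAL * temperature)


@dataclass(frozen=True)
class WindowSpec:
    """One biased umbrella window.

    Parameters
    ----------
    index
        Unique window index.
    center
        RC restraint target ``(η1_i, η2_i)`` in Å.
    force_constants
        Harmonic strengths ``(k1_i, k2_i)`` in kcal/mol/Å²; the restraint is
        ``½ k (η − η_i)²`` per dimension.
    n_frames
        Number of frames recorded from this window.
    """

    index: int
    center: tuple[float, float]
    force_constants: tuple[float, float]
    n_frames: int = 0

    def __post_init__(self) -> None:
        if min(self.force_constants) < 0:
            raise ValueError(f"force constants must be >= 0, got {self.force_constants}")
        if self.n_frames < 0:
            raise ValueError("n_frames must be >= 0")


@dataclass(frozen=True)
class Frame:
    """A single sampled configuration, reduced to RC values and energies."""

    window_index: int
    rc: tuple[float, float]
    u_low: float
    u_high: float | None = None
    observables: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.rc)):
            raise ValueError(f"rc must be finite, got {self.rc}")
        if not np.isfinite(self.u_low):
            raise ValueError("u_low must be finite")
        if self.u_high is not None and not np.isfinite(self.u_high):
            raise ValueError("u_high must be finite when present")


def bias_energy(window: WindowSpec, rc) -> float:
    """Harmonic restraint energy ``W_i(η)`` of ``window`` at RC point ``rc``.

    ``W_i(η) = ½ k1_i (η1 − η1_i)² + ½ k2_i (η2 − η2_i)²`` in kcal/mol.
    Accepts a single RC pair or an (N, 2) array; returns a scalar or (N,) array.
    """
    rc = np.asarray(rc, dtype=float)
    d = rc - np.asarray(window.center)
    k = np.asarray(window.force_constants)
    w = 0.5 * (d * d * k).sum(axis=-1)
    return float(w) if w.ndim == 0 else w


class SampleSet:
    """All frames from all windows, stored column-wise as numpy arrays.

    Attributes
    ----------
    windows : list[WindowSpec]
        Window table; ``windows[s].n_frames`` equals the number of frames whose
        ``window_index`` is ``windows[s].index``.
    rc : (N, 2) ndarray
        RC values in Å.
    u_low : (N,) ndarray
        Unbiased low-level potential energies in kcal/mol.
    u_high : (N,) ndarray or None
        High-level energies; NaN marks frames where they were not evaluated.
    observables : dict[str, (N,) ndarray]
        Optional named per-frame observables.
    """

    def __init__(
        self,
        windows: Sequence[WindowSpec],
        window_index: np.ndarray,
        rc: np.ndarray,
        u_low: np.ndarray,
        temperature: float,
        u_high: np.ndarray | None = None,
        observables: Mapping[str, np.ndarray] | None = None,
    ) -> None:
        self.windows = list(windows)
        self.window_index = np.asarray(window_index, dtype=np.int64)
        self.rc = np.asarray(rc, dtype=float)
        self.u_low = np.asarray(u_low, dtype=float)
        self.u_high = None if u_high is None else np.asarray(u_high, dtype=float)
        self.observables = {k: np.asarray(v, dtype=float) for k, v in (observables or {}).items()}
        self.temperature = float(temperature)
        self.beta = beta_from_temperature(temperature)
        self._validate()

    def _validate(self) -> None:
        n = len(self.window_index)
        if self.rc.shape != (n, 2):
            raise ValueError(f"rc must have shape ({n}, 2), got {self.rc.shape}")
        if self.u_low.shape != (n,):
            raise ValueError("u_low length mismatch")
        if self.u_high is not None and self.u_high.shape != (n,):
            raise ValueError("u_high length mismatch")
        for name, v in self.observables.items():
            if v.shape != (n,):
                raise ValueError(f"observable {name!r} length mismatch")
        idx = [w.index for w in self.windows]
        if len(set(idx)) != len(idx):
            raise ValueError("window indices must be unique")
        known = set(idx)
        present = set(np.unique(self.window_index).tolist())
        if not present <= known:
            raise ValueError(f"frames refer to unknown windows: {sorted(present - known)}")
        counts = {i: 0 for i in idx}
        vals, cnts = np.unique(self.window_index, return_counts=True)
        counts.update(dict(zip(vals.tolist(), cnts.tolist())))
        # reconcile declared n_frames with actual counts
        self.windows = [
            WindowSpec(w.index, w.center, w.force_constants, counts[w.index]) for w in self.windows
        ]
        if not np.all(np.isfinite(self.rc)):
            raise ValueError("rc values must be finite")
        if not np.all(np.isfinite(self.u_low)):
            raise ValueError("u_low values must be finite")

    @property
    def n_frames(self) -> int:
        return len(self.window_index)

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def frame_counts(self) -> np.ndarray:
        """Frame count per window, ordered like ``self.windows``."""
        return np.array([w.n_frames for w in self.windows], dtype=np.int64)

    def has_u_high(self) -> bool:
        return self.u_high is not None and bool(np.all(np.isfinite(self.u_high)))

    @classmethod
    def from_frames(
        cls, windows: Sequence[WindowSpec], frames: Sequence[Frame], temperature: float
    ) -> "SampleSet":
        """Build a column-wise set from individual :class:`Frame` records."""
        n = len(frames)
        widx = np.array([f.window_index for f in frames], dtype=np.int64)
        rc = np.array([f.rc for f in frames], dtype=float).reshape(n, 2)
        u_low = np.array([f.u_low for f in frames], dtype=float)
        any_high = any(f.u_high is not None for f in frames)
        u_high = None
        if any_high:
            u_high = np.array(
                [np.nan if f.u_high is None else f.u_high for f in frames], dtype=float
            )
        names: set[str] = set()
        for f in frames:
            if f.observables:
                names.update(f.observables)
        obs = {
            name: np.array(
                [np.nan if not f.observables else f.observables.get(name, np.nan) for f in frames]
            )
            for name in names
        }
        return cls(windows, widx, rc, u_low, temperature, u_high=u_high, observables=obs or None)

    def subset(self, mask: np.ndarray) -> "SampleSet":
        """Return a new SampleSet restricted to frames where ``mask`` is True."""
        return SampleSet(
            self.windows,
            self.window_index[mask],
            self.rc[mask],
            self.u_low[mask],
            self.temperature,
            u_high=None if self.u_high is None else self.u_high[mask],
            observables={k: v[mask] for k, v in self.observables.items()} or None,
        )


class Grid2D:
    """Regular 2D histogram grid over the reaction coordinates.

    Bin ``(i, j)`` covers the half-open rectangle
    ``[c1_i − w1/2, c1_i + w1/2) × [c2_j − w2/2, c2_j + w2/2)``; the bins tile
    the RC range without overlap. Flat bin indices are row-major in
    ``(axis1, axis2)``.
    """

    def __init__(self, axis1: np.ndarray, axis2: np.ndarray, bin_width: tuple[float, float]):
        self.axis1 = np.asarray(axis1, dtype=float)
        self.axis2 = np.asarray(axis2, dtype=float)
        self.bin_width = (float(bin_width[0]), float(bin_width[1]))
        for ax, w in ((self.axis1, self.bin_width[0]), (self.axis2, self.bin_width[1])):
            if ax.ndim != 1 or len(ax) < 1:
                raise ValueError("axes must be non-empty 1D arrays")
            if w <= 0:
                raise ValueError("bin widths must be positive")
            if len(ax) > 1:
                d = np.diff(ax)
                if np.any(d <= 0):
                    raise ValueError("bin centers must be strictly increasing")
                if not np.allclose(d, d[0], rtol=1e-9, atol=1e-12):
                    raise ValueError("bin centers must be evenly spaced")
                if not np.isclose(d[0], w, rtol=1e-9):
                    raise ValueError("bin width must equal center spacing (tiling without gaps)")

    @classmethod
    def from_range(
        cls, lo: float, hi: float, spacing: float, lo2=None, hi2=None, spacing2=None
    ) -> "Grid2D":
        """Grid with centers ``lo, lo+spacing, ..., hi`` on each axis."""
        lo2 = lo if lo2 is None else lo2
        hi2 = hi if hi2 is None else hi2
        spacing2 = spacing if spacing2 is None else spacing2
        n1 = int(round((hi - lo) / spacing)) + 1
        n2 = int(round((hi2 - lo2) / spacing2)) + 1
        ax1 = lo + spacing * np.arange(n1)
        ax2 = lo2 + spacing2 * np.arange(n2)
        return cls(ax1, ax2, (spacing, spacing2))

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.axis1), len(self.axis2))

    @property
    def n_bins(self) -> int:
        return len(self.axis1) * len(self.axis2)

    def centers(self) -> np.ndarray:
        """All bin centers as an (n_bins, 2) array (row-major flat order)."""
        g1, g2 = np.meshgrid(self.axis1, self.axis2, indexing="ij")
        return np.column_stack([g1.ravel(), g2.ravel()])

    def flat_index(self, i: int, j: int) -> int:
        return i * len(self.axis2) + j

    def unravel(self, flat: int) -> tuple[int, int]:
        return divmod(flat, len(self.axis2))

    def assign(self, rc: np.ndarray) -> np.ndarray:
        """Map RC points to flat bin indices; out-of-grid points get ``OUT_OF_GRID``.

        Points exactly on a boundary belong to the higher-index bin (half-open
        convention). Each in-range point maps to exactly one bin.
        """
        rc = np.atleast_2d(np.asarray(rc, dtype=float))
        out = np.empty(len(rc), dtype=np.int64)
        idx = []
        for d, (ax, w) in enumerate(
            ((self.axis1, self.bin_width[0]), (self.axis2, self.bin_width[1]))
        ):
            # edges: ax[0]-w/2, ax[0]+w/2, ... ; searchsorted with side="right"
            # sends boundary points up, matching the half-open convention
            edges = np.concatenate([ax - w / 2, [ax[-1] + w / 2]])
            k = np.searchsorted(edges, rc[:, d], side="right") - 1
            k[(rc[:, d] < edges[0]) | (rc[:, d] >= edges[-1])] = OUT_OF_GRID
            idx.append(k)
        i, j = idx
        ok = (i != OUT_OF_GRID) & (j != OUT_OF_GRID)
        out[ok] = i[ok] * len(self.axis2) + j[ok]
        out[~ok] = OUT_OF_GRID
        n_out = int((~ok).sum())
        if n_out:
            logger.info("assign_bins: %d of %d frames fall outside the grid", n_out, len(rc))
        return out


def assign_bins(samples: SampleSet, grid: Grid2D) -> np.ndarray:
    """Flat bin index per frame of ``samples``; ``OUT_OF_GRID`` for outside points."""
    return grid.assign(samples.rc)


@dataclass
class Surface2D:
    """Values of a field (free energy or observable) on a :class:`Grid2D`.

    All per-bin arrays have the grid's 2D shape. ``value`` is meaningful only
    where ``occupied``; unoccupied bins hold NaN.
    """

    grid: Grid2D
    value: np.ndarray
    variance: np.ndarray | None = None
    count: np.ndarray | None = None
    entropy: np.ndarray | None = None
    occupied: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.value = np.asarray(self.value, dtype=float)
        if self.value.shape != self.grid.shape:
            raise ValueError(f"value shape {self.value.shape} != grid shape {self.grid.shape}")
        if self.occupied is None:
            self.occupied = np.isfinite(self.value)
        self.occupied = np.asarray(self.occupied, dtype=bool)
        if self.variance is not None:
            self.variance = np.asarray(self.variance, dtype=float)
            if np.any(self.variance[self.occupied & np.isfinite(self.variance)] < 0):
                raise ValueError("variance must be >= 0 on occupied bins")
        if self.count is not None:
            self.count = np.asarray(self.count, dtype=np.int64)
            if np.any(self.count < 0):
                raise ValueError("count must be >= 0")

    def value_at(self, i: int, j: int) -> float:
        if not self.occupied[i, j]:
            raise ValueError(f"bin ({i}, {j}) is unoccupied")
        return float(self.value[i, j])

    def anchored(self, anchor: tuple[int, int]) -> "Surface2D":
        """Shifted copy with the anchor bin at zero."""
        i, j = anchor
        ref = self.value_at(i, j)
        return Surface2D(
            self.grid, self.value - ref, self.variance, self.count, self.entropy, self.occupied
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table: eta1, eta2, value, variance, count, entropy, occupied."""
        c = self.grid.centers()
        cols = {
            "eta1": c[:, 0],
            "eta2": c[:, 1],
            "value": self.value.ravel(),
            "variance": (np.full(self.grid.n_bins, np.nan) if self.variance is None
                         else self.variance.ravel()),
            "count": (np.zeros(self.grid.n_bins, dtype=int) if self.count is None
                      else self.count.ravel()),
            "entropy": (np.full(self.grid.n_bins, np.nan) if self.entropy is None
                        else self.entropy.ravel()),
            "occupied": self.occupied.ravel(),
        }
        return pd.DataFrame(cols)
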