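"""Solvent electric fields at bond midpoints and the dipole-field energy.

During the cycloaddition the two nascent C-C bonds develop local dipoles
(charge flows between the diene and dienophile carbons). The surrounding
solvent point charges generate an electric field at each bond midpoint; its
projection on the bond axis couples to the dipole change, stabilizing or
destabilizing the transition state by

    dE = -0.5 (dq2 - dq1) * l_CC * E_hat,

where dq1/dq2 are the Mulliken-charge changes (reactant -> TS) of the two
bonded carbons in e, l_CC the TS bond length in Å, and E_hat the field
projection in atomic units. Unit chain: fields are evaluated in a.u.
(1 a.u. = 51.42 V/Å, positions converted Å -> bohr), the product
e · Å · V/Å is an energy in eV, converted to kcal/mol with 23.0605.
A negative dE is a stabilization of the transition state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .data_model import Grid2D, SampleSet, Surface2D
from .mbar import MBARSolution
from .surface import reweighted_observable

BOHR_IN_ANGSTROM = 0.529177
AU_FIELD_V_PER_ANGSTROM = 51.42
EV_IN_KCAL_MOL = 23.0605


@dataclass
class ChargeConfiguration:
    """Solvent point charges plus named probe points and projection axes.

    Positions in Å, charges in e. ``probe_points`` are the bond midpoints
    (conventionally "M1", "M2"); ``unit_vectors`` the bond-axis unit vectors
    (conventionally "e1" pointing C1->C3 and "e2" pointing C2->C4).
    """

    positions: np.ndarray
    charges: np.ndarray
    probe_points: Mapping[str, np.ndarray]
    unit_vectors: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.charges = np.asarray(self.charges, dtype=float)
        if len(self.charges) != len(self.positions):
            raise ValueError("positions and charges length mismatch")
        self.probe_points = {k: np.asarray(v, dtype=float) for k, v in self.probe_points.items()}
        self.unit_vectors = {k: np.asarray(v, dtype=float) for k, v in self.unit_vectors.items()}
        for name, v in self.unit_vectors.items():
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise ValueError(f"unit vector {name!r} does not have norm 1")
        for name, p in self.probe_points.items():
            d = np.linalg.norm(self.positions - p, axis=1)
            if len(d) and d.min() < 1e-9:
                raise ValueError(f"a charge coincides with probe point {name!r}")


@dataclass(frozen=True)
class DipoleFieldInput:
    """Inputs of the dipole-field energy for one nascent bond."""

    dq1: float                # charge change of the diene carbon, e
    dq2: float                # charge change of the dienophile carbon, e
    bond_length: float        # TS C-C distance, Å
    field_projection: float   # solvent field projected on the bond axis, a.u.

    def __post_init__(self) -> None:
        if self.bond_length <= 0:
            raise ValueError("bond_length must be positive")


def field_at_point(config: ChargeConfiguration, probe: str, direction: str) -> float:
    """Coulomb field of all solvent charges at a probe, projected on an axis (a.u.).

    ``E_j = sum_i q_i (r_j - r_i) / |r_j - r_i|^3`` with positions in bohr and
    charges in e; every charge contributes, with no distance cutoff.
    """
    if probe not in config.probe_points:
        raise KeyError(f"unknown probe point {probe!r}")
    if direction not in config.unit_vectors:
        raise KeyError(f"unknown unit vector {direction!r}")
    rj = config.probe_points[probe] / BOHR_IN_ANGSTROM
    ri = config.positions / BOHR_IN_ANGSTROM
    d = rj[None, :] - ri
    r3 = np.linalg.norm(d, axis=1) ** 3
    if len(r3) and r3.min() < 1e-18:
        raise ValueError(f"charge coincides with probe {probe!r}")
    e_vec = (config.charges[:, None] * d / r3[:, None]).sum(axis=0)
    return float(e_vec @ config.unit_vectors[direction])


def dipole_field_energy(inp: DipoleFieldInput) -> float:
    """Dipole-field interaction energy of one bond, kcal/mol (negative = stabilizing)."""
    ev = -0.5 * (inp.dq2 - inp.dq1) * inp.bond_length * (
        inp.field_projection * AU_FIELD_V_PER_ANGSTROM
    )
    return ev * EV_IN_KCAL_MOL


def total_stabilization(bonds: Sequence[DipoleFieldInput]) -> float:
    """Summed dipole-field energy over the nascent bonds, kcal/mol."""
    return float(sum(dipole_field_energy(b) for b in bonds))


def ensemble_field(
    samples: SampleSet,
    sol: MBARSolution,
    grid: Grid2D,
    configs: Sequence[ChargeConfiguration],
    probe: str,
    direction: str,
    bin_index: tuple[int, int] | None = None,
    level: str = "high",
):
    """Reweighted ensemble average of the field projection, per bin.

    Evaluates the projected field for each frame's charge configuration and
    feeds it through the perturbation-reweighted bin average (the same
    estimator as any other observable). Returns ``(mean, variance)`` surfaces,
    or the scalar pair for ``bin_index`` if given.
    """
    if len(configs) != samples.n_frames:
        raise ValueError(
            f"need one charge configuration per frame ({samples.n_frames}), got {len(configs)}"
        )
    if any(c is None for c in configs):
        raise ValueError("missing charge configuration for at least one frame")
    values = np.array([field_at_point(c, probe, direction) for c in configs])
    name = f"_field_{probe}_{direction}"
    augmented = SampleSet(
        samples.windows,
        samples.window_index,
        samples.rc,
        samples.u_low,
        samples.temperature,
        u_high=samples.u_high,
        observables={**samples.observables, name: values},
    )
    mean, var = reweighted_observable(augmented, sol, grid, name, level=level)
    if bin_index is None:
        return mean, var
    i, j = bin_index
    return float(mean.value[i, j]), float(var.value[i, j])
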