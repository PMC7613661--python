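"""Agent-based model of mechanosensitive Notch signaling between VSMCs.

A one-dimensional array of vascular smooth muscle cells (VSMCs) spans the
arterial wall from the luminal side.  Each cell carries continuous counts of
Notch receptors (N), Jagged (J) and Delta (D) ligands, and the Notch
intracellular domain (I, NICD).  Neighboring cells interact in trans
(receptor of one cell binding a ligand of the next, releasing NICD);
receptors and ligands of the same cell inactivate each other in cis.
Transactivation feeds back on production through Hill functions, and
circumferential Green-Lagrange strain downregulates Notch and Jagged
production through exponential factors exp(A_N E) and exp(A_J E) with
negative mechanosensitivity coefficients.

An endothelial cell on the luminal side presents a constant pool of Jagged
ligands (J_EC) to the first VSMC; the abluminal boundary sees no proteins.

Units: molecules and hours.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "NotchParameters",
    "CellArrayState",
    "SteadyStateResult",
    "MultistabilityWarning",
    "hill",
    "rhs",
    "integrate_to_steady_state",
    "normalized_nicd",
    "phenotype_score",
    "phenotype_label",
    "cell_count",
]

CELL_SIZE_MM = 0.01
INIT_MAX_MOLECULES = 6000.0


class MultistabilityWarning(UserWarning):
    """Independent initializations did not converge to a common steady state."""


@dataclass
class NotchParameters:
    """Kinetic constants of the VSMC Notch-Jagged-Delta network.

    Production rates in molecules/h, interaction rates in 1/(molecules h),
    degradation rates in 1/h.  ``notch_scale`` and ``jagged_scale`` multiply
    the basal Notch and Jagged production rates to emulate over- or
    under-expression.
    """

    N_pr: float = 1400.0
    J_pr: float = 1600.0
    D_pr: float = 100.0
    k_c: float = 5.0e-4
    k_t: float = 2.5e-5
    gamma: float = 0.1
    gamma_I: float = 0.5
    Lambda_N: float = 2.0
    Lambda_J: float = 2.0
    Lambda_D: float = 0.0
    n_N: float = 2.0
    n_J: float = 5.0
    n_D: float = 2.0
    I0: float = 200.0
    A_N: float = -5.79
    A_J: float = -4.17
    J_EC: float = 4000.0
    notch_scale: float = 1.0
    jagged_scale: float = 1.0

    def __post_init__(self) -> None:
        for name in ("N_pr", "J_pr", "D_pr", "k_c", "k_t", "gamma", "gamma_I", "I0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.notch_scale <= 0 or self.jagged_scale <= 0:
            raise ValueError("expression scales must be positive")

    def with_scales(self, notch_scale=None, jagged_scale=None) -> "NotchParameters":
        return replace(
            self,
            notch_scale=self.notch_scale if notch_scale is None else notch_scale,
            jagged_scale=self.jagged_scale if jagged_scale is None else jagged_scale,
        )


def cell_count(wall_thickness_mm: float, cell_size_mm: float = CELL_SIZE_MM) -> int:
    """Number of VSMCs across the wall (stress-free thickness / cell size)."""
    return int(round(wall_thickness_mm / cell_size_mm))


@dataclass
class CellArrayState:
    """Per-cell protein counts and imposed circumferential strains.

    Index 0 is the luminal cell (adjacent to the endothelium).
    """

    N: np.ndarray
    J: np.ndarray
    D: np.ndarray
    I: np.ndarray
    strain: np.ndarray

    def __post_init__(self) -> None:
        arrays = [np.asarray(a, dtype=float) for a in (self.N, self.J, self.D, self.I, self.strain)]
        self.N, self.J, self.D, self.I, self.strain = arrays
        n = {a.shape for a in arrays}
        if len(n) != 1:
            raise ValueError("all per-cell arrays must have the same length")

    @property
    def n_cells(self) -> int:
        return len(self.N)

    @classmethod
    def zeros(cls, strain: np.ndarray) -> "CellArrayState":
        strain = np.asarray(strain, dtype=float)
        z = np.zeros_like(strain)
        return cls(z.copy(), z.copy(), z.copy(), z.copy(), strain)

    @classmethod
    def random(cls, strain: np.ndarray, rng: np.random.Generator) -> "CellArrayState":
        """Uniform random counts in [0, 6000] per protein per cell."""
        strain = np.asarray(strain, dtype=float)
        n = len(strain)
        c = rng.uniform(0.0, INIT_MAX_MOLECULES, size=(4, n))
        return cls(c[0], c[1], c[2], c[3], strain)

    def pack(self) -> np.ndarray:
        return np.concatenate([self.N, self.J, self.D, self.I])

    @classmethod
    def unpack(cls, y: np.ndarray, strain: np.ndarray) -> "CellArrayState":
        n = len(strain)
        return cls(y[:n], y[n : 2 * n], y[2 * n : 3 * n], y[3 * n :], strain)


def hill(I, Lambda: float, n: float, I0: float):
    """Hill-type transactivation feedback on protein production.

    HS(I) = Lambda + (1 - Lambda) / (1 + (I / I0)^n): equals 1 at I = 0 and
    tends to Lambda as NICD accumulates (upregulation for Lambda > 1,
    shutdown for Lambda = 0).
    """
    I = np.asarray(I, dtype=float)
    return Lambda + (1.0 - Lambda) / (1.0 + (np.maximum(I, 0.0) / I0) ** n)


def _neighbor_sums(N, J, D, params):
    """Half-sums of neighbor ligand/receptor counts with boundary conditions.

    The luminal (index 0) cell sees the endothelial Jagged pool J_EC and no
    Notch or Delta; beyond the abluminal cell everything is zero.
    """
    Nl = np.concatenate([[0.0], N[:-1]])
    Nr = np.concatenate([N[1:], [0.0]])
    Jl = np.concatenate([[params.J_EC], J[:-1]])
    Jr = np.concatenate([J[1:], [0.0]])
    Dl = np.concatenate([[0.0], D[:-1]])
    Dr = np.concatenate([D[1:], [0.0]])
    ligands = 0.5 * (Dl + Dr + Jl + Jr)
    receptors = 0.5 * (Nl + Nr)
    return ligands, receptors


def rhs(state: CellArrayState, params: NotchParameters) -> np.ndarray:
    """Time derivatives (molecules/h) of all cell states, packed as the state."""
    N, J, D, I, E = state.N, state.J, state.D, state.I, state.strain
    ligands, receptors = _neighbor_sums(N, J, D, params)
    prod_N = params.N_pr * params.notch_scale * hill(I, params.Lambda_N, params.n_N, params.I0) * np.exp(params.A_N * E)
    prod_J = params.J_pr * params.jagged_scale * hill(I, params.Lambda_J, params.n_J, params.I0) * np.exp(params.A_J * E)
    prod_D = params.D_pr * hill(I, params.Lambda_D, params.n_D, params.I0)
    dN = prod_N - params.k_c * N * (D + J) - params.k_t * N * ligands - params.gamma * N
    dJ = prod_J - params.k_c * J * N - params.k_t * J * receptors - params.gamma * J
    dD = prod_D - params.k_c * D * N - params.k_t * D * receptors - params.gamma * D
    dI = params.k_t * N * ligands - params.gamma_I * I
    return np.concatenate([dN, dJ, dD, dI])


@dataclass
class SteadyStateResult:
    """Common steady state of the cell array with convergence diagnostics."""

    state: CellArrayState
    converged: bool
    repeat_spread: float      # max relative per-cell spread across repeats
    residual: float           # max |dX/dt| at the returned state
    n_repeats: int
    seeds: list

    @property
    def nicd(self) -> np.ndarray:
        return self.state.I


def integrate_to_steady_state(
    strain: np.ndarray,
    params: NotchParameters,
    t_end: float = 250.0,
    n_repeats: int = 25,
    seed: int = 0,
    rtol: float = 1e-8,
    spread_tol: float = 1e-3,
) -> SteadyStateResult:
    """Integrate the Notch ODEs to steady state from random initial counts.

    ``n_repeats`` independent initializations (uniform 0-6000 molecules per
    protein per cell) are each integrated over ``t_end`` hours with the
    strains held fixed.  The endpoint states are compared; disagreement
    beyond ``spread_tol`` (relative) raises a multistability warning.
    """
    strain = np.asarray(strain, dtype=float)
    master = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % 2**31) for s in master.spawn(n_repeats)]
    endpoints = []
    for s in child_seeds:
        init = CellArrayState.random(strain, np.random.default_rng(s))
        sol = solve_ivp(
            lambda t, y: rhs(CellArrayState.unpack(y, strain), params),
            (0.0, t_end),
            init.pack(),
            method="LSODA",
            rtol=rtol,
            atol=1e-8,
        )
        if not sol.success:
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        endpoints.append(sol.y[:, -1])
    endpoints = np.array(endpoints)
    mean = endpoints.mean(axis=0)
    scale = np.maximum(np.abs(mean), 1.0)
    spread = float(np.max(np.abs(endpoints - mean) / scale)) if n_repeats > 1 else 0.0
    converged = spread <= spread_tol
    if not converged:
        warnings.warn(
            f"steady-state repeats disagree (relative spread {spread:.2e}); "
            "possible multistability",
            MultistabilityWarning,
        )
    final = CellArrayState.unpack(mean, strain)
    residual = float(np.max(np.abs(rhs(final, params))))
    return SteadyStateResult(
        state=final,
        converged=converged,
        repeat_spread=spread,
        residual=residual,
        n_repeats=n_repeats,
        seeds=child_seeds,
    )


def normalized_nicd(result: SteadyStateResult, reference: SteadyStateResult) -> np.ndarray:
    """Per-cell NICD relative to the normotensive reference steady state."""
    if result.state.n_cells != reference.state.n_cells:
        raise ValueError("result and reference have different cell counts")
    ref = reference.nicd
    if np.any(ref <= 0):
        raise ValueError("reference NICD must be positive in every cell")
    return result.nicd / ref


def phenotype_score(normalized: np.ndarray) -> np.ndarray:
    """Continuous phenotype score: log of the NICD ratio to the reference.

    0 is the homeostatic contractile reference; negative scores indicate a
    progressively synthetic shift, positive scores a contractile shift.
    """
    normalized = np.asarray(normalized, dtype=float)
    if np.any(normalized <= 0):
        raise ValueError("NICD ratios must be positive")
    return np.log(normalized)


def phenotype_label(score: float, tol: float = 1e-3) -> str:
    """Categorical label for reporting, derived from the score's sign."""
    if score < -tol:
        return "synthetic-shifted"
    if score > tol:
        return "contractile-shifted"
    return "homeostatic"
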