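"""Fiber-reinforced, slightly compressible hyperelastic arterial material.

The arterial wall is modeled as a Neo-Hookean ground matrix (volume fraction
``1 - phi_f``) reinforced by ``n_dirs`` fiber directions lying in the
circumferential-axial plane.  The fiber volume fractions follow a periodic
(von Mises-like) version of the normal distribution centered on the main
fiber angle ``alpha`` with dispersity ``d``.  Each fiber direction stores
exponential strain energy and bears stress only in tension.

All deformations handled here are diagonal in cylindrical coordinates
``(r, theta, z)``: the total elastic deformation ``F_e`` and the residual
pre-stretch ``F_a`` are pure stretches.  Fiber directions are pushed through
``F_a`` (and renormalized) before the elastic stretch is measured, so the
fiber angle seen by ``F_e`` is ``psi = atan2(la_z sin w, la_th cos w)``.

For a single, non-symmetric fiber family the Cauchy stress has a
theta-z shear component; it is reacted by the circumferential symmetry
constraints of the cylindrical boundary value problem and never enters the
radial equilibrium equation, so only the diagonal components are returned.

Units: stresses and energy densities in kPa, angles in radians.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MaterialParameters",
    "FiberSet",
    "DeformationState",
    "bulk_modulus",
    "build_fiber_set",
    "fiber_elastic_stretch",
    "strain_energy",
    "cauchy_stress",
]

# cap on the exponent of the fiber energy to keep far-off optimizer trials
# finite; never active for physiological stretches
_EXP_CAP = 500.0


def bulk_modulus(mu: float, nu: float) -> float:
    """Bulk modulus of the matrix from shear modulus and Poisson's ratio.

    kappa = 2 mu (1 + nu) / (3 (1 - 2 nu)), in kPa.
    """
    if mu <= 0:
        raise ValueError(f"shear modulus must be positive, got {mu}")
    if not 0 < nu < 0.5:
        raise ValueError(
            f"Poisson's ratio must lie in (0, 0.5), got {nu}; "
            "nu = 0.5 is the incompressible limit"
        )
    return 2.0 * mu * (1.0 + nu) / (3.0 * (1.0 - 2.0 * nu))


@dataclass
class MaterialParameters:
    """Constitutive constants of the arterial wall material.

    Parameters
    ----------
    mu : float
        Shear modulus of the Neo-Hookean matrix (kPa).
    nu : float
        Poisson's ratio; slightly below 0.5 for near-incompressibility.
    k1, k2 : float
        Fiber stiffness (kPa) and dimensionless fiber exponent.
    alpha : float
        Main fiber angle relative to the circumferential direction (radians).
    d : float
        Dispersity of the fiber-angle distribution.
    phi_f : float
        Total fiber volume fraction.
    n_dirs : int
        Number of discrete fiber directions.
    kappa : float
        Bulk modulus (kPa); derived from ``mu`` and ``nu`` if not given.
    """

    mu: float = 95.4
    nu: float = 0.498
    k1: float = 2.31
    k2: float = 7.57
    alpha: float = np.deg2rad(31.2)
    d: float = 0.059
    phi_f: float = 0.41
    n_dirs: int = 60
    kappa: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.kappa is None:
            self.kappa = bulk_modulus(self.mu, self.nu)
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("fiber parameters k1, k2 must be positive")
        if not 0 < self.phi_f < 1:
            raise ValueError("fiber volume fraction must lie in (0, 1)")
        if self.n_dirs < 1:
            raise ValueError("need at least one fiber direction")


@dataclass
class FiberSet:
    """Discrete fiber directions with their volume fractions.

    ``angles`` span one period of the distribution in the circumferential-
    axial plane; ``fractions`` sum to the total fiber volume fraction.
    """

    angles: np.ndarray
    fractions: np.ndarray
    scale: float

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if np.any(self.fractions < 0):
            raise ValueError("fiber fractions must be non-negative")


def build_fiber_set(params: MaterialParameters) -> FiberSet:
    """Discretize the periodic fiber-angle distribution.

    ``n_dirs`` angles are equally spaced over [-pi/2, pi/2) — one full
    period of the cos(2 w) symmetry — and weighted by
    ``B exp[(cos(2 (w - alpha)) + 1) / d]`` with B chosen so the weights
    sum to ``phi_f``.
    """
    if params.d <= 0:
        raise ValueError(f"dispersity must be positive, got {params.d}")
    n = params.n_dirs
    angles = -np.pi / 2 + np.arange(n) * (np.pi / n)
    weights = np.exp((np.cos(2.0 * (angles - params.alpha)) + 1.0) / params.d)
    scale = params.phi_f / weights.sum()
    return FiberSet(angles=angles, fractions=scale * weights, scale=scale)


@dataclass
class DeformationState:
    """Diagonal pre-stretch and elastic deformation at a material point.

    ``lambda_a`` holds the components of the incompatible pre-stretch
    ``F_a = diag(la_r, la_th, la_z)``; ``lambda_e`` holds the elastic
    deformation ``F_e = diag(le_r, le_th, le_z)`` measured from the
    incompatible stress-free configuration.
    """

    lambda_a: np.ndarray
    lambda_e: np.ndarray

    def __post_init__(self) -> None:
        self.lambda_a = np.asarray(self.lambda_a, dtype=float)
        self.lambda_e = np.asarray(self.lambda_e, dtype=float)
        if np.any(self.lambda_a <= 0) or np.any(self.lambda_e <= 0):
            raise ValueError("stretch components must be positive")

    @classmethod
    def identity(cls) -> "DeformationState":
        return cls(np.ones(3), np.ones(3))

    @property
    def J_e(self) -> float:
        """Elastic volume ratio det(F_e)."""
        return float(np.prod(self.lambda_e))


# ----------------------------------------------------------------------
# vectorized kernels: every argument broadcasts; fiber axis appended last
# ----------------------------------------------------------------------

def _pushed_angle(omega, la_th, la_z):
    """Fiber angle after pushing the reference direction through F_a."""
    la_th = np.asarray(la_th, dtype=float)[..., None]
    la_z = np.asarray(la_z, dtype=float)[..., None]
    return np.arctan2(la_z * np.sin(omega), la_th * np.cos(omega))


def _fiber_stretch_sq(le_th, le_z, psi):
    """Squared elastic fiber stretch C_e : (e* x e*) for in-plane fibers."""
    le_th = np.asarray(le_th, dtype=float)[..., None]
    le_z = np.asarray(le_z, dtype=float)[..., None]
    return (le_th * np.cos(psi)) ** 2 + (le_z * np.sin(psi)) ** 2


def _matrix_energy(le_r, le_th, le_z, params):
    J = le_r * le_th * le_z
    lnJ = np.log(J)
    I1 = le_r**2 + le_th**2 + le_z**2
    return (1.0 - params.phi_f) * (
        0.5 * params.kappa * lnJ**2 + 0.5 * params.mu * (I1 - 3.0 - 2.0 * lnJ)
    )


def _fiber_energy_density(x, params):
    """Per-direction fiber energy as a function of x = stretch^2 (tension only)."""
    e = np.exp(np.minimum(params.k2 * (x - 1.0), _EXP_CAP))
    psi = params.k1 / (2.0 * params.k2) * (e - params.k2 * (x - 1.0) - 1.0)
    return np.where(x > 1.0, psi, 0.0)


def _fiber_energy_dx(x, params):
    """d(per-direction fiber energy)/dx, zero in compression."""
    e = np.exp(np.minimum(params.k2 * (x - 1.0), _EXP_CAP))
    return np.where(x > 1.0, 0.5 * params.k1 * (e - 1.0), 0.0)


def energy_density(le_r, le_th, le_z, la_r, la_th, la_z, params, fibers):
    """Strain energy density (kPa) at points with diagonal F_e and F_a.

    All stretch arguments broadcast against each other.
    """
    psi_ang = _pushed_angle(fibers.angles, la_th, la_z)
    x = _fiber_stretch_sq(le_th, le_z, psi_ang)
    wf = np.sum(fibers.fractions * _fiber_energy_density(x, params), axis=-1)
    return _matrix_energy(
        np.asarray(le_r, dtype=float),
        np.asarray(le_th, dtype=float),
        np.asarray(le_z, dtype=float),
        params,
    ) + wf


def stress_diag(le_r, le_th, le_z, la_r, la_th, la_z, params, fibers):
    """Diagonal Cauchy stress components (sigma_rr, sigma_tt, sigma_zz) in kPa.

    Matrix part: (1-phi_f)/J_e [kappa ln(J_e) I + mu (B_e - I)].
    Each taut fiber direction adds (2/J_e) phi_f^i dPsi/dx times the
    deformed dyad components along theta and z; fibers never load r.
    """
    le_r = np.asarray(le_r, dtype=float)
    le_th = np.asarray(le_th, dtype=float)
    le_z = np.asarray(le_z, dtype=float)
    J = le_r * le_th * le_z
    lnJ = np.log(J)
    pref = (1.0 - params.phi_f) / J
    s_rr = pref * (params.kappa * lnJ + params.mu * (le_r**2 - 1.0))
    s_tt = pref * (params.kappa * lnJ + params.mu * (le_th**2 - 1.0))
    s_zz = pref * (params.kappa * lnJ + params.mu * (le_z**2 - 1.0))

    psi_ang = _pushed_angle(fibers.angles, la_th, la_z)
    x = _fiber_stretch_sq(le_th, le_z, psi_ang)
    dpsi = _fiber_energy_dx(x, params) * fibers.fractions
    c2 = np.cos(psi_ang) ** 2
    s2 = np.sin(psi_ang) ** 2
    s_tt = s_tt + (2.0 / J) * le_th**2 * np.sum(dpsi * c2, axis=-1)
    s_zz = s_zz + (2.0 / J) * le_z**2 * np.sum(dpsi * s2, axis=-1)
    return s_rr, s_tt, s_zz


# ----------------------------------------------------------------------
# scalar, state-based surface
# ----------------------------------------------------------------------

def fiber_elastic_stretch(state: DeformationState, omega: float) -> float:
    """Elastic stretch of the fiber direction at reference angle ``omega``.

    The reference direction is pushed through the pre-stretch ``F_a`` and
    renormalized before the elastic right Cauchy-Green tensor is applied.
    """
    psi = _pushed_angle(np.atleast_1d(omega), state.lambda_a[1], state.lambda_a[2])
    x = _fiber_stretch_sq(state.lambda_e[1], state.lambda_e[2], psi)
    return float(np.sqrt(np.squeeze(x)))


def strain_energy(
    state: DeformationState, params: MaterialParameters, fibers: FiberSet
) -> float:
    """Strain energy density (kPa) of the state: matrix plus taut fibers."""
    return float(
        energy_density(
            state.lambda_e[0],
            state.lambda_e[1],
            state.lambda_e[2],
            state.lambda_a[0],
            state.lambda_a[1],
            state.lambda_a[2],
            params,
            fibers,
        )
    )


def cauchy_stress(
    state: DeformationState, params: MaterialParameters, fibers: FiberSet
) -> np.ndarray:
    """Diagonal Cauchy stress (sigma_rr, sigma_tt, sigma_zz) in kPa."""
    s = stress_diag(
        state.lambda_e[0],
        state.lambda_e[1],
        state.lambda_e[2],
        state.lambda_a[0],
        state.lambda_a[1],
        state.lambda_a[2],
        params,
        fibers,
    )
    return np.array([float(c) for c in s])
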