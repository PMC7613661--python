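"""Residually stressed thick-walled artery under luminal pressure.

The artery is a circular cylinder held at fixed axial length.  Geometry,
loads and boundary conditions are axisymmetric, so the problem reduces
exactly (up to radial discretization) to a one-dimensional two-point
boundary value problem for the deformed radius map r(R):

    d(sigma_rr)/dr + (sigma_rr - sigma_tt)/r = 0,
    sigma_rr(r_i) = -P,   sigma_rr(r_o) = 0.

Residual stress enters through the incompatible pre-stretch
``F_a = diag(1, 1/lambda_circ(R), 1/lambda_axial)``: the elastic stretches
driving the constitutive law are ``lambda_e = lambda_total / lambda_a``.
The circumferential pre-stretch profile follows from the classical
opening-angle construction (opened stress-free sector, constant thickness),
closed by the convention that the mid-wall circumference is unstretched.

Discretization: a second-order box (midpoint collocation) scheme on a
uniform reference grid with unknowns (r_j, sigma_rr_j) at each station,
solved with a damped Newton method (scipy.optimize.root).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .constitutive import FiberSet, MaterialParameters, energy_density, stress_diag
from .units import mmhg_to_kpa

__all__ = [
    "ArteryGeometry",
    "ResidualStretchField",
    "WallSolution",
    "StretchProfiles",
    "prestretch_profile",
    "solve_equilibrium",
    "calibrate_opening_angle",
    "simulate_axial_release",
    "simulate_radial_cut",
    "stretch_profiles",
    "EquilibriumError",
]


class EquilibriumError(RuntimeError):
    """Raised when the wall equilibrium solver fails to converge."""


@dataclass
class ArteryGeometry:
    """Stress-free geometry of the arterial segment.

    Lengths in mm.  ``n_radial`` stations are placed uniformly through the
    wall; the default 33 puts stations at the boundaries of the 32 cells of
    the signaling model.
    """

    r_i0: float = 1.5
    T0: float = 0.32
    L0: float = 0.03
    n_radial: int = 33

    def __post_init__(self) -> None:
        if self.r_i0 <= 0 or self.T0 <= 0:
            raise ValueError("geometry dimensions must be positive")
        if self.n_radial < 8:
            raise ValueError("need at least 8 radial stations")

    @property
    def r_o0(self) -> float:
        return self.r_i0 + self.T0

    def stations(self, n: int | None = None) -> np.ndarray:
        return np.linspace(self.r_i0, self.r_o0, n or self.n_radial)


@dataclass
class ResidualStretchField:
    """Axial and circumferential pre-stretch of the closed, unloaded artery.

    ``Phi`` is the opening angle in degrees; ``lambda_axial`` the axial
    pre-stretch.  ``retain_frac_axial`` / ``retain_frac_circ`` scale the
    deviation of the pre-stretches from unity, emulating partial loss of
    residual stress (1.0 = fully retained, 0.0 = lost).
    """

    geom: ArteryGeometry
    Phi: float
    lambda_axial: float = 1.39
    retain_frac_axial: float = 1.0
    retain_frac_circ: float = 1.0
    k: float = field(init=False)

    def __post_init__(self) -> None:
        if not 0 <= self.Phi < 360:
            raise ValueError(f"opening angle must lie in [0, 360), got {self.Phi}")
        self.k = 2 * math.pi / (2 * math.pi - math.radians(self.Phi))

    def lambda_circ(self, R) -> np.ndarray:
        """Circumferential pre-stretch at stress-free radius R (mm).

        Circular-segment, constant-thickness construction with the mid-wall
        circumference unstretched; retention scaling applied to the
        deviation from unity.
        """
        R = np.asarray(R, dtype=float)
        Rm = self.geom.r_i0 + self.geom.T0 / 2.0
        lam = self.k * R / (self.k * Rm + R - Rm)
        return 1.0 + self.retain_frac_circ * (lam - 1.0)

    @property
    def lambda_axial_eff(self) -> float:
        return 1.0 + self.retain_frac_axial * (self.lambda_axial - 1.0)

    @property
    def lambda_circ_profile(self) -> np.ndarray:
        """Pre-stretch values at the geometry's radial stations."""
        return self.lambda_circ(self.geom.stations())

    def lambda_a(self, R):
        """Components of F_a = diag(la_r, la_th, la_z) at radius R.

        The circumferential and axial components are the inverses of the
        pre-stretches; the radial component closes det(F_a) = 1, so the
        incompatible pre-stretch is volume-preserving.
        """
        lc = self.lambda_circ(R)
        la_th = 1.0 / lc
        la_z = np.full_like(lc, 1.0 / self.lambda_axial_eff)
        return 1.0 / (la_th * la_z), la_th, la_z


def prestretch_profile(
    geom: ArteryGeometry,
    Phi: float,
    lambda_axial: float = 1.39,
    retain_frac_axial: float = 1.0,
    retain_frac_circ: float = 1.0,
) -> ResidualStretchField:
    """Build the residual pre-stretch field for an opening angle in degrees."""
    return ResidualStretchField(
        geom=geom,
        Phi=Phi,
        lambda_axial=lambda_axial,
        retain_frac_axial=retain_frac_axial,
        retain_frac_circ=retain_frac_circ,
    )


@dataclass
class WallSolution:
    """Converged radial profiles of the pressurized (or released) wall."""

    pressure_mmhg: float
    R: np.ndarray          # reference radii (mm)
    r: np.ndarray          # deformed radii (mm)
    lambda_e_r: np.ndarray
    lambda_e_theta: np.ndarray
    lambda_e_z: np.ndarray
    sigma_rr: np.ndarray   # kPa
    sigma_tt: np.ndarray
    sigma_zz: np.ndarray
    residual_norm: float   # max interior equilibrium residual (kPa/mm)
    sector_factor: float = 1.0

    @property
    def J_e(self) -> np.ndarray:
        return self.lambda_e_r * self.lambda_e_theta * self.lambda_e_z


def _solve_radial_stretch(target_srr, le_th, le_z, params, x0=None):
    """Invert sigma_rr(lambda_e_r) = target for lambda_e_r (vectorized Newton).

    Fibers lie in the theta-z plane, so sigma_rr only involves the matrix
    response and is strictly increasing in lambda_e_r.
    """
    target = np.asarray(target_srr, dtype=float)
    le_th = np.asarray(le_th, dtype=float)
    le_z = np.asarray(le_z, dtype=float)
    c = le_th * le_z
    A = 1.0 - params.phi_f
    lr = np.full(np.broadcast(target, c).shape, 1.0) if x0 is None else np.array(x0, dtype=float)
    for _ in range(60):
        J = lr * c
        f = A * (params.kappa * np.log(J) + params.mu * (lr**2 - 1.0)) / J - target
        df = A * (
            (params.kappa / lr + 2.0 * params.mu * lr) / J
            - (params.kappa * np.log(J) + params.mu * (lr**2 - 1.0)) / (J * lr)
        )
        step = f / df
        step = np.clip(step, -0.2, 0.2)
        lr = np.maximum(lr - step, 1e-3)
        if np.max(np.abs(f)) < 1e-12 * max(params.kappa, 1.0):
            break
    return lr


def _assemble(geom: ArteryGeometry, resid: ResidualStretchField, sector_factor: float):
    """Precompute station/midpoint grids and pre-stretch fields."""
    R = geom.stations()
    dR = R[1] - R[0]
    Rm = 0.5 * (R[:-1] + R[1:])
    la_r_m, la_th_m, la_z_m = resid.lambda_a(Rm)
    lc_m = resid.lambda_circ(Rm)
    lc_s = resid.lambda_circ(R)
    le_z = resid.lambda_axial_eff  # lambda_tot_z = 1 at fixed length
    return R, dR, Rm, (la_r_m, la_th_m, la_z_m), lc_m, lc_s, le_z


def solve_equilibrium(
    geom: ArteryGeometry,
    resid: ResidualStretchField,
    params: MaterialParameters,
    fibers: FiberSet,
    pressure: float,
    sector_factor: float = 1.0,
    initial: np.ndarray | None = None,
) -> WallSolution:
    """Solve radial equilibrium of the wall at a luminal pressure (mmHg).

    ``sector_factor`` generalizes the closed tube (1.0) to an open sector
    subtending an angle 2 pi / sector_factor, used by the radial-cut
    release simulation.
    """
    if pressure < 0:
        raise ValueError("pressure must be non-negative")
    P = mmhg_to_kpa(pressure)
    R, dR, Rm, (la_r_m, la_th_m, la_z_m), lc_m, lc_s, le_z = _assemble(
        geom, resid, sector_factor
    )
    n = len(R)
    ko = sector_factor

    def residual(u):
        r = u[:n]
        s = u[n:]
        r_m = 0.5 * (r[:-1] + r[1:])
        drdR = (r[1:] - r[:-1]) / dR
        le_th_m = r_m * lc_m / (ko * Rm)
        le_r_m = np.maximum(drdR / la_r_m, 1e-6)
        srr_m, stt_m, _ = stress_diag(
            le_r_m, le_th_m, le_z, la_r_m, la_th_m, la_z_m, params, fibers
        )
        res = np.empty(2 * n)
        # constitutive consistency at midpoints
        res[: n - 1] = srr_m - 0.5 * (s[:-1] + s[1:])
        # radial equilibrium at midpoints (reference-coordinate form)
        res[n - 1 : 2 * n - 2] = (s[1:] - s[:-1]) / dR - (stt_m - srr_m) / r_m * drdR
        res[2 * n - 2] = s[0] + P
        res[2 * n - 1] = s[-1]
        return res

    if initial is None:
        r0 = R / lc_s * ko if pressure == 0 else R.copy()
        s0 = np.linspace(-P, 0.0, n)
        u0 = np.concatenate([r0, s0])
    else:
        u0 = initial

    sol = optimize.root(residual, u0, method="hybr", options={"xtol": 1e-12})
    if not sol.success or np.max(np.abs(residual(sol.x))) > 1e-6 * max(P, 1.0):
        # pressure continuation fallback
        u = np.concatenate([R / lc_s * ko, np.zeros(n)])
        for frac in np.linspace(0.2, 1.0, 5):
            Pf = mmhg_to_kpa(pressure * frac)

            def residual_f(u, Pf=Pf):
                r2 = residual(u)
                r2[2 * n - 2] = u[n] + Pf
                return r2

            sol = optimize.root(residual_f, u, method="hybr", options={"xtol": 1e-12})
            u = sol.x
        if not (sol.success and np.max(np.abs(residual(sol.x))) < 1e-6 * max(P, 1.0)):
            raise EquilibriumError(
                f"equilibrium solve failed at P={pressure} mmHg; "
                f"max residual {np.max(np.abs(residual(sol.x))):.3e} kPa"
            )

    r = sol.x[:n]
    s = sol.x[n:]
    la_r_s, la_th_s, la_z_s = resid.lambda_a(R)
    le_th = r * lc_s / (ko * R)
    le_r = _solve_radial_stretch(s, le_th, le_z, params)
    srr, stt, szz = stress_diag(
        le_r, le_th, le_z, la_r_s, la_th_s, la_z_s, params, fibers
    )
    # interior equilibrium residual measured on the station profiles
    interior = np.abs(
        (s[2:] - s[:-2]) / (r[2:] - r[:-2]) + (s[1:-1] - stt[1:-1]) / r[1:-1]
    )
    return WallSolution(
        pressure_mmhg=pressure,
        R=R,
        r=r,
        lambda_e_r=le_r,
        lambda_e_theta=le_th,
        lambda_e_z=np.full(n, le_z),
        sigma_rr=s,
        sigma_tt=stt,
        sigma_zz=szz,
        residual_norm=float(np.max(interior)) if len(interior) else 0.0,
        sector_factor=ko,
    )


def calibrate_opening_angle(
    geom: ArteryGeometry,
    params: MaterialParameters,
    fibers: FiberSet,
    lambda_axial: float = 1.39,
    pressure: float = 100.0,
    bounds: tuple[float, float] = (1.0, 179.0),
    xatol: float = 0.05,
) -> float:
    """Opening angle (degrees) that homogenizes the circumferential stretch.

    Minimizes the sum of absolute deviations of the station-wise elastic
    circumferential stretch from its wall mean, for the artery loaded at
    the given pressure (mmHg, default mean physiological pressure).
    """

    def objective(Phi: float) -> float:
        resid = prestretch_profile(geom, Phi, lambda_axial=lambda_axial)
        w = solve_equilibrium(geom, resid, params, fibers, pressure)
        lam = w.lambda_e_theta
        return float(np.sum(np.abs(lam - lam.mean())))

    res = optimize.minimize_scalar(
        objective, bounds=bounds, method="bounded", options={"xatol": xatol}
    )
    if not res.success:
        raise EquilibriumError(f"opening-angle calibration failed near Phi={res.x}")
    return float(res.x)


def simulate_axial_release(
    geom: ArteryGeometry,
    resid: ResidualStretchField,
    loaded_length: float | None = None,
) -> float:
    """Length (mm) of the segment after releasing the axial residual stress.

    The pre-stretched (closed, unloaded) segment of length L shortens to
    L / lambda_axial upon excision.
    """
    L = geom.L0 if loaded_length is None else loaded_length
    return L / resid.lambda_axial_eff


def simulate_radial_cut(
    geom: ArteryGeometry,
    resid: ResidualStretchField,
    params: MaterialParameters,
    fibers: FiberSet,
    bounds: tuple[float, float] | None = None,
    xatol: float = 0.05,
) -> float:
    """Opened angle (degrees) after a radial cut releases the hoop stress.

    The cut, unloaded sector relaxes to the configuration of minimum total
    strain energy over the family of equilibrium open-sector states
    parameterized by the opened angle; at the minimum the cut faces carry
    no net circumferential force or bending moment.
    """
    R, dR, Rm, (la_r_m, la_th_m, la_z_m), lc_m, _, _ = _assemble(geom, resid, 1.0)
    J_a_m = la_r_m * la_th_m * la_z_m

    def energy(Phi_open: float) -> float:
        ko = 2 * math.pi / (2 * math.pi - math.radians(Phi_open))
        w = solve_equilibrium(geom, resid, params, fibers, 0.0, sector_factor=ko)
        r_m = 0.5 * (w.r[:-1] + w.r[1:])
        le_r_m = (w.r[1:] - w.r[:-1]) / dR
        le_th_m = r_m * lc_m / (ko * Rm)
        psi = energy_density(
            le_r_m, le_th_m, w.lambda_e_z[0], la_r_m, la_th_m, la_z_m, params, fibers
        )
        return float(np.sum(psi * J_a_m * Rm) * dR)

    if bounds is None:
        bounds = (-30.0, min(resid.Phi + 90.0, 250.0)) if resid.Phi > 0 else (-30.0, 120.0)
    res = optimize.minimize_scalar(
        energy, bounds=bounds, method="bounded", options={"xatol": xatol}
    )
    if not res.success:
        raise EquilibriumError("radial-cut release failed to converge")
    return float(res.x)


@dataclass
class StretchProfiles:
    """Station-wise circumferential elastic stretch under the three measures."""

    R: np.ndarray
    systolic: np.ndarray
    mean: np.ndarray
    dynamic: np.ndarray
    solutions: dict

    def profile(self, hypothesis: str) -> np.ndarray:
        try:
            return getattr(self, hypothesis)
        except AttributeError:
            raise ValueError(
                f"unknown stretch hypothesis {hypothesis!r}; "
                "expected 'systolic', 'mean' or 'dynamic'"
            ) from None


def stretch_profiles(
    geom: ArteryGeometry,
    resid: ResidualStretchField,
    params: MaterialParameters,
    fibers: FiberSet,
    p_sys: float,
    p_dia: float,
) -> StretchProfiles:
    """Systolic, mean and dynamic circumferential stretch profiles.

    Systolic and mean stretches are the elastic stretches at systolic and
    mean pressure ((p_sys + p_dia)/2); the dynamic stretch is the ratio of
    the systolic to the diastolic elastic stretch, station by station.
    Pressures in mmHg.
    """
    if not p_sys >= p_dia >= 0:
        raise ValueError("require p_sys >= p_dia >= 0")
    p_mean = 0.5 * (p_sys + p_dia)
    w_sys = solve_equilibrium(geom, resid, params, fibers, p_sys)
    w_mean = solve_equilibrium(geom, resid, params, fibers, p_mean)
    w_dia = solve_equilibrium(geom, resid, params, fibers, p_dia)
    return StretchProfiles(
        R=w_sys.R,
        systolic=w_sys.lambda_e_theta,
        mean=w_mean.lambda_e_theta,
        dynamic=w_sys.lambda_e_theta / w_dia.lambda_e_theta,
        solutions={"systolic": w_sys, "mean": w_mean, "diastolic": w_dia},
    )
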