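"""Synthetic tensile-test fixtures and constitutive parameter fitting.

The experimental dataset behind the material constants (uniaxial and
biaxial tension of porcine coronary artery strips) is not redistributable,
so this module generates synthetic stress-strain tables from the
constitutive model itself and fits the five free material parameters
(mu, k1, k2, alpha, d) to them by Levenberg-Marquardt nonlinear least
squares.  Noiseless self-fits double as parameter-recovery tests.

A tensile specimen is a thin sheet cut in the circumferential-axial plane,
free of residual stress, with a traction-free thickness direction: for
prescribed in-plane stretches (lambda_theta, lambda_z) the radial stretch
solves sigma_rr = 0 and the reported quantities are the in-plane Cauchy
stresses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .constitutive import FiberSet, MaterialParameters, build_fiber_set, stress_diag

__all__ = [
    "TensileProtocol",
    "FitResult",
    "default_protocols",
    "simulate_tensile",
    "fit_parameters",
    "r_squared",
    "write_fixture",
    "read_fixture",
]


@dataclass
class TensileProtocol:
    """One tensile test: loading mode, stretch grid and noise level."""

    mode: str  # "uniaxial-theta", "uniaxial-z" or "biaxial"
    n_points: int = 20
    lam_max: float = 1.4
    ratio: float = 1.0  # biaxial lambda_z : lambda_theta pacing
    noise_sd: float = 0.0  # kPa
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("uniaxial-theta", "uniaxial-z", "biaxial"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.lam_max <= 1.0:
            raise ValueError("stretch grid must extend beyond 1")
        if self.ratio <= 0:
            raise ValueError("biaxial ratio must be positive")


def default_protocols(noise_sd: float = 0.0, seed: int = 0) -> list[TensileProtocol]:
    """Two uniaxial and five biaxial protocols covering both axes.

    Biaxial strain paths pace lambda_z against lambda_theta at ratios
    1:1, 0.75:1, 1:0.75, 0.5:1 and 1:0.5 (excess stretch on one axis),
    spanning the deformation modes an artery sees across the
    normotensive-to-hypertensive pressure range.
    """
    protos = [
        TensileProtocol("uniaxial-theta", lam_max=1.5, noise_sd=noise_sd, seed=seed),
        TensileProtocol("uniaxial-z", lam_max=1.5, noise_sd=noise_sd, seed=seed + 1),
    ]
    for i, ratio in enumerate((1.0, 0.75, 1.0 / 0.75, 0.5, 2.0)):
        protos.append(
            TensileProtocol("biaxial", ratio=ratio, noise_sd=noise_sd, seed=seed + 2 + i)
        )
    return protos


def _solve_thickness_stretch(le_th, le_z, params):
    """Radial stretch of a traction-free sheet: sigma_rr = 0 (vectorized)."""
    le_th = np.asarray(le_th, dtype=float)
    le_z = np.asarray(le_z, dtype=float)
    c = le_th * le_z
    lr = 1.0 / np.sqrt(c)  # incompressible guess
    for _ in range(80):
        J = lr * c
        g = params.kappa * np.log(J) + params.mu * (lr**2 - 1.0)
        dg = params.kappa / lr + 2.0 * params.mu * lr
        step = np.clip(g / dg, -0.2, 0.2)
        lr = np.maximum(lr - step, 1e-3)
        if np.max(np.abs(g)) < 1e-11 * params.kappa:
            break
    return lr


def _planar_stresses(le_th, le_z, params, fibers):
    """In-plane Cauchy stresses of the traction-free sheet (kPa)."""
    lr = _solve_thickness_stretch(le_th, le_z, params)
    ones = np.ones_like(np.asarray(le_th, dtype=float))
    _, s_tt, s_zz = stress_diag(lr, le_th, le_z, ones, ones, ones, params, fibers)
    return s_tt, s_zz


def _protocol_stretches(protocol: TensileProtocol, params, fibers):
    """In-plane stretch path (lambda_theta, lambda_z) of one protocol.

    Uniaxial modes leave the transverse in-plane axis traction-free: its
    stretch solves the corresponding zero-stress condition.
    """
    lam = np.linspace(1.0, protocol.lam_max, protocol.n_points)
    if protocol.mode == "biaxial":
        # pace the slower axis at `ratio` relative to the faster one; the
        # faster axis runs the full grid so neither exceeds lam_max
        pace_th = min(1.0, 1.0 / protocol.ratio)
        pace_z = min(1.0, protocol.ratio)
        le_th = 1.0 + (lam - 1.0) * pace_th
        le_z = 1.0 + (lam - 1.0) * pace_z
        return le_th, le_z
    # uniaxial: outer Newton on the free transverse stretch
    free = np.ones_like(lam)
    for _ in range(80):
        if protocol.mode == "uniaxial-theta":
            s_tt, s_zz = _planar_stresses(lam, free, params, fibers)
            g = s_zz
        else:
            s_tt, s_zz = _planar_stresses(free, lam, params, fibers)
            g = s_tt
        h = 1e-6
        if protocol.mode == "uniaxial-theta":
            gp = (_planar_stresses(lam, free + h, params, fibers)[1] - g) / h
        else:
            gp = (_planar_stresses(free + h, lam, params, fibers)[0] - g) / h
        step = np.clip(g / np.where(np.abs(gp) > 1e-12, gp, 1e-12), -0.1, 0.1)
        free = np.clip(free - step, 0.3, 3.0)
        if np.max(np.abs(g)) < 1e-9 * max(params.mu, 1.0):
            break
    if protocol.mode == "uniaxial-theta":
        return lam, free
    return free, lam


def simulate_tensile(
    params: MaterialParameters, fibers: FiberSet, protocol: TensileProtocol
) -> pd.DataFrame:
    """Stress-strain table of one tensile test (stresses in kPa).

    Gaussian noise of sd ``protocol.noise_sd`` is added to the stresses
    when positive; the table is bit-reproducible for a fixed seed.
    """
    le_th, le_z = _protocol_stretches(protocol, params, fibers)
    s_tt, s_zz = _planar_stresses(le_th, le_z, params, fibers)
    if protocol.noise_sd > 0:
        rng = np.random.default_rng(protocol.seed)
        s_tt = s_tt + rng.normal(0.0, protocol.noise_sd, s_tt.shape)
        s_zz = s_zz + rng.normal(0.0, protocol.noise_sd, s_zz.shape)
    return pd.DataFrame(
        {
            "lambda_theta": le_th,
            "lambda_z": le_z,
            "sigma_tt": s_tt,
            "sigma_zz": s_zz,
            "mode": protocol.mode,
        }
    )


def r_squared(observed: np.ndarray, fitted: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    observed = np.asarray(observed, dtype=float).ravel()
    fitted = np.asarray(fitted, dtype=float).ravel()
    ss_res = np.sum((observed - fitted) ** 2)
    ss_tot = np.sum((observed - observed.mean()) ** 2)
    return 1.0 - ss_res / ss_tot


@dataclass
class FitResult:
    """Fitted constitutive parameters with per-test goodness of fit."""

    params: MaterialParameters
    per_test_r2: list
    mean_r2: float
    cost: float
    n_iterations: int


def _candidate(x, template: MaterialParameters) -> MaterialParameters:
    mu, k1, k2, alpha, d = x
    return MaterialParameters(
        mu=abs(mu),
        nu=template.nu,
        k1=abs(k1),
        k2=abs(k2),
        alpha=alpha,
        d=abs(d),
        phi_f=template.phi_f,
        n_dirs=template.n_dirs,
    )


def fit_parameters(
    tables: list[pd.DataFrame],
    initial: MaterialParameters,
    template: MaterialParameters | None = None,
) -> FitResult:
    """Fit (mu, k1, k2, alpha, d) to stress-strain tables by Levenberg-Marquardt.

    The fixed constants (nu, phi_f, n_dirs) are taken from ``template``
    (default: the initial guess).  Residuals are the stacked differences of
    both in-plane Cauchy stresses across all tests; per-test and mean
    coefficients of determination use the definition
    R^2 = 1 - sum((obs - fit)^2) / sum((obs - mean(obs))^2).
    """
    template = template or initial
    le_th = [t["lambda_theta"].to_numpy() for t in tables]
    le_z = [t["lambda_z"].to_numpy() for t in tables]
    obs = [t[["sigma_tt", "sigma_zz"]].to_numpy() for t in tables]
    n_points = sum(o.size for o in obs)
    if n_points < 25:
        raise ValueError("need at least 5 data points per free parameter")

    def predict(p: MaterialParameters):
        fibers = build_fiber_set(p)
        out = []
        for lth, lz in zip(le_th, le_z):
            s_tt, s_zz = _planar_stresses(lth, lz, p, fibers)
            out.append(np.column_stack([s_tt, s_zz]))
        return out

    def residuals(x):
        try:
            p = _candidate(x, template)
            pred = predict(p)
        except (ValueError, FloatingPointError):
            return np.full(n_points, 1e6)
        r = np.concatenate([(pr - ob).ravel() for pr, ob in zip(pred, obs)])
        return np.where(np.isfinite(r), r, 1e6)

    x0 = np.array([initial.mu, initial.k1, initial.k2, initial.alpha, initial.d])
    sol = optimize.least_squares(residuals, x0, method="lm", xtol=1e-12, ftol=1e-12)
    if not sol.success:
        raise RuntimeError(f"parameter fit did not converge: {sol.message}")
    fitted = _candidate(sol.x, template)
    pred = predict(fitted)
    r2 = [r_squared(ob, pr) for ob, pr in zip(obs, pred)]
    return FitResult(
        params=fitted,
        per_test_r2=r2,
        mean_r2=float(np.mean(r2)),
        cost=float(sol.cost),
        n_iterations=int(sol.nfev),
    )


def write_fixture(directory, tables: list[pd.DataFrame], protocols: list[TensileProtocol]) -> None:
    """Write one CSV per test plus a JSON protocol manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, (tab, proto) in enumerate(zip(tables, protocols)):
        name = f"test_{i:02d}.csv"
        tab.to_csv(directory / name, index=False)
        manifest.append({"file": name, **proto.__dict__})
    (directory / "protocols.json").write_text(json.dumps(manifest, indent=2))


def read_fixture(directory) -> tuple[list[pd.DataFrame], list[TensileProtocol]]:
    directory = Path(directory)
    manifest = json.loads((directory / "protocols.json").read_text())
    tables, protocols = [], []
    for entry in manifest:
        tables.append(pd.read_csv(directory / entry.pop("file")))
        protocols.append(TensileProtocol(**entry))
    return tables, protocols
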