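"""In-silico experiment drivers: hypertension grids, residual-stress loss
and Notch/Jagged expression manipulation.

Each scenario is expressed as a grid of conditions around a common
normotensive reference (120/80 mmHg, full residual stress, unscaled
expression).  Results come back as long-format tables with one row per
(condition, cell).

Default pressure grids follow clinical staging conventions: isolated
systolic hypertension raises the systolic pressure only, isolated diastolic
the diastolic only, combined hypertension raises both.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .artery_bvp import ArteryGeometry, prestretch_profile
from .constitutive import FiberSet, MaterialParameters
from .coupling import CouplingSpec, run_coupled
from .notch_abm import NotchParameters, integrate_to_steady_state, normalized_nicd

__all__ = [
    "ScenarioGrid",
    "hypertension_grids",
    "run_grid",
    "compare_manipulations",
    "SEVERE_CH",
]

NORMAL = (120.0, 80.0)
ISH_PRESSURES = [(140.0, 80.0), (160.0, 80.0), (180.0, 80.0)]
IDH_PRESSURES = [(120.0, 90.0), (120.0, 100.0), (120.0, 110.0)]
CH_PRESSURES = [(140.0, 90.0), (160.0, 100.0), (180.0, 110.0)]
SEVERE_CH = (180.0, 110.0)
EXPRESSION_SCALES = [0.75, 0.9, 1.0, 1.1, 1.25]


@dataclass
class ScenarioGrid:
    """A named sweep of loading / residual-stress / expression conditions."""

    name: str
    pressures: list = field(default_factory=lambda: [NORMAL])
    retain_frac_axial: list = field(default_factory=lambda: [1.0])
    retain_frac_circ: list = field(default_factory=lambda: [1.0])
    notch_scale: list = field(default_factory=lambda: [1.0])
    jagged_scale: list = field(default_factory=lambda: [1.0])
    hypothesis: str = "mean"

    def __post_init__(self) -> None:
        if not self.pressures:
            raise ValueError("grid needs at least one pressure pair")
        for ps, pd_ in self.pressures:
            if not ps >= pd_ >= 0:
                raise ValueError(f"invalid pressure pair ({ps}, {pd_})")

    def conditions(self):
        for ps, pdia in self.pressures:
            for ra in self.retain_frac_axial:
                for rc in self.retain_frac_circ:
                    for ns in self.notch_scale:
                        for js in self.jagged_scale:
                            yield dict(
                                p_sys=ps,
                                p_dia=pdia,
                                retain_frac_axial=ra,
                                retain_frac_circ=rc,
                                notch_scale=ns,
                                jagged_scale=js,
                            )


def hypertension_grids(hypothesis: str = "mean") -> dict:
    """The three standard hypertension sweeps under one stretch hypothesis."""
    return {
        "ISH": ScenarioGrid("ISH", pressures=list(ISH_PRESSURES), hypothesis=hypothesis),
        "IDH": ScenarioGrid("IDH", pressures=list(IDH_PRESSURES), hypothesis=hypothesis),
        "CH": ScenarioGrid("CH", pressures=list(CH_PRESSURES), hypothesis=hypothesis),
    }


def run_grid(
    grid: ScenarioGrid,
    geom: ArteryGeometry,
    params: MaterialParameters,
    fibers: FiberSet,
    notch_params: NotchParameters,
    Phi: float,
    lambda_axial: float = 1.39,
    n_repeats: int = 2,
    seed: int = 0,
    t_end: float = 250.0,
) -> pd.DataFrame:
    """Run every condition of a grid against a shared normotensive reference.

    Returns a long-format table with one row per (condition, cell); failed
    conditions are recorded with NaNs and the error message, and the sweep
    continues.
    """
    ref_resid = prestretch_profile(geom, Phi, lambda_axial=lambda_axial)
    reference_run = run_coupled(
        geom,
        ref_resid,
        params,
        fibers,
        notch_params.with_scales(1.0, 1.0),
        CouplingSpec(hypothesis=grid.hypothesis, p_sys=NORMAL[0], p_dia=NORMAL[1]),
        n_repeats=n_repeats,
        seed=seed,
    )
    reference = reference_run.reference
    rows = []
    for cond in grid.conditions():
        label = (
            f"{cond['p_sys']:.0f}/{cond['p_dia']:.0f}"
            f"|ax{cond['retain_frac_axial']:.2f}|circ{cond['retain_frac_circ']:.2f}"
            f"|N{cond['notch_scale']:.2f}|J{cond['jagged_scale']:.2f}"
        )
        try:
            resid = prestretch_profile(
                geom,
                Phi,
                lambda_axial=lambda_axial,
                retain_frac_axial=cond["retain_frac_axial"],
                retain_frac_circ=cond["retain_frac_circ"],
            )
            np_cond = notch_params.with_scales(cond["notch_scale"], cond["jagged_scale"])
            spec = CouplingSpec(
                hypothesis=grid.hypothesis, p_sys=cond["p_sys"], p_dia=cond["p_dia"]
            )
            res = run_coupled(
                geom, resid, params, fibers, np_cond, spec,
                reference=reference, n_repeats=n_repeats, seed=seed, t_end=t_end,
            )
        except Exception as err:  # record and continue the sweep
            rows.append(
                dict(scenario=grid.name, condition=label, cell=np.nan, error=str(err), **cond)
            )
            continue
        frame = res.to_frame()
        frame.insert(0, "scenario", grid.name)
        frame.insert(1, "condition", label)
        for key, val in cond.items():
            frame[key] = val
        frame["error"] = ""
        rows.append(frame)
    frames = [r if isinstance(r, pd.DataFrame) else pd.DataFrame([r]) for r in rows]
    return pd.concat(frames, ignore_index=True)


def compare_manipulations(
    strain: np.ndarray,
    notch_params: NotchParameters,
    reference,
    scales=tuple(EXPRESSION_SCALES),
    n_repeats: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Effect of Notch vs Jagged expression scaling at a fixed strain field.

    For each scale, the steady state is recomputed with the basal Notch
    (resp. Jagged) production rate multiplied by the scale, and the
    per-cell and wall-mean absolute change in normalized NICD relative to
    the unscaled run is reported.
    """
    base = integrate_to_steady_state(
        strain, notch_params.with_scales(1.0, 1.0), n_repeats=n_repeats, seed=seed
    )
    base_norm = normalized_nicd(base, reference)
    rows = []
    for target in ("notch", "jagged"):
        for scale in scales:
            p = (
                notch_params.with_scales(notch_scale=scale, jagged_scale=1.0)
                if target == "notch"
                else notch_params.with_scales(notch_scale=1.0, jagged_scale=scale)
            )
            res = integrate_to_steady_state(strain, p, n_repeats=n_repeats, seed=seed)
            norm = normalized_nicd(res, reference)
            delta = np.abs(norm - base_norm)
            for j in range(len(strain)):
                rows.append(
                    dict(
                        target=target,
                        scale=scale,
                        cell=j + 1,
                        normalized_nicd=norm[j],
                        delta_nicd=delta[j],
                        wall_mean_delta=float(delta.mean()),
                    )
                )
    return pd.DataFrame(rows)
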