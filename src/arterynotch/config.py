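"""Configuration loading: flat YAML/JSON documents to domain objects.

Angles are written in degrees at the I/O boundary and stored in radians
internally; blood pressures are mmHg throughout the configuration.
A missing section falls back to the published defaults.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .artery_bvp import ArteryGeometry, ResidualStretchField, prestretch_profile
from .constitutive import MaterialParameters, build_fiber_set
from .coupling import CouplingSpec
from .notch_abm import NotchParameters

__all__ = ["SimulationConfig", "load_config", "material_from_dict"]


def material_from_dict(d: dict) -> MaterialParameters:
    d = dict(d)
    if "alpha_deg" in d:
        d["alpha"] = math.radians(d.pop("alpha_deg"))
    return MaterialParameters(**d)


@dataclass
class SimulationConfig:
    """Fully resolved inputs of one coupled simulation."""

    material: MaterialParameters
    geometry: ArteryGeometry
    notch: NotchParameters
    coupling: CouplingSpec
    Phi: float | str = "calibrate"  # degrees, or "calibrate"
    lambda_axial: float = 1.39
    retain_frac_axial: float = 1.0
    retain_frac_circ: float = 1.0
    seed: int = 0
    n_repeats: int = 3
    t_end: float = 250.0

    def fiber_set(self):
        return build_fiber_set(self.material)

    def residual_field(self, Phi: float | None = None) -> ResidualStretchField:
        if Phi is None:
            if self.Phi == "calibrate":
                raise ValueError("opening angle not yet calibrated; pass Phi explicitly")
            Phi = float(self.Phi)
        return prestretch_profile(
            self.geometry,
            Phi,
            lambda_axial=self.lambda_axial,
            retain_frac_axial=self.retain_frac_axial,
            retain_frac_circ=self.retain_frac_circ,
        )

    def to_dict(self) -> dict:
        out = {
            "material": {**self.material.__dict__},
            "geometry": {**self.geometry.__dict__},
            "notch": {**self.notch.__dict__},
            "coupling": {**self.coupling.__dict__},
            "Phi": self.Phi,
            "lambda_axial": self.lambda_axial,
            "retain_frac_axial": self.retain_frac_axial,
            "retain_frac_circ": self.retain_frac_circ,
            "seed": self.seed,
            "n_repeats": self.n_repeats,
            "t_end": self.t_end,
        }
        out["material"]["alpha_deg"] = math.degrees(out["material"].pop("alpha"))
        return out


def load_config(path_or_dict) -> SimulationConfig:
    """Load a simulation configuration from YAML/JSON or a plain dict."""
    if isinstance(path_or_dict, dict):
        doc = path_or_dict
    else:
        text = Path(path_or_dict).read_text()
        doc = yaml.safe_load(text)  # YAML is a JSON superset
    doc = doc or {}
    material = material_from_dict(doc.get("material", {}))
    geometry = ArteryGeometry(**doc.get("geometry", {}))
    notch = NotchParameters(**doc.get("notch", {}))
    coupling = CouplingSpec(**doc.get("coupling", {}))
    top = {
        k: doc[k]
        for k in (
            "Phi",
            "lambda_axial",
            "retain_frac_axial",
            "retain_frac_circ",
            "seed",
            "n_repeats",
            "t_end",
        )
        if k in doc
    }
    return SimulationConfig(
        material=material, geometry=geometry, notch=notch, coupling=coupling, **top
    )
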