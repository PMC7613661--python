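"""Basic visualization helpers: wall profiles and per-cell heat maps.

Deliberately plain — these are working plots for inspecting simulations,
not publication figures.
"""

from __future__ import annotations

import numpy as np

__all__ = ["plot_wall_profile", "plot_cell_heatmap"]


def plot_wall_profile(solution, quantity: str = "lambda_e_theta", ax=None):
    """Plot one radial profile of a wall solution against reference radius."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    y = getattr(solution, quantity)
    ax.plot(solution.R, y, marker=".", lw=1)
    ax.set_xlabel("stress-free radius (mm)")
    ax.set_ylabel(quantity)
    ax.set_title(f"{quantity} at {solution.pressure_mmhg:g} mmHg")
    return ax


def plot_cell_heatmap(values_by_condition: dict, ax=None, label="normalized NICD"):
    """Heat map of per-cell values (rows: conditions, columns: cells).

    Cell 1 (luminal) is on the left; a diverging scale is centered on 1 so
    synthetic shifts read blue and contractile shifts red.
    """
    import matplotlib.pyplot as plt

    names = list(values_by_condition)
    data = np.array([np.asarray(values_by_condition[k], dtype=float) for k in names])
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.5 + 0.4 * len(names)))
    span = max(np.max(np.abs(data - 1.0)), 1e-6)
    im = ax.imshow(
        data, aspect="auto", cmap="RdBu_r", vmin=1.0 - span, vmax=1.0 + span
    )
    ax.set_yticks(range(len(names)), names)
    ax.set_xlabel("cell (luminal to abluminal)")
    ax.figure.colorbar(im, ax=ax, label=label)
    return ax
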