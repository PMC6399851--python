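"""Deterministic figure rendering for scenario sweeps.

Figures are a reporting convenience: every numeric claim lives in the
exported CSV/JSON trajectories, and determinism is asserted on those.
Rendering uses a fixed size, the Agg backend and legends ordered by
sorted label, so repeated runs produce identical plots from identical
data.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .trajectory import Trajectory

_FIGSIZE = (7.0, 4.5)
_DPI = 150

#: default series per figure style
_STYLE_SERIES = {
    "fig2": ("C_int_p", "C_int_n", "total_intracellular"),
    "fig3": ("T1", "T2", "T_total"),
    "fig4": ("T_total",),
    "fig5": ("T_total",),
    "generic": None,
}


def plot_scenario(
    trajectories: Mapping[str, Trajectory],
    out_dir: str | Path,
    style: str = "generic",
    stem: str | None = None,
) -> list[Path]:
    """Render one panel per series of ``style``; returns the files written.

    ``trajectories`` maps legend labels to trajectories on arbitrary
    grids.  With ``style="generic"`` every series present in the first
    trajectory gets a panel.
    """
    if not trajectories:
        raise ValueError("no trajectories to plot")
    if style not in _STYLE_SERIES:
        raise ValueError(f"unknown style {style!r}; choose from {sorted(_STYLE_SERIES)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = sorted(trajectories)
    series = _STYLE_SERIES[style]
    if series is None:
        series = tuple(trajectories[labels[0]].names)
    stem = stem or style
    written: list[Path] = []
    for name in series:
        fig, ax = plt.subplots(figsize=_FIGSIZE, dpi=_DPI)
        for label in labels:
            traj = trajectories[label]
            if name not in traj:
                continue
            ax.plot(traj.time, traj[name], label=label, linewidth=1.2)
        ax.set_xlabel("time (days)")
        ax.set_ylabel(name)
        ax.set_title(f"{stem}: {name}")
        ax.legend(fontsize=6, ncol=2)
        path = out_dir / f"{stem}_{name}.png"
        fig.savefig(path)
        plt.close(fig)
        written.append(path)
    if not written:
        raise ValueError(f"no trajectory contains any of the series {series}")
    return written
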