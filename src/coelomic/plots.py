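"""Optional Davenport-style diagnostics (pH vs [HCO3-] with the NBB line)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .chemistry import SolubilityTable, hco3_from_tco2
from .tonometry import TonometrySeries, fit_nbb_line


def davenport_figure(series: TonometrySeries, table: SolubilityTable | None = None):
    """Per-individual titration points and fitted non-bicarbonate buffer line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if table is None:
        table = SolubilityTable.default()
    alpha = table.alpha_at(series.temperature)
    ph = np.array([s.measured_ph for s in series.steps])
    hco3 = np.array(
        [hco3_from_tco2(s.measured_tco2, s.set_tension, alpha) for s in series.steps]
    )
    line = fit_nbb_line(series, table)
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.scatter(ph, hco3, color="tab:blue", zorder=3)
    grid = np.linspace(ph.min(), ph.max(), 50)
    ax.plot(grid, line.intercept + line.slope * grid, color="tab:red",
            label=f"NBB slope {line.slope:.2f}")
    ax.set_xlabel("pH")
    ax.set_ylabel("[HCO3-] (mmol/L)")
    ax.set_title(f"{series.individual_id} @ {series.temperature:g} C")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    return fig


def save_davenport_plots(series_list, out_dir, table=None) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for series in series_list:
        fig = davenport_figure(series, table)
        path = out / f"davenport_{series.individual_id}.png"
        fig.savefig(path, dpi=100)
        paths.append(path)
        import matplotlib.pyplot as plt

        plt.close(fig)
    return paths
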