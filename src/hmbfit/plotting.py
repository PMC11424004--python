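"""Optional plotting helpers (requires matplotlib).

Log-log rate-versus-time scatter with the fitted and noise-free
prediction lines; never required by any analysis path.
"""

from __future__ import annotations

import numpy as np

from .data import RateDataset
from .model import ModelFit, denoised_prediction, predict_rate
from .uncertainty import default_time_grid


def plot_fit(dataset: RateDataset, fit: ModelFit, ax=None):
    """Scatter the data and overlay fitted and denoised curves."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    grid = default_time_grid(dataset)
    positive = dataset.rate > 0
    ax.scatter(dataset.time[positive], dataset.rate[positive], s=8, alpha=0.4,
               label="observed")
    ax.plot(grid, predict_rate(fit.params, grid), "k-",
            label=f"{fit.variant.label} fit")
    denoised = np.asarray(denoised_prediction(fit.params, grid))
    ok = denoised > 0
    if ok.any():
        ax.plot(grid[ok], denoised[ok], "g--", label="without h/t term")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("time")
    ax.set_ylabel("rate")
    ax.legend()
    return ax
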