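"""Static figures: calibration-by-decile and paired-calculator scatter."""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .metrics import calibration_plot_data, scatter_compare  # noqa: E402


def plot_calibration(predictions, times, events, horizon: float = 10.0, ax=None,
                     title: str = ""):
    """Observed (KM, with CI bars) vs predicted risk by decile of prediction."""
    tab = calibration_plot_data(predictions, times, events, horizon=horizon)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    x = tab["mean_predicted"]
    y = tab["observed_km_risk"]
    yerr = [(y - tab["observed_ci_lower"]).clip(lower=0),
            (tab["observed_ci_upper"] - y).clip(lower=0)]
    ax.errorbar(x, y, yerr=yerr, fmt="o", capsize=3)
    lim = max(float(x.max()), float(tab["observed_ci_upper"].max())) * 1.05
    ax.plot([0, lim], [0, lim], "--", color="grey")
    ax.set_xlabel("Predicted 10-year risk")
    ax.set_ylabel("Observed 10-year risk (KM)")
    ax.set_title(title)
    return ax


def plot_scatter_compare(pred_reference, pred_model, ax=None, title: str = "",
                         xlabel: str = "reference", ylabel: str = "model"):
    """Paired risks with identity (dashed) and a lowess trend (solid)."""
    tab = scatter_compare(pred_reference, pred_model)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(tab["x"], tab["y"], s=4, alpha=0.3)
    order = tab.sort_values("x")
    ax.plot(order["x"], order["identity"], "--", color="grey")
    ax.plot(order["x"], order["trend"], "-", color="black")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.set_title(title)
    return ax
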