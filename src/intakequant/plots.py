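"""Static PNG diagnostics: posterior histograms, trace plots, dose boxplots
and predictive-intake histograms.

Histogram panels annotate the posterior median and equal-tailed 95% credible
interval; predictive histograms keep the full draw vector so multi-modal
intake distributions render faithfully.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .model_core import InterventionData
from .prediction import PredictionResult
from .sampler import FittedModel, summarize_chain

__all__ = ["plot_outputs"]

_SCALAR_CHAINS = ("alpha", "beta", "sigma2", "theta2", "zeta", "w")


def _scalar_series(model: FittedModel):
    for name in _SCALAR_CHAINS:
        arr = model.chains[name]
        for k in range(arr.shape[1]):
            yield f"{name}_{k + 1}", arr[:, k]


def _hist_panel(ax, draws, title):
    med, _, lo, hi = summarize_chain(draws)
    ax.hist(draws, bins=40, color="#6baed6", edgecolor="white")
    ax.axvline(med, color="#08306b", lw=1.5,
               label=f"median {med:.3g}")
    ax.axvline(lo, color="#08306b", lw=1.0, ls="--",
               label=f"95% CI [{lo:.3g}, {hi:.3g}]")
    ax.axvline(hi, color="#08306b", lw=1.0, ls="--")
    ax.set_title(title, fontsize=9)
    ax.legend(fontsize=6, frameon=False)


def _posterior_histograms(model: FittedModel, path: Path) -> list:
    series = list(_scalar_series(model))
    ncol = 3
    nrow = int(np.ceil(len(series) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 2.4 * nrow),
                             squeeze=False)
    for ax in axes.ravel():
        ax.set_axis_off()
    for ax, (name, draws) in zip(axes.ravel(), series):
        ax.set_axis_on()
        _hist_panel(ax, draws, name)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return [path]


def _trace_plots(model: FittedModel, outdir: Path) -> list:
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, draws in _scalar_series(model):
        fig, ax = plt.subplots(figsize=(6, 2.2))
        ax.plot(draws, lw=0.5, color="#238b45")
        ax.set_title(f"trace: {name}", fontsize=9)
        ax.set_xlabel("retained iteration", fontsize=8)
        fig.tight_layout()
        target = outdir / f"trace_{name}.png"
        fig.savefig(target, dpi=100)
        plt.close(fig)
        written.append(target)
    return written


def _dose_boxplots(data: InterventionData, path: Path) -> list:
    P = data.P
    fig, axes = plt.subplots(1, P, figsize=(3.0 * P, 3.2), squeeze=False)
    for p, ax in enumerate(axes[0]):
        groups = [data.biomarkers[data.dose_index == d, p]
                  for d in range(data.D)]
        ax.boxplot(groups, tick_labels=[f"{x:g}" for x in data.dose_levels])
        ax.set_xlabel(f"food quantity ({data.unit})", fontsize=8)
        ax.set_title(f"biomarker {p + 1}", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return [path]


def _prediction_histograms(result: PredictionResult, path: Path) -> list:
    n = result.n_obs
    ncol = min(n, 3) or 1
    nrow = int(np.ceil(max(n, 1) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 2.4 * nrow),
                             squeeze=False)
    for ax in axes.ravel():
        ax.set_axis_off()
    unit = result.meta.get("unit") or "units"
    for j in range(n):
        ax = axes.ravel()[j]
        ax.set_axis_on()
        _hist_panel(ax, result.draws[:, j], f"observation {j + 1} ({unit})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return [path]


def plot_outputs(obj: Union[FittedModel, PredictionResult, InterventionData],
                 kind: str, path) -> list:
    """Write PNG output(s) for a model, prediction result or dataset.

    ``kind`` is one of ``posterior_histogram`` (fitted model),
    ``trace`` (fitted model; ``path`` is a directory, one file per
    parameter), ``boxplot`` (intervention data) or ``predictive_histogram``
    (prediction result).  Returns the list of files written.
    """
    path = Path(path)
    if kind == "posterior_histogram":
        if not isinstance(obj, FittedModel):
            raise TypeError("posterior_histogram requires a FittedModel")
        return _posterior_histograms(obj, path)
    if kind == "trace":
        if not isinstance(obj, FittedModel):
            raise TypeError("trace requires a FittedModel")
        return _trace_plots(obj, path)
    if kind == "boxplot":
        if not isinstance(obj, InterventionData):
            raise TypeError("boxplot requires InterventionData")
        return _dose_boxplots(obj, path)
    if kind == "predictive_histogram":
        if not isinstance(obj, PredictionResult):
            raise TypeError("predictive_histogram requires a PredictionResult")
        return _prediction_histograms(obj, path)
    raise ValueError(f"unknown plot kind {kind!r}")
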