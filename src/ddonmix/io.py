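"""Reading and writing the package's file formats.

The canonical exchange format for survey counts is a long-format CSV
(UTF-8, header required) with the columns
``species, plot, year, replicate, observer_primary, observer_secondary,
y_primary, y_secondary`` plus an optional plot-metadata CSV
(``plot, ownership``). Posterior draws and summaries are written as CSV;
simulation truths as a two-column parameter/value CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import DDOCounts
from .mcmc import PosteriorSamples
from .simulate import SimulationTruth

__all__ = [
    "read_dataset",
    "write_dataset",
    "write_truth",
    "read_truth",
    "write_draws",
    "read_draws",
]


def read_dataset(path, plot_meta_path=None) -> DDOCounts:
    """Read and validate a long-format DDO count CSV.

    Schema violations raise :class:`ddonmix.datasets.SchemaError` naming
    the offending rows or columns.
    """
    table = pd.read_csv(path)
    meta = pd.read_csv(plot_meta_path) if plot_meta_path else None
    return DDOCounts.from_frame(table, plot_meta=meta)


def write_dataset(data: DDOCounts, path, plot_meta_path=None) -> None:
    """Write counts (and, if present, plot metadata) as canonical CSV."""
    data.to_frame().to_csv(path, index=False)
    meta = data.plot_meta_frame()
    if meta is not None:
        if plot_meta_path is None:
            plot_meta_path = Path(path).with_name(Path(path).stem + "_plots.csv")
        meta.to_csv(plot_meta_path, index=False)


def _truth_records(truth: SimulationTruth, data: DDOCounts):
    if truth.lambda_species is not None:
        for s, v in zip(data.species, truth.lambda_species):
            yield f"lambda[{s}]", v
    if truth.p_primary is not None:
        yield "p[primary]", truth.p_primary
        yield "p[secondary]", truth.p_secondary
    if truth.observer_p is not None:
        for o, v in zip(data.observers, truth.observer_p):
            yield f"p[{o}]", v
    for name, arr in (("beta0", truth.beta0), ("beta1", truth.beta1), ("beta2", truth.beta2)):
        if arr is not None:
            for s, v in zip(data.species, arr):
                yield f"{name}[{s}]", v
    if truth.alpha is not None and truth.sigma_plot is not None and truth.sigma_plot > 0:
        for p, v in zip(data.plots, truth.alpha):
            yield f"alpha[{p}]", v
        yield "sigma_plot", truth.sigma_plot
    S, J, Y = truth.N.shape
    for si, s in enumerate(data.species):
        for pj, p in enumerate(data.plots):
            for yi, y in enumerate(data.years):
                label = f"N[{s},{p}]" if Y == 1 else f"N[{s},{p},{y}]"
                yield label, int(truth.N[si, pj, yi])


def write_truth(truth: SimulationTruth, data: DDOCounts, path) -> None:
    """Persist generating parameter values as a parameter/value CSV."""
    pd.DataFrame(_truth_records(truth, data), columns=["parameter", "value"]).to_csv(
        path, index=False
    )


def read_truth(path) -> dict:
    """Load a truth CSV back as a parameter-name -> value dict."""
    df = pd.read_csv(path)
    return dict(zip(df["parameter"], df["value"]))


def write_draws(samples: PosteriorSamples, path) -> None:
    """Persist kept draws as long CSV (chain, draw, parameter, value)."""
    samples.to_frame().to_csv(path, index=False)


def read_draws(path) -> PosteriorSamples:
    """Reconstruct a :class:`PosteriorSamples` from a draws CSV.

    The chain x draw grid must be complete for every parameter.
    """
    df = pd.read_csv(path)
    chains = np.sort(df["chain"].unique())
    draws = np.sort(df["draw"].unique())
    C, T = len(chains), len(draws)
    names = list(dict.fromkeys(df["parameter"]))
    wide = df.pivot_table(index=["chain", "draw"], columns="parameter", values="value")
    if len(wide) != C * T or wide[names].isna().any().any():
        raise ValueError("draws file has an incomplete chain x draw grid")
    groups, labels = {}, {}
    for name in names:
        g = "N" if name.startswith("N[") else "params"
        labels.setdefault(g, []).append(name)
    for g, ls in labels.items():
        arr = np.empty((C, T, len(ls)))
        for pos, name in enumerate(ls):
            arr[:, :, pos] = wide[name].to_numpy().reshape(C, T)
        groups[g] = arr
    return PosteriorSamples(groups, labels, acceptance={}, spec=None, config=None)
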