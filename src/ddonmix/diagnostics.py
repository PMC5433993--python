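"""Convergence diagnostics and posterior summaries.

R-hat is the classic Gelman–Rubin potential scale reduction factor,
computed on *split* chains (each chain halved) so that within-chain drift
is also detected; the usual pass criterion is values below about 1.01
(strictly below 1.1 as a coarse gate).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .mcmc import PosteriorSamples

__all__ = ["rhat", "summarize", "trace_report"]


def rhat(draws: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for one parameter.

    Parameters
    ----------
    draws:
        Array of shape (n_chains, n_draws) with burn-in already removed;
        at least 2 chains and 4 draws per chain are required.

    Returns
    -------
    float
        sqrt(((n-1)/n * W + B/n) / W) over the 2*n_chains half-chains.
        Chains with zero total variance return exactly 1.0.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2:
        raise ValueError("rhat needs draws shaped (n_chains >= 2, n_draws)")
    if draws.shape[1] < 4:
        raise ValueError("rhat needs at least 4 draws per chain")
    n_half = draws.shape[1] // 2
    halves = np.concatenate(
        [draws[:, :n_half], draws[:, n_half: 2 * n_half]], axis=0
    )
    m, n = halves.shape
    chain_means = halves.mean(axis=1)
    W = halves.var(axis=1, ddof=1).mean()
    B = n * chain_means.var(ddof=1)
    if W <= 0.0:
        # all half-chains constant: either fully degenerate (treated as
        # converged) or disjoint constants (clearly diverged)
        return 1.0 if B <= 0.0 else np.inf
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def summarize(samples: PosteriorSamples, params: list | None = None) -> pd.DataFrame:
    """Posterior summary table: mean, sd, equal-tailed 95% CRI and R-hat.

    Chains are pooled for the moments and percentiles (linear interpolation
    between order statistics, the numpy default). One row per parameter.
    """
    names = params if params is not None else samples.param_names()
    rows = []
    for name in names:
        draws = samples.get(name)
        pooled = draws.ravel()
        q_lo, q_hi = np.percentile(pooled, [2.5, 97.5])
        rows.append(
            {
                "parameter": name,
                "mean": float(pooled.mean()),
                "sd": float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0,
                "q2.5": float(q_lo),
                "q97.5": float(q_hi),
                "rhat": rhat(draws) if draws.shape[0] >= 2 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def max_rhat(samples: PosteriorSamples, monitored_only: bool = True) -> float:
    """Largest split-chain R-hat over the (monitored) parameters.

    Monitored parameters are the abundance and detection parameters; the
    per-site latent N draws are excluded by default.
    """
    values = [
        rhat(samples.get(name))
        for name in samples.param_names(monitored_only=monitored_only)
    ]
    return float(np.max(values))


def trace_report(samples: PosteriorSamples, path, params: list | None = None) -> list:
    """Render trace and posterior-density plots, one figure per parameter.

    Returns the list of written file paths. An empty parameter selection
    produces no artifacts and logs a warning.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from pathlib import Path

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    names = params if params is not None else samples.param_names(monitored_only=True)
    if not names:
        warnings.warn("trace_report: empty parameter selection, nothing rendered")
        return []
    written = []
    for name in names:
        draws = samples.get(name)
        fig, (ax_tr, ax_de) = plt.subplots(1, 2, figsize=(8, 2.6), constrained_layout=True)
        for c in range(draws.shape[0]):
            ax_tr.plot(draws[c], lw=0.4)
        ax_tr.set_title(f"trace: {name}", fontsize=9)
        ax_tr.set_xlabel("kept iteration")
        pooled = draws.ravel()
        if np.ptp(pooled) > 0:
            ax_de.hist(pooled, bins=60, density=True, color="0.4")
        else:
            ax_de.axvline(pooled[0], color="0.4")
        ax_de.set_title("posterior density", fontsize=9)
        fname = path / (name.replace("[", "_").replace("]", "").replace(",", "_") + ".png")
        fig.savefig(fname, dpi=100)
        plt.close(fig)
        written.append(fname)
    return written
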