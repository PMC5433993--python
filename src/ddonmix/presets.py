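"""Shipped study designs.

``basic`` is the single-season evaluation design: four species on 20
plots, three replicate visits, fixed observer roles with detection 0.3
(primary) and 0.5 (secondary). ``casestudy`` emulates the two-year
songbird field layout: eight species, 40 public + 40 private plots,
three visits per year, a pool of 14 observers with heterogeneous
detection, and ownership/year/plot effects on log abundance.
"""

from __future__ import annotations

from .mcmc import MCMCConfig
from .model import ModelSpec, Priors
from .simulate import SimConfig

__all__ = ["PRESETS", "get_preset"]

PRESETS = {
    "basic": {
        "sim": SimConfig(),
        "spec": ModelSpec(variant="basic", detection_structure="by_role"),
        "simulator": "basic",
    },
    "casestudy": {
        "sim": SimConfig(
            n_species=8,
            n_plots=80,
            n_years=2,
            n_replicates=3,
            n_observers=14,
            sigma_plot_truth=0.3,
        ),
        "spec": ModelSpec(variant="covariate", detection_structure="by_observer_and_species"),
        "simulator": "covariate",
    },
}


def get_preset(name: str) -> dict:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    preset = dict(PRESETS[name])
    preset.setdefault("priors", Priors())
    preset.setdefault("mcmc", MCMCConfig())
    return preset
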