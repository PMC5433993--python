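"""Containers for dependent double-observer (DDO) survey count data.

A DDO survey records, for every species x plot x replicate (x year), two
counts: the number of individuals detected by the primary observer
(``y_primary``) and the number detected by the secondary observer that the
primary missed (``y_secondary``). Individuals missed by both observers are
unobserved; their number is part of the latent state of the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = (
    "species",
    "plot",
    "year",
    "replicate",
    "observer_primary",
    "observer_secondary",
    "y_primary",
    "y_secondary",
)


class SchemaError(ValueError):
    """Raised when a count table violates the DDO data schema."""


@dataclass
class DDOCounts:
    """Validated, array-backed DDO count dataset.

    The canonical exchange form is a long-format table with one row per
    (species, plot, year, replicate). Internally the counts are stored as
    dense arrays indexed ``[species, plot, year, replicate]`` so the model
    layer can operate without group-bys. The design must be complete: every
    species is surveyed on every plot, year and replicate, with explicit
    zero counts where nothing was seen.

    Attributes
    ----------
    species, plots, years, observers:
        Ordered label registries; array axes refer to positions in these.
    y1, y2:
        Integer count arrays of shape (S, J, Y, K): primary detections and
        secondary-only detections.
    obs_primary, obs_secondary:
        Observer-index arrays of shape (J, Y, K); the observer pair is a
        property of the survey visit and is shared across species.
    ownership:
        Optional per-plot binary covariate (0 = public, 1 = private),
        shape (J,). Required by the covariate model variant.
    """

    species: list
    plots: list
    years: list
    observers: list
    y1: np.ndarray
    y2: np.ndarray
    obs_primary: np.ndarray
    obs_secondary: np.ndarray
    ownership: np.ndarray | None = None
    year_codes: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.y1 = np.asarray(self.y1, dtype=np.int64)
        self.y2 = np.asarray(self.y2, dtype=np.int64)
        S, J, Y, K = self.shape
        if self.y1.shape != (S, J, Y, K) or self.y2.shape != (S, J, Y, K):
            raise SchemaError(
                f"count arrays must have shape {(S, J, Y, K)}, "
                f"got {self.y1.shape} / {self.y2.shape}"
            )
        if (self.y1 < 0).any() or (self.y2 < 0).any():
            raise SchemaError("negative counts are not allowed")
        self.obs_primary = np.asarray(self.obs_primary, dtype=np.int64)
        self.obs_secondary = np.asarray(self.obs_secondary, dtype=np.int64)
        if self.obs_primary.shape != (J, Y, K) or self.obs_secondary.shape != (J, Y, K):
            raise SchemaError(f"observer index arrays must have shape {(J, Y, K)}")
        if self.ownership is not None:
            self.ownership = np.asarray(self.ownership, dtype=np.int64)
            if self.ownership.shape != (J,):
                raise SchemaError("ownership must be one code per plot")
            if not np.isin(self.ownership, [0, 1]).all():
                raise SchemaError("ownership codes must be 0 (public) or 1 (private)")
        if self.year_codes is None:
            # years coded 0, 1, ... in sorted order (binary in the two-year design)
            self.year_codes = np.arange(Y, dtype=np.int64)
        else:
            self.year_codes = np.asarray(self.year_codes, dtype=np.int64)

    # ------------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int, int]:
        """(n_species, n_plots, n_years, n_replicates)."""
        return (len(self.species), len(self.plots), len(self.years), self.y1.shape[3] if self.y1.ndim == 4 else 0)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_plots(self) -> int:
        return len(self.plots)

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def n_replicates(self) -> int:
        return self.y1.shape[3]

    @property
    def detected(self) -> np.ndarray:
        """Total detected per survey, y1 + y2, shape (S, J, Y, K)."""
        return self.y1 + self.y2

    @property
    def n_floor(self) -> np.ndarray:
        """Lower bound on latent abundance: max over replicates of y1+y2, shape (S, J, Y)."""
        if self.n_replicates == 0:
            return np.zeros((self.n_species, self.n_plots, self.n_years), dtype=np.int64)
        return self.detected.max(axis=3)

    @property
    def is_empty(self) -> bool:
        return self.y1.size == 0

    # ------------------------------------------------------------------
    @classmethod
    def empty(cls, species: list, observers: list | None = None) -> "DDOCounts":
        """A dataset with a species registry but no surveys (prior-only fits)."""
        S = len(species)
        return cls(
            species=list(species),
            plots=[],
            years=[0],
            observers=list(observers) if observers else ["obs1", "obs2"],
            y1=np.zeros((S, 0, 1, 0), dtype=np.int64),
            y2=np.zeros((S, 0, 1, 0), dtype=np.int64),
            obs_primary=np.zeros((0, 1, 0), dtype=np.int64),
            obs_secondary=np.zeros((0, 1, 0), dtype=np.int64),
        )

    @classmethod
    def from_frame(
        cls,
        table: pd.DataFrame,
        plot_meta: pd.DataFrame | None = None,
    ) -> "DDOCounts":
        """Build a validated dataset from a long-format table.

        Raises :class:`SchemaError` with the offending rows named when the
        table is malformed.
        """
        missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
        if missing:
            raise SchemaError(f"missing required columns: {missing}")
        tbl = table.copy()
        for col in ("y_primary", "y_secondary"):
            bad = tbl.index[pd.to_numeric(tbl[col], errors="coerce").fillna(-1) < 0]
            if len(bad):
                raise SchemaError(f"negative or non-numeric {col} in rows {list(bad[:10])}")
            tbl[col] = tbl[col].astype(np.int64)
        key = ["species", "plot", "year", "replicate"]
        dup = tbl.index[tbl.duplicated(subset=key)]
        if len(dup):
            raise SchemaError(f"duplicate (species, plot, year, replicate) rows: {list(dup[:10])}")

        species = sorted(tbl["species"].astype(str).unique())
        plots = sorted(tbl["plot"].astype(str).unique())
        years = sorted(tbl["year"].astype(int).unique())
        reps = sorted(tbl["replicate"].astype(int).unique())
        S, J, Y, K = len(species), len(plots), len(years), len(reps)
        if len(tbl) != S * J * Y * K:
            raise SchemaError(
                f"incomplete design: expected {S * J * Y * K} rows "
                f"({S} species x {J} plots x {Y} years x {K} replicates), got {len(tbl)}"
            )
        obs_labels = sorted(
            set(tbl["observer_primary"].astype(str)) | set(tbl["observer_secondary"].astype(str))
        )
        sp_idx = {s: i for i, s in enumerate(species)}
        pl_idx = {p: j for j, p in enumerate(plots)}
        yr_idx = {y: t for t, y in enumerate(years)}
        rp_idx = {r: k for k, r in enumerate(reps)}
        ob_idx = {o: m for m, o in enumerate(obs_labels)}

        y1 = np.zeros((S, J, Y, K), dtype=np.int64)
        y2 = np.zeros((S, J, Y, K), dtype=np.int64)
        obs_p = np.full((J, Y, K), -1, dtype=np.int64)
        obs_s = np.full((J, Y, K), -1, dtype=np.int64)
        si = tbl["species"].astype(str).map(sp_idx).to_numpy()
        ji = tbl["plot"].astype(str).map(pl_idx).to_numpy()
        yi = tbl["year"].astype(int).map(yr_idx).to_numpy()
        ki = tbl["replicate"].astype(int).map(rp_idx).to_numpy()
        y1[si, ji, yi, ki] = tbl["y_primary"].to_numpy()
        y2[si, ji, yi, ki] = tbl["y_secondary"].to_numpy()
        op = tbl["observer_primary"].astype(str).map(ob_idx).to_numpy()
        os_ = tbl["observer_secondary"].astype(str).map(ob_idx).to_numpy()
        # observer pair belongs to the survey visit; verify consistency across species
        prev_p = obs_p[ji, yi, ki]
        conflict = (prev_p >= 0) & (prev_p != op)
        obs_p[ji, yi, ki] = op
        prev_s = obs_s[ji, yi, ki]
        conflict |= (prev_s >= 0) & (prev_s != os_)
        obs_s[ji, yi, ki] = os_
        if conflict.any():
            rows = list(tbl.index[conflict][:10])
            raise SchemaError(f"inconsistent observer assignment within a survey: rows {rows}")

        ownership = None
        if plot_meta is not None:
            if not {"plot", "ownership"} <= set(plot_meta.columns):
                raise SchemaError("plot metadata needs columns 'plot' and 'ownership'")
            meta = plot_meta.astype({"plot": str}).set_index("plot")["ownership"]
            missing_plots = [p for p in plots if p not in meta.index]
            if missing_plots:
                raise SchemaError(f"plots missing from metadata: {missing_plots[:10]}")
            codes = meta.loc[plots].map({"public": 0, "private": 1, 0: 0, 1: 1})
            if codes.isna().any():
                raise SchemaError("ownership must be 'public'/'private' (or 0/1)")
            ownership = codes.to_numpy(dtype=np.int64)

        return cls(
            species=species,
            plots=plots,
            years=years,
            observers=obs_labels,
            y1=y1,
            y2=y2,
            obs_primary=obs_p,
            obs_secondary=obs_s,
            ownership=ownership,
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with canonical column order and row sort."""
        S, J, Y, K = self.shape
        si, ji, yi, ki = np.meshgrid(
            np.arange(S), np.arange(J), np.arange(Y), np.arange(K), indexing="ij"
        )
        si, ji, yi, ki = (a.ravel() for a in (si, ji, yi, ki))
        return pd.DataFrame(
            {
                "species": np.asarray(self.species, dtype=object)[si],
                "plot": np.asarray(self.plots, dtype=object)[ji],
                "year": np.asarray(self.years)[yi],
                "replicate": ki + 1,
                "observer_primary": np.asarray(self.observers, dtype=object)[
                    self.obs_primary[ji, yi, ki]
                ],
                "observer_secondary": np.asarray(self.observers, dtype=object)[
                    self.obs_secondary[ji, yi, ki]
                ],
                "y_primary": self.y1[si, ji, yi, ki],
                "y_secondary": self.y2[si, ji, yi, ki],
            }
        )

    def plot_meta_frame(self) -> pd.DataFrame | None:
        if self.ownership is None:
            return None
        return pd.DataFrame(
            {
                "plot": self.plots,
                "ownership": np.where(self.ownership == 1, "private", "public"),
            }
        )
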