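"""Observed-count summary fixture from the two-year sagebrush songbird study.

Eight prairie songbird species were surveyed with the dependent
double-observer protocol on 40 public-land and 40 private-land plots
(three visits per year, 2013 and 2014). For each species x ownership x
year cell the fixture records in how many of the 40 plots the species was
detected and the total number of individuals observed. The raw per-survey
records are not public; this summary table is the packaged case-study
reference, used for totals checks and as the size template for the
case-study emulation preset.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = ["case_study_observations", "case_study_totals"]

_OBSERVATIONS_CSV = """\
species,year,ownership,plots_detected,observed
Brewer's sparrow,2013,public,35,979
Brewer's sparrow,2013,private,27,804
Brewer's sparrow,2014,public,33,1101
Brewer's sparrow,2014,private,24,927
Brown-headed cowbird,2013,public,30,200
Brown-headed cowbird,2013,private,17,90
Brown-headed cowbird,2014,public,26,203
Brown-headed cowbird,2014,private,20,120
Chestnut-collared longspur,2013,public,16,168
Chestnut-collared longspur,2013,private,19,272
Chestnut-collared longspur,2014,public,5,209
Chestnut-collared longspur,2014,private,16,197
Horned lark,2013,public,33,597
Horned lark,2013,private,37,1015
Horned lark,2014,public,31,870
Horned lark,2014,private,37,1075
Lark bunting,2013,public,17,345
Lark bunting,2013,private,17,113
Lark bunting,2014,public,19,352
Lark bunting,2014,private,20,234
McCown's longspur,2013,public,18,1037
McCown's longspur,2013,private,31,2450
McCown's longspur,2014,public,15,726
McCown's longspur,2014,private,29,2824
Vesper sparrow,2013,public,39,1066
Vesper sparrow,2013,private,39,936
Vesper sparrow,2014,public,38,1057
Vesper sparrow,2014,private,37,1030
Western meadowlark,2013,public,40,795
Western meadowlark,2013,private,40,400
Western meadowlark,2014,public,40,779
Western meadowlark,2014,private,39,471
"""


def case_study_observations() -> pd.DataFrame:
    """The packaged case-study observation summary (long format)."""
    return pd.read_csv(io.StringIO(_OBSERVATIONS_CSV))


def case_study_totals(fixture: pd.DataFrame | None = None) -> dict:
    """Column and yearly totals of the case-study observation summary.

    Returns a dict with per-(year, ownership) totals of observed
    individuals and per-year totals summed over ownership.

    Raises
    ------
    ValueError
        If the fixture is incomplete (any of the 8 species x 2 ownerships
        x 2 years cells missing) or contains negative counts.
    """
    fx = case_study_observations() if fixture is None else fixture
    required = {"species", "year", "ownership", "observed"}
    if not required <= set(fx.columns):
        raise ValueError(f"fixture must have columns {sorted(required)}")
    if (fx["observed"] < 0).any() or ("plots_detected" in fx and (fx["plots_detected"] < 0).any()):
        raise ValueError("fixture counts must be nonnegative")
    cells = fx.groupby(["year", "ownership"])["species"].nunique()
    n_species = fx["species"].nunique()
    if len(cells) != 4 or (cells != n_species).any():
        raise ValueError("fixture is incomplete: need every species x ownership x year cell")

    by_cell = fx.groupby(["year", "ownership"])["observed"].sum()
    out = {
        f"{year}_{own}": int(total) for (year, own), total in by_cell.items()
    }
    for year, total in fx.groupby("year")["observed"].sum().items():
        out[f"{year}_total"] = int(total)
    return out
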