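"""Areal count tables and prevalence aggregation.

The central container is :class:`RegionTable`: one row per areal unit
(country, province, or synthetic lattice cell) carrying an event count
(women meeting the recommended number of antenatal-care contacts), a
denominator (women surveyed), a survey year, and optional community-level
covariate proportions.

A packaged summary of the most recent DHS surveys of 34 sub-Saharan
African countries (2010-2023) ships with the package; see
:func:`load_anc_table`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RegionTable",
    "SSA_SUBREGIONS",
    "load_anc_table",
    "weighted_group_proportion",
    "assign_survey_era",
    "round_half_up",
]

ERA_BEFORE = "Before 2017"
ERA_AFTER = "After 2017 (included)"

#: Columns with reserved meaning in a region table; all other numeric
#: columns are treated as covariates (proportions in [0, 100]).
CORE_COLUMNS = ("unit_id", "country", "region_label", "survey_year", "sample", "events")

# Country-level DHS summary: (country, survey year, women surveyed,
# number of provinces, women meeting the recommended ANC contacts).
# The recommended threshold is >= 4 contacts for surveys run under the
# pre-2016 WHO guideline and >= 8 contacts afterwards.
_ANC_ROWS = [
    ("Angola", 2015, 6103, 18, 475),
    ("Benin", 2017, 8720, 12, 782),
    ("Burkina Faso", 2021, 6211, 13, 54),
    ("Burundi", 2016, 8260, 18, 4118),
    ("Cameroon", 2018, 5295, 12, 376),
    ("Chad", 2014, 10601, 21, 3243),
    ("Comoros", 2012, 1851, 3, 902),
    ("DR Congo", 2013, 9862, 11, 4656),
    ("Cote d'Ivoire", 2021, 4499, 14, 177),
    ("Ethiopia", 2016, 7532, 11, 2379),
    ("Gabon", 2019, 3189, 11, 434),
    ("Gambia", 2019, 5045, 8, 218),
    ("Ghana", 2022, 4115, 16, 1589),
    ("Guinea", 2018, 5134, 8, 156),
    ("Kenya", 2022, 7857, 47, 339),
    ("Lesotho", 2014, 2153, 10, 1610),
    ("Liberia", 2019, 2948, 5, 811),
    ("Madagascar", 2021, 8324, 23, 192),
    ("Malawi", 2015, 12368, 3, 183),
    ("Mali", 2018, 6366, 9, 206),
    ("Mauritania", 2019, 7669, 14, 308),
    ("Mozambique", 2022, 5120, 11, 95),
    ("Namibia", 2013, 1948, 13, 1259),
    ("Niger", 2012, 7910, 8, 2593),
    ("Nigeria", 2018, 18217, 6, 3800),
    ("Rwanda", 2019, 5655, 5, 15),
    ("Senegal", 2011, 7410, 14, 165),
    ("Sierra Leone", 2019, 6308, 5, 1388),
    ("South Africa", 2016, 1460, 9, 1097),
    ("Tanzania", 2022, 5054, 30, 147),
    ("Togo", 2013, 4551, 6, 2599),
    ("Uganda", 2016, 9568, 15, 5730),
    ("Zambia", 2018, 6334, 10, 74),
    ("Zimbabwe", 2015, 9518, 10, 7260),
]

#: Sub-regional membership of the 34 study countries, following the
#: standard sub-Saharan Africa sub-regions (UN geoscheme adapted to the
#: DHS country set).
SSA_SUBREGIONS = {
    "Southern": ["Lesotho", "Namibia", "South Africa"],
    "Central": ["Angola", "Cameroon", "Chad", "DR Congo", "Gabon"],
    "East": [
        "Burundi", "Comoros", "Ethiopia", "Kenya", "Madagascar", "Malawi",
        "Mozambique", "Rwanda", "Tanzania", "Uganda", "Zambia", "Zimbabwe",
    ],
    "West": [
        "Benin", "Burkina Faso", "Cote d'Ivoire", "Gambia", "Ghana", "Guinea",
        "Liberia", "Mali", "Mauritania", "Niger", "Nigeria", "Senegal",
        "Sierra Leone", "Togo",
    ],
}


def round_half_up(x, decimals: int = 2):
    """Round half away from zero (the convention of printed survey tables).

    numpy rounds half to even; prevalence tables conventionally round
    half up, and the two differ exactly on ties such as 22.005.
    """
    x = np.asarray(x, dtype=float)
    factor = 10.0 ** decimals
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    return out if out.ndim else float(out)


def assign_survey_era(year) -> str:
    """Classify a survey year relative to the 2016 WHO guideline revision.

    Surveys fielded in 2016 or earlier measured the recommended number of
    antenatal-care contacts against the older >= 4-contact guideline;
    surveys from 2017 onwards against the revised >= 8-contact guideline.

    Parameters
    ----------
    year : int
        Four-digit survey year; must lie in [1980, 2100].

    Returns
    -------
    str
        ``"Before 2017"`` or ``"After 2017 (included)"``.
    """
    if isinstance(year, bool) or not isinstance(year, (int, np.integer)):
        raise TypeError(f"survey year must be an integer, got {year!r}")
    if not 1980 <= year <= 2100:
        raise ValueError(f"implausible survey year {year}; expected 1980..2100")
    return ERA_BEFORE if year <= 2016 else ERA_AFTER


@dataclass
class RegionTable:
    """One aggregated observation per areal unit.

    Parameters
    ----------
    df : pandas.DataFrame
        Must contain ``unit_id``, ``sample`` and ``events`` columns;
        ``country``, ``region_label`` and ``survey_year`` are optional, as
        are covariate columns (proportions in [0, 100]).  A pre-computed
        ``proportion`` column is accepted but recomputed from counts when
        both are present.
    extra : dict
        Auxiliary per-table metadata (e.g. a province-count column for
        country-level summaries).
    """

    df: pd.DataFrame
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in ("unit_id", "sample", "events") if c not in df.columns]
        if missing:
            raise ValueError(f"region table missing required column(s): {missing}")
        if df["unit_id"].duplicated().any():
            dupes = sorted(df.loc[df["unit_id"].duplicated(), "unit_id"].unique())
            raise ValueError(f"duplicate unit_id values: {dupes}")
        if (df["sample"] < 0).any() or (df["events"] < 0).any():
            raise ValueError("sample and events must be non-negative")
        bad = df.loc[df["events"] > df["sample"], "unit_id"].tolist()
        if bad:
            raise ValueError(f"events exceed sample for unit(s): {bad}")
        for name in self.covariate_names():
            col = pd.to_numeric(df[name], errors="coerce")
            if col.notna().any() and ((col < 0) | (col > 100)).any():
                raise ValueError(
                    f"covariate {name!r} has values outside [0, 100]"
                )
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def covariate_names(self) -> list[str]:
        # `y` is a direct Gaussian-scale response (synthetic scenarios),
        # not a covariate proportion
        skip = set(CORE_COLUMNS) | {"proportion", "y"} | set(self.extra)
        return [
            c for c in self.df.columns
            if c not in skip and pd.api.types.is_numeric_dtype(self.df[c])
        ]

    @property
    def proportion(self) -> np.ndarray:
        """Outcome proportion per unit on the percent scale."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return 100.0 * self.df["events"].to_numpy(float) / self.df["sample"].to_numpy(float)

    def with_era(self) -> pd.DataFrame:
        out = self.df.copy()
        out["survey_era"] = [assign_survey_era(int(y)) for y in out["survey_year"]]
        return out


def load_anc_table() -> RegionTable:
    """Packaged country-level antenatal-care utilization summary.

    Returns the most recent DHS summary for the 34 sub-Saharan African
    study countries: survey year, number of women surveyed, number of
    women who met the recommended antenatal-care contacts, and the number
    of first-level administrative provinces (carried in
    ``extra["provinces"]``, a Series indexed like the table).

    The total surveyed sample across countries is 223,155 women and the
    province counts sum to 429 areal units.
    """
    df = pd.DataFrame(
        _ANC_ROWS,
        columns=["country", "survey_year", "sample", "provinces", "events"],
    )
    region_of = {c: r for r, cs in SSA_SUBREGIONS.items() for c in cs}
    df["unit_id"] = df["country"]
    df["region_label"] = df["country"].map(region_of)
    provinces = df.pop("provinces")
    table = RegionTable(
        df[["unit_id", "country", "region_label", "survey_year", "sample", "events"]]
    )
    table.extra["provinces"] = provinces
    return table


def weighted_group_proportion(
    table: RegionTable, grouping: str = "all"
) -> pd.DataFrame:
    """Pooled outcome proportion per group, weighted by sample size.

    The group proportion is ``100 * sum(events) / sum(sample)``, i.e. the
    sample-size-weighted mean of unit proportions — the exact pooled
    prevalence, not the unweighted mean of unit percentages.

    Parameters
    ----------
    table : RegionTable
    grouping : {"all", "country", "region_label", "survey_era"}

    Returns
    -------
    pandas.DataFrame
        Columns ``group``, ``proportion`` (rounded half-up to 2 decimals)
        and ``proportion_full`` (full precision).  Groups whose summed
        sample is zero are omitted.
    """
    if len(table) == 0:
        raise ValueError("empty region table: nothing to aggregate")
    valid = {"all", "country", "region_label", "survey_era"}
    if grouping not in valid:
        raise ValueError(f"grouping must be one of {sorted(valid)}, got {grouping!r}")

    if grouping == "all":
        df = table.df.assign(_group="all")
        key = "_group"
    elif grouping == "survey_era":
        df = table.with_era()
        key = "survey_era"
    else:
        if grouping not in table.df.columns:
            raise ValueError(f"table has no {grouping!r} column")
        df = table.df
        key = grouping

    agg = df.groupby(key, sort=False, dropna=True)[["events", "sample"]].sum()
    agg = agg[agg["sample"] > 0]
    full = 100.0 * agg["events"] / agg["sample"]
    return pd.DataFrame(
        {
            "group": agg.index.astype(str),
            "proportion": round_half_up(full.to_numpy(), 2),
            "proportion_full": full.to_numpy(),
        }
    ).reset_index(drop=True)
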