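"""Per-patch-year covariates and analysis tables.

Connectivity follows the incidence function model: for focal patch i in year
t,

    S_i(t) = sum_{j != i} exp(-alpha * d_ij) * N_j(t-1),

summing over every patch occupied in the previous fall (N_j its nest count),
with Euclidean distances in km and alpha the inverse mean dispersal distance
(1/km by default).  The neighbourhood growth-rate trend is

    Ntrend_i(t) = S_i(t) - S_i(t-1).

Population trends over one or two generations classify each occupied
patch-year as declined / increased / stable from its fall nest counts, with
the two-generation rule requiring a consistent direction across both
transitions ("stable" covers fluctuation with no directionality).

``build_analysis_table`` assembles the response and covariate columns for
the three binary responses (annual extinction, overwinter extinction,
overwinter nest mortality), applies the inclusion filters (>=2 genotypes
per unit, surveys present, merged nests removed for the nest response,
trend availability for models 5-6), log-transforms nest count, area and
connectivity, and z-standardizes all continuous covariates on the final
analysis subset.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "read_patches",
    "read_survey",
    "read_nests",
    "connectivity",
    "connectivity_all_years",
    "ntrend",
    "classify_trend",
    "build_analysis_table",
    "STANDARDIZED_COLUMNS",
]

#: continuous covariates that get z-standardized copies ("<name>_z")
STANDARDIZED_COLUMNS = [
    "he",
    "log_nest_count",
    "ntrend",
    "log_area",
    "log_connectivity",
    "host_abundance",
    "prop_low_veg",
    "prop_dry",
    "prop_grazed",
]


def read_patches(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patch_id": str})
    required = {"patch_id", "x_km", "y_km", "area", "host_abundance",
                "prop_dry", "prop_low_veg", "prop_grazed"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"patches file missing columns: {sorted(missing)}")
    return df


def read_survey(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patch_id": str})
    required = {"patch_id", "year", "season", "nest_count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"survey file missing columns: {sorted(missing)}")
    bad = set(df["season"].unique()) - {"fall", "spring"}
    if bad:
        raise ValueError(f"unknown seasons in survey: {sorted(bad)}")
    return df


def read_nests(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"nest_id": str, "patch_id": str})
    required = {"nest_id", "patch_id", "year", "n_families", "survived_overwinter"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"nests file missing columns: {sorted(missing)}")
    return df


def _fall_counts(survey: pd.DataFrame, year: int) -> pd.Series:
    rows = survey[(survey["year"] == year) & (survey["season"] == "fall")]
    return rows.set_index("patch_id")["nest_count"]


def connectivity(
    patches: pd.DataFrame,
    survey: pd.DataFrame,
    year: int,
    alpha: float = 1.0,
) -> pd.DataFrame:
    """Incidence-function-model connectivity S_i for one year.

    Sources are all patches occupied in fall of ``year - 1`` (not only
    genotyped ones).  Raises if the prior-year fall survey is absent.
    """
    prev = _fall_counts(survey, year - 1)
    if prev.empty:
        raise ValueError(f"no fall survey for year {year - 1}; cannot compute connectivity")
    ids = patches["patch_id"].to_numpy()
    xy = patches[["x_km", "y_km"]].to_numpy(dtype=float)
    n = prev.reindex(ids).fillna(0.0).to_numpy(dtype=float)
    # pairwise Euclidean distances in km
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2))
    kernel = np.exp(-alpha * d)
    np.fill_diagonal(kernel, 0.0)
    s = kernel @ n
    return pd.DataFrame({"patch_id": ids, "year": year, "s_i": s})


def connectivity_all_years(
    patches: pd.DataFrame, survey: pd.DataFrame, alpha: float = 1.0
) -> pd.DataFrame:
    """S_i for every year with a prior-year fall survey."""
    years = sorted(survey.loc[survey["season"] == "fall", "year"].unique())
    out = [connectivity(patches, survey, int(y), alpha) for y in years[1:]]
    return pd.concat(out, ignore_index=True)


def ntrend(s_t: pd.DataFrame, s_tm1: pd.DataFrame) -> pd.DataFrame:
    """Ntrend_i = S_i(t) - S_i(t-1); NA where a patch is missing from either."""
    a = s_t.set_index("patch_id")["s_i"]
    b = s_tm1.set_index("patch_id")["s_i"]
    joined = pd.concat({"s_t": a, "s_tm1": b}, axis=1)
    year = int(s_t["year"].iloc[0])
    return pd.DataFrame(
        {
            "patch_id": joined.index,
            "year": year,
            "ntrend": (joined["s_t"] - joined["s_tm1"]).to_numpy(),
        }
    ).reset_index(drop=True)


def classify_trend(fall_counts: pd.DataFrame, horizon: int) -> pd.DataFrame:
    """Trend category per patch-year from fall nest counts.

    ``fall_counts`` has columns patch_id, year, nest_count (fall).  For
    horizon 1: declined iff N_t < N_{t-1}, increased iff N_t > N_{t-1},
    stable iff equal.  For horizon 2: declined/increased only if strictly
    monotone across both transitions, otherwise stable.  A patch unoccupied
    (or unsurveyed) at any required earlier time gets NA.
    """
    if horizon not in (1, 2):
        raise ValueError("horizon must be 1 or 2")
    wide = fall_counts.pivot_table(
        index="patch_id", columns="year", values="nest_count", aggfunc="first"
    )
    years = sorted(wide.columns)
    records = []
    for t in years:
        n_t = wide[t]
        prev_ok = pd.Series(True, index=wide.index)
        for k in range(1, horizon + 1):
            if t - k not in wide.columns:
                prev_ok &= False
            else:
                prev_ok &= wide[t - k].fillna(0) > 0
        if horizon == 1:
            n1 = wide.get(t - 1)
            cat = pd.Series("stable", index=wide.index, dtype=object)
            if n1 is not None:
                cat[n_t < n1] = "declined"
                cat[n_t > n1] = "increased"
        else:
            n1, n2 = wide.get(t - 1), wide.get(t - 2)
            cat = pd.Series("stable", index=wide.index, dtype=object)
            if n1 is not None and n2 is not None:
                cat[(n1 < n2) & (n_t < n1)] = "declined"
                cat[(n1 > n2) & (n_t > n1)] = "increased"
        cat[~prev_ok] = pd.NA
        records.append(
            pd.DataFrame(
                {"patch_id": wide.index, "year": t, f"trend_{horizon}gen": cat.to_numpy()}
            )
        )
    return pd.concat(records, ignore_index=True)


def _survey_wide(survey: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    fall = survey[survey["season"] == "fall"].pivot_table(
        index="patch_id", columns="year", values="nest_count", aggfunc="first"
    )
    spring = survey[survey["season"] == "spring"].pivot_table(
        index="patch_id", columns="year", values="nest_count", aggfunc="first"
    )
    return fall, spring


def build_analysis_table(
    patches: pd.DataFrame,
    survey: pd.DataFrame,
    het: pd.DataFrame,
    nests: pd.DataFrame | None,
    response: str,
    model_id: int,
    alpha: float = 1.0,
    standardize: bool = True,
) -> pd.DataFrame:
    """Assemble the filtered, standardized analysis table for one response.

    For the extinction responses rows are occupied patch-years with a
    population-level He; for nest mortality rows are single-family nests
    with a nest-level He.  Covariates (log nest count, Ntrend, log area,
    log connectivity, habitat quality scores) are attached per patch-year
    and z-standardized over the final subset.
    """
    if response not in ("annual_ext", "overwinter_ext", "nest_mortality"):
        raise ValueError(f"unknown response {response!r}")
    fall, spring = _survey_wide(survey)
    years = sorted(fall.columns)
    if len(years) < 3:
        raise ValueError("need at least 3 fall survey years")

    sy = {y: connectivity(patches, survey, y, alpha).set_index("patch_id")["s_i"]
          for y in years[1:]}

    # patch-year covariate frame: occupied patch-years with S and Ntrend
    rows = []
    for t in years[2:]:
        occ = fall[t] > 0
        for pid in fall.index[occ.fillna(False)]:
            rows.append(
                {
                    "patch_id": pid,
                    "year": t,
                    "nest_count": fall.loc[pid, t],
                    "s_i": sy[t].get(pid, np.nan),
                    "ntrend": sy[t].get(pid, np.nan) - sy[t - 1].get(pid, np.nan),
                }
            )
    base = pd.DataFrame(rows)
    if base.empty:
        raise ValueError("no occupied patch-years in the analysis window")

    # responses
    base["annual_ext"] = [
        (0 if fall.loc[pid, t + 1] > 0 else 1)
        if (t + 1 in fall.columns and not pd.isna(fall.loc[pid, t + 1]))
        else np.nan
        for pid, t in zip(base["patch_id"], base["year"])
    ]
    base["overwinter_ext"] = [
        (0 if spring.loc[pid, t] > 0 else 1)
        if (pid in spring.index and t in spring.columns and not pd.isna(spring.loc[pid, t]))
        else np.nan
        for pid, t in zip(base["patch_id"], base["year"])
    ]

    # trends
    fall_long = (
        fall.reset_index()
        .melt(id_vars="patch_id", var_name="year", value_name="nest_count")
        .dropna()
    )
    for h in (1, 2):
        tr = classify_trend(fall_long, h)
        base = base.merge(tr, on=["patch_id", "year"], how="left")

    # patch attributes
    base = base.merge(
        patches[
            ["patch_id", "area", "host_abundance", "prop_dry", "prop_low_veg", "prop_grazed"]
        ],
        on="patch_id",
        how="left",
    )

    # heterozygosity: population level for extinction, nest level for mortality
    if response == "nest_mortality":
        if nests is None:
            raise ValueError("nest mortality response requires the nest table")
        het_n = het[het["level"] == "nest"].copy()
        nest_rows = nests.merge(
            het_n[["unit_id", "he", "ho", "n_individuals"]],
            left_on="nest_id",
            right_on="unit_id",
            how="inner",
        )
        nest_rows = nest_rows[nest_rows["n_families"] == 1]  # merged nests removed
        df = nest_rows.merge(base, on=["patch_id", "year"], how="inner")
        df["nest_mortality"] = 1 - df["survived_overwinter"]
        df = df.dropna(subset=["nest_mortality"])
    else:
        het_p = het[het["level"] == "population"].copy()
        het_p["patch_id"] = het_p["unit_id"].str.split(":").str[0]
        het_p["year"] = het_p["unit_id"].str.split(":").str[1].astype(int)
        df = base.merge(
            het_p[["patch_id", "year", "he", "ho", "n_individuals"]],
            on=["patch_id", "year"],
            how="inner",
        )
        df = df.dropna(subset=[response])
        df[response] = df[response].astype(int)

    # missing-survey / covariate availability
    df = df.dropna(subset=["s_i", "ntrend", "area"])
    if model_id in (5, 6):
        df = df.dropna(subset=[f"trend_{model_id - 4}gen"])

    # transforms
    if (df["s_i"] <= 0).any():
        bad = df.loc[df["s_i"] <= 0, ["patch_id", "year"]]
        raise ValueError(
            "connectivity is zero for some patch-years; exclude them before "
            f"taking logs: {bad.to_dict('records')}"
        )
    df["log_nest_count"] = np.log(df["nest_count"].astype(float))
    df["log_area"] = np.log(df["area"].astype(float))
    df["log_connectivity"] = np.log(df["s_i"].astype(float))

    if standardize:
        for col in STANDARDIZED_COLUMNS:
            v = df[col].to_numpy(dtype=float)
            sd = v.std(ddof=0)
            df[col + "_z"] = (v - v.mean()) / sd if sd > 0 else 0.0
    df = df.reset_index(drop=True)
    return df
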