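"""Data model, CSV I/O and validation for the study tables.

A study is a long-format panel of cumulative forest loss (one row per
reserve x year, in hectares lost since the first panel year), a
reserve-level covariate table of structural deforestation drivers, a
treatment table giving each tiger reserve's intervention (gazettement)
year, and an optional carbon table with above-/belowground carbon
densities used for emissions accounting.

Conventions
-----------
* Years are integer calendar years; every reserve shares the same
  contiguous year range (2001-2020 in the motivating study).
* Cumulative loss is measured relative to the first panel year and is
  non-decreasing within each reserve.
* The pre-intervention period is years strictly before the intervention
  year; the post period includes the intervention year itself
  (gazettement takes effect within its year).
* Reserves excluded by a filter (e.g. the 2007-2015 treatment window)
  are retained with an exclusion reason; they are neither treated nor
  donors downstream, but never silently dropped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError, ValidationError

logger = logging.getLogger(__name__)

OUTCOME_COLUMNS = ["reserve_id", "year", "cumulative_loss_ha"]

#: Numeric reserve-level deforestation drivers used as matching predictors.
NUMERIC_COVARIATES = [
    "pop_density",     # persons / km^2
    "road_length",     # km of road inside the reserve
    "precipitation",   # mm / yr
    "elevation",       # m
    "slope",           # degrees
    "aspect",          # degrees
    "agb_baseline",    # Mg/ha aboveground biomass in the baseline year
    "ppp",             # local purchasing power parity, US$
    "age",             # years since oldest constituent protected area
    "travel_time",     # minutes to nearest city >50,000
    "area_ha",         # total reserve area
]
COVARIATE_COLUMNS = ["reserve_id", *NUMERIC_COVARIATES, "group"]
TREATMENT_COLUMNS = ["reserve_id", "intervention_year"]
CARBON_COLUMNS = [
    "reserve_id",
    "agb_c_density",
    "bgb_c_density",
    "agb_c_se",
    "bgb_c_se",
    "forest_cover_2010",
    "forest_cover_interv",
]


@dataclass
class StudyDataset:
    """Validated container for the four study tables.

    ``exclusions`` maps reserve_id -> human-readable reason for treated
    reserves demoted by a filter; excluded reserves are not in
    ``treated_ids`` and never enter the donor pool.
    """

    outcomes: pd.DataFrame
    covariates: pd.DataFrame
    treatments: pd.DataFrame
    carbon: pd.DataFrame | None = None
    exclusions: dict[str, str] = field(default_factory=dict)

    # -- derived views -------------------------------------------------
    @property
    def reserve_ids(self) -> list[str]:
        return sorted(self.covariates["reserve_id"])

    @property
    def start_year(self) -> int:
        return int(self.outcomes["year"].min())

    @property
    def end_year(self) -> int:
        return int(self.outcomes["year"].max())

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.end_year + 1)

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year + 1

    def intervention_year(self, reserve_id: str) -> int:
        row = self.treatments.loc[self.treatments["reserve_id"] == reserve_id]
        if row.empty or pd.isna(row["intervention_year"].iloc[0]):
            raise KeyError(f"{reserve_id!r} has no intervention year")
        return int(row["intervention_year"].iloc[0])

    @property
    def treated_ids(self) -> list[str]:
        mask = self.treatments["intervention_year"].notna()
        ids = self.treatments.loc[mask, "reserve_id"]
        return sorted(r for r in ids if r not in self.exclusions)

    @property
    def donor_ids(self) -> list[str]:
        mask = self.treatments["intervention_year"].isna()
        return sorted(self.treatments.loc[mask, "reserve_id"])

    @property
    def groups(self) -> dict[str, list[str]]:
        """Landscape-group label -> sorted reserve ids."""
        out: dict[str, list[str]] = {}
        for label, sub in self.covariates.groupby("group"):
            out[str(label)] = sorted(sub["reserve_id"])
        return out

    def group_of(self, reserve_id: str) -> str:
        sub = self.covariates.loc[self.covariates["reserve_id"] == reserve_id]
        if sub.empty:
            raise KeyError(f"unknown reserve {reserve_id!r}")
        return str(sub["group"].iloc[0])

    def group_donors(self, reserve_id: str) -> list[str]:
        """Donor reserves in the same landscape grouping as ``reserve_id``."""
        group = self.group_of(reserve_id)
        donors = set(self.donor_ids)
        return sorted(r for r in self.groups[group] if r in donors)

    def outcome_series(self, reserve_id: str) -> pd.Series:
        sub = self.outcomes.loc[self.outcomes["reserve_id"] == reserve_id]
        if sub.empty:
            raise KeyError(f"unknown reserve {reserve_id!r}")
        return sub.set_index("year")["cumulative_loss_ha"].sort_index()

    def outcome_matrix(self, reserve_ids: list[str] | None = None) -> pd.DataFrame:
        """Year x reserve matrix of cumulative loss (hectares)."""
        wide = self.outcomes.pivot(
            index="year", columns="reserve_id", values="cumulative_loss_ha"
        ).sort_index()
        if reserve_ids is not None:
            wide = wide[list(reserve_ids)]
        return wide

    def covariate_row(self, reserve_id: str) -> pd.Series:
        sub = self.covariates.loc[self.covariates["reserve_id"] == reserve_id]
        if sub.empty:
            raise KeyError(f"unknown reserve {reserve_id!r}")
        return sub.iloc[0]


def _check_columns(df: pd.DataFrame, expected: list[str], name: str, strict: bool) -> pd.DataFrame:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise FormatError(f"{name}: missing column(s) {missing}")
    extra = [c for c in df.columns if c not in expected]
    if extra:
        if strict:
            raise FormatError(f"{name}: unknown column(s) {extra} (use lenient=True to ignore)")
        warnings.warn(f"{name}: ignoring unknown column(s) {extra}")
    return df[expected]


def validate_study(study: StudyDataset) -> StudyDataset:
    """Assert every documented invariant; raise with the offender named."""
    out = study.outcomes
    if out.duplicated(["reserve_id", "year"]).any():
        dup = out[out.duplicated(["reserve_id", "year"])].iloc[0]
        raise ValidationError(
            f"outcomes: duplicate row for reserve {dup['reserve_id']!r} year {int(dup['year'])}"
        )

    start, end = study.start_year, study.end_year
    full = np.arange(start, end + 1)
    for rid, sub in out.groupby("reserve_id"):
        years = np.sort(sub["year"].to_numpy())
        if len(years) != len(full) or not np.array_equal(years, full):
            raise ValidationError(
                f"outcomes: reserve {rid!r} does not cover the common contiguous "
                f"year range {start}-{end}"
            )
        vals = sub.sort_values("year")["cumulative_loss_ha"].to_numpy(float)
        if vals[0] < 0:
            raise ValidationError(f"outcomes: reserve {rid!r} has negative loss at {start}")
        dec = np.nonzero(np.diff(vals) < 0)[0]
        if dec.size:
            bad_year = int(full[dec[0] + 1])
            raise ValidationError(
                f"outcomes: cumulative_loss_ha decreases for reserve {rid!r} at year {bad_year}"
            )

    cov = study.covariates
    if cov["reserve_id"].duplicated().any():
        rid = cov.loc[cov["reserve_id"].duplicated(), "reserve_id"].iloc[0]
        raise ValidationError(f"covariates: reserve {rid!r} appears more than once")
    panel_ids = set(out["reserve_id"])
    cov_ids = set(cov["reserve_id"])
    missing = panel_ids - cov_ids
    if missing:
        raise ConsistencyError(
            f"reserve(s) present in outcomes but absent from covariates: {sorted(missing)}"
        )
    if (cov["area_ha"] <= 0).any():
        rid = cov.loc[cov["area_ha"] <= 0, "reserve_id"].iloc[0]
        raise ValidationError(f"covariates: reserve {rid!r} has non-positive area_ha")
    if (cov["age"] < 0).any():
        rid = cov.loc[cov["age"] < 0, "reserve_id"].iloc[0]
        raise ValidationError(f"covariates: reserve {rid!r} has negative age")

    trt = study.treatments
    trt_ids = set(trt["reserve_id"])
    missing = panel_ids - trt_ids
    if missing:
        raise ConsistencyError(
            f"reserve(s) present in outcomes but absent from treatments: {sorted(missing)}"
        )
    treated = trt[trt["intervention_year"].notna()]
    for _, row in treated.iterrows():
        iy = int(row["intervention_year"])
        if not (start < iy < end):
            raise ValidationError(
                f"treatments: reserve {row['reserve_id']!r} intervention_year {iy} "
                f"is not strictly inside the panel range {start}-{end}"
            )

    if study.carbon is not None:
        carb = study.carbon
        unknown = set(carb["reserve_id"]) - cov_ids
        if unknown:
            raise ConsistencyError(f"carbon: unknown reserve(s) {sorted(unknown)}")
        for col in ["agb_c_density", "bgb_c_density", "agb_c_se", "bgb_c_se"]:
            if (carb[col] < 0).any():
                rid = carb.loc[carb[col] < 0, "reserve_id"].iloc[0]
                raise ValidationError(f"carbon: reserve {rid!r} has negative {col}")
        for col in ["forest_cover_2010", "forest_cover_interv"]:
            if (carb[col] <= 0).any():
                rid = carb.loc[carb[col] <= 0, "reserve_id"].iloc[0]
                raise ValidationError(f"carbon: reserve {rid!r} has non-positive {col}")
    return study


def load_study(
    outcome_path: str | Path,
    covariate_path: str | Path,
    treatment_path: str | Path,
    carbon_path: str | Path | None = None,
    lenient: bool = False,
) -> StudyDataset:
    """Read and validate the study CSVs.

    All files are UTF-8 with a header row and '.' decimal separator.
    Unknown columns are rejected unless ``lenient`` is set.
    """
    strict = not lenient
    outcomes = _check_columns(pd.read_csv(outcome_path), OUTCOME_COLUMNS, "outcomes", strict)
    outcomes = outcomes.astype(
        {"reserve_id": str, "year": int, "cumulative_loss_ha": float}
    )
    covariates = _check_columns(
        pd.read_csv(covariate_path), COVARIATE_COLUMNS, "covariates", strict
    )
    covariates = covariates.astype({"reserve_id": str, "group": str})
    covariates[NUMERIC_COVARIATES] = covariates[NUMERIC_COVARIATES].astype(float)
    treatments = _check_columns(
        pd.read_csv(treatment_path), TREATMENT_COLUMNS, "treatments", strict
    )
    treatments = treatments.astype({"reserve_id": str})
    treatments["intervention_year"] = treatments["intervention_year"].astype("Int64")
    carbon = None
    if carbon_path is not None:
        carbon = _check_columns(pd.read_csv(carbon_path), CARBON_COLUMNS, "carbon", strict)
        carbon = carbon.astype({"reserve_id": str})
    study = StudyDataset(outcomes, covariates, treatments, carbon)
    return validate_study(study)


def write_study(study: StudyDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the study tables as the canonical CSVs; returns the paths.

    Floats are written with shortest-roundtrip repr so a load/write
    cycle reproduces numeric content exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "outcomes": outdir / "outcomes.csv",
        "covariates": outdir / "covariates.csv",
        "treatments": outdir / "treatments.csv",
    }
    study.outcomes[OUTCOME_COLUMNS].to_csv(paths["outcomes"], index=False)
    study.covariates[COVARIATE_COLUMNS].to_csv(paths["covariates"], index=False)
    study.treatments[TREATMENT_COLUMNS].to_csv(paths["treatments"], index=False)
    if study.carbon is not None:
        paths["carbon"] = outdir / "carbon.csv"
        study.carbon[CARBON_COLUMNS].to_csv(paths["carbon"], index=False)
    return paths


def filter_treatment_window(
    study: StudyDataset, min_year: int, max_year: int
) -> StudyDataset:
    """Demote treated reserves whose intervention year falls outside
    [min_year, max_year].

    Excluded reserves keep their treatment record but gain an exclusion
    reason; they do not join the donor pool.
    """
    if min_year > max_year:
        raise ValueError(f"min_year {min_year} > max_year {max_year}")
    exclusions = dict(study.exclusions)
    n_before = len(study.treated_ids)
    for rid in study.treated_ids:
        iy = study.intervention_year(rid)
        if not (min_year <= iy <= max_year):
            exclusions[rid] = (
                f"intervention_year {iy} outside treatment window "
                f"[{min_year}, {max_year}]"
            )
    filtered = replace(study, exclusions=exclusions)
    n_excluded = n_before - len(filtered.treated_ids)
    logger.info(
        "treatment window [%d, %d]: excluded %d of %d treated reserves",
        min_year, max_year, n_excluded, n_before,
    )
    if n_before and not filtered.treated_ids:
        warnings.warn(
            f"treatment window [{min_year}, {max_year}] excluded every treated reserve"
        )
    return filtered
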