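"""Carbon accounting: averted forest loss -> avoided CO2e -> value.

Averted hectares (counterfactual minus observed cumulative loss) are
converted to avoided emissions using reserve-specific above- and
belowground carbon densities (tC/ha, reference year 2010, scaled to
the intervention year by the forest-cover ratio), the 44/12 molar
emissions factor of 3.67 tCO2e/tC, and a 10-year linear decay of the
belowground pool: forest lost ``a`` years before the evaluation year
has released the fraction min(1, a/10) of its belowground carbon.

Avoided emissions are valued two ways: at the social cost of carbon
for India (US$86/tCO2e) and at the voluntary-carbon-market offset
price (US$5.8/tCO2e), both reported in thousand US$.  Uncertainty is
propagated as |averted ha| x 3.67 x (AGB SE + BGB SE) — additive over
the two pools and, at the portfolio level, additive over signed
hectares, so the net uncertainty is the gains-side minus the
losses-side uncertainty.

Negative effects (reserves losing more forest than their
counterfactual) flow through the same formulas and appear as damages /
foregone revenue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ConfigError


@dataclass(frozen=True)
class PriceConfig:
    """Prices and conversion constants (all strictly positive).

    scc_price : social cost of carbon, US$/tCO2e (86 for India).
    offset_price : voluntary-market carbon price, US$/tCO2e (5.8).
    emissions_factor : tCO2e per tC (44/12 ~ 3.67).
    bgb_decay_years : linear-decay horizon of the belowground pool.
    """

    scc_price: float = 86.0
    offset_price: float = 5.8
    emissions_factor: float = 3.67
    bgb_decay_years: float = 10.0

    def __post_init__(self):
        if min(self.scc_price, self.offset_price,
               self.emissions_factor, self.bgb_decay_years) <= 0:
            raise ConfigError("PriceConfig values must all be > 0")


@dataclass
class CarbonAccount:
    """Avoided emissions and valuation for one reserve.

    averted_ha may be negative for underperforming reserves; every
    downstream quantity then carries the same sign.  Monetary fields
    are thousand US$.
    """

    reserve_id: str
    intervention_year: int | None
    averted_ha: float
    avoided_tco2e: float
    avoided_tco2e_uncertainty: float
    agb_component_tco2e: float
    bgb_component_tco2e: float
    agb_uncertainty_tco2e: float
    bgb_uncertainty_tco2e: float
    scc_value_kusd: float
    offset_value_kusd: float
    scc_value_uncertainty_kusd: float
    offset_value_uncertainty_kusd: float

    def to_row(self) -> dict:
        return {
            "reserve_id": self.reserve_id,
            "treatment_year": self.intervention_year,
            "averted_ha": self.averted_ha,
            "avoided_ktco2e": self.avoided_tco2e / 1e3,
            "avoided_ktco2e_unc": self.avoided_tco2e_uncertainty / 1e3,
            "scc_kusd": round(self.scc_value_kusd, 2),
            "scc_kusd_unc": round(self.scc_value_uncertainty_kusd, 2),
            "offset_kusd": round(self.offset_value_kusd, 2),
            "offset_kusd_unc": round(self.offset_value_uncertainty_kusd, 2),
        }


def scale_density(density_2010: float, cover_2010: float, cover_interv: float) -> float:
    """Scale a year-2010 carbon density (tC/ha) to the intervention year
    proportionally to the forest-cover ratio."""
    if cover_2010 <= 0 or cover_interv <= 0:
        raise ValueError("forest covers must be > 0")
    if density_2010 < 0:
        raise ValueError("density must be >= 0")
    return density_2010 * cover_interv / cover_2010


def annual_increments(effect_cumulative: pd.Series) -> pd.Series:
    """Per-year increments of a cumulative effect series (first year
    keeps its own cumulative value)."""
    s = effect_cumulative.sort_index().astype(float)
    return s.diff().fillna(s.iloc[0])


def terminal_effect_series(
    averted_ha: float, intervention_year: int, eval_year: int
) -> pd.Series:
    """Cumulative effect series for the fallback case where only a
    terminal averted-hectare figure is known: the total is spread
    uniformly over the post-intervention years."""
    if eval_year < intervention_year:
        raise ValueError("eval_year precedes intervention_year")
    years = np.arange(intervention_year, eval_year + 1)
    per_year = averted_ha / len(years)
    return pd.Series(per_year * np.arange(1, len(years) + 1), index=years)


def avoided_emissions(
    effect_increments: pd.Series,
    agb_density: float,
    bgb_density: float,
    eval_year: int,
    prices: PriceConfig = PriceConfig(),
) -> tuple[float, float]:
    """Convert annual averted-hectare increments to (AGB, BGB) tCO2e.

    ``effect_increments`` is indexed by year and holds the annual
    counterfactual-minus-observed hectares; densities are tC/ha already
    scaled to the intervention year.  The AGB pool is counted in full;
    the BGB pool is counted as the fraction of its 10-year linear decay
    elapsed by ``eval_year``.
    """
    years = np.asarray(effect_increments.index, int)
    if years.size and eval_year < years.min():
        raise ValueError(f"eval_year {eval_year} precedes the first effect year")
    delta = effect_increments.to_numpy(float)
    ef = prices.emissions_factor
    agb = float(np.sum(delta * agb_density * ef))
    decay = np.minimum(1.0, (eval_year - years) / prices.bgb_decay_years)
    decay = np.maximum(decay, 0.0)
    bgb = float(np.sum(delta * bgb_density * ef * decay))
    return agb, bgb


def emissions_uncertainty(
    averted_ha: float,
    agb_se: float,
    bgb_se: float,
    emissions_factor: float = 3.67,
) -> float:
    """Additive SE combination: |ha| x EF x (AGB SE + BGB SE), tCO2e."""
    return abs(averted_ha) * emissions_factor * (agb_se + bgb_se)


def value_emissions(avoided_tco2e: float, price_per_t: float) -> float:
    """Monetary value in thousand US$."""
    if price_per_t <= 0:
        raise ValueError("price must be > 0")
    return avoided_tco2e * price_per_t / 1e3


def account_for_reserve(
    reserve_id: str,
    effect_cumulative: pd.Series,
    carbon_record: pd.Series,
    intervention_year: int,
    eval_year: int | None = None,
    prices: PriceConfig = PriceConfig(),
) -> CarbonAccount:
    """Full carbon account for one reserve from its cumulative effect
    series (year -> counterfactual minus observed, hectares) and its
    carbon table row.

    Densities and their standard errors are scaled from 2010 to the
    intervention year by the forest-cover ratio.  Only post-intervention
    increments (intervention year onwards) enter the account.
    """
    if eval_year is None:
        eval_year = int(effect_cumulative.index.max())
    ratio_years = (
        carbon_record["forest_cover_interv"],
        carbon_record["forest_cover_2010"],
    )
    agb_d = scale_density(float(carbon_record["agb_c_density"]), ratio_years[1], ratio_years[0])
    bgb_d = scale_density(float(carbon_record["bgb_c_density"]), ratio_years[1], ratio_years[0])
    agb_se = scale_density(float(carbon_record["agb_c_se"]), ratio_years[1], ratio_years[0])
    bgb_se = scale_density(float(carbon_record["bgb_c_se"]), ratio_years[1], ratio_years[0])

    post = effect_cumulative.loc[effect_cumulative.index >= intervention_year]
    increments = annual_increments(effect_cumulative).loc[post.index]
    averted_ha = float(effect_cumulative.loc[eval_year])
    agb_t, bgb_t = avoided_emissions(increments, agb_d, bgb_d, eval_year, prices)
    total = agb_t + bgb_t
    ef = prices.emissions_factor
    agb_unc = abs(averted_ha) * ef * agb_se
    bgb_unc = abs(averted_ha) * ef * bgb_se
    unc = agb_unc + bgb_unc
    return CarbonAccount(
        reserve_id=reserve_id,
        intervention_year=intervention_year,
        averted_ha=averted_ha,
        avoided_tco2e=total,
        avoided_tco2e_uncertainty=unc,
        agb_component_tco2e=agb_t,
        bgb_component_tco2e=bgb_t,
        agb_uncertainty_tco2e=agb_unc,
        bgb_uncertainty_tco2e=bgb_unc,
        scc_value_kusd=value_emissions(total, prices.scc_price),
        offset_value_kusd=value_emissions(total, prices.offset_price),
        scc_value_uncertainty_kusd=value_emissions(unc, prices.scc_price),
        offset_value_uncertainty_kusd=value_emissions(unc, prices.offset_price),
    )


@dataclass
class PortfolioSummary:
    """Gains (positive effects), losses (negative, reported as
    magnitudes) and nets, aggregated over reserves."""

    n_accounts: int = 0
    gains_ha: float = 0.0
    losses_ha: float = 0.0
    gains_tco2e: float = 0.0
    losses_tco2e: float = 0.0
    gains_scc_kusd: float = 0.0
    losses_scc_kusd: float = 0.0
    gains_offset_kusd: float = 0.0
    losses_offset_kusd: float = 0.0
    gains_unc_tco2e: float = 0.0
    losses_unc_tco2e: float = 0.0
    reserve_ids: list[str] = field(default_factory=list)

    @property
    def net_ha(self) -> float:
        return self.gains_ha - self.losses_ha

    @property
    def net_tco2e(self) -> float:
        return self.gains_tco2e - self.losses_tco2e

    @property
    def net_scc_kusd(self) -> float:
        return self.gains_scc_kusd - self.losses_scc_kusd

    @property
    def net_offset_kusd(self) -> float:
        return self.gains_offset_kusd - self.losses_offset_kusd

    @property
    def net_unc_tco2e(self) -> float:
        # signed-additive propagation: losses offset gains-side uncertainty
        return self.gains_unc_tco2e - self.losses_unc_tco2e

    def net_unc_value_kusd(self, price_per_t: float) -> float:
        return value_emissions(self.net_unc_tco2e, price_per_t)

    def to_dict(self, prices: PriceConfig = PriceConfig()) -> dict:
        return {
            "n_accounts": self.n_accounts,
            "reserve_ids": self.reserve_ids,
            "gains": {
                "ha": self.gains_ha,
                "tco2e": self.gains_tco2e,
                "tco2e_uncertainty": self.gains_unc_tco2e,
                "scc_kusd": round(self.gains_scc_kusd, 2),
                "offset_kusd": round(self.gains_offset_kusd, 2),
            },
            "losses": {
                "ha": self.losses_ha,
                "tco2e": self.losses_tco2e,
                "tco2e_uncertainty": self.losses_unc_tco2e,
                "scc_kusd": round(self.losses_scc_kusd, 2),
                "offset_kusd": round(self.losses_offset_kusd, 2),
            },
            "net": {
                "ha": self.net_ha,
                "tco2e": self.net_tco2e,
                "tco2e_uncertainty": self.net_unc_tco2e,
                "scc_kusd": round(self.net_scc_kusd, 2),
                "offset_kusd": round(self.net_offset_kusd, 2),
                "scc_kusd_uncertainty": round(
                    self.net_unc_value_kusd(prices.scc_price), 2
                ),
                "offset_kusd_uncertainty": round(
                    self.net_unc_value_kusd(prices.offset_price), 2
                ),
            },
        }


def aggregate_portfolio(
    accounts: list[CarbonAccount],
    significance_flags: dict[str, bool] | None = None,
) -> PortfolioSummary:
    """Aggregate reserve accounts into a portfolio summary.

    When ``significance_flags`` is given, only reserves flagged True
    are aggregated (the convention of reporting only reserves whose
    placebo test was significant).  An empty account list yields an
    all-zero summary.
    """
    summary = PortfolioSummary()
    for acc in accounts:
        if significance_flags is not None and not significance_flags.get(
            acc.reserve_id, False
        ):
            continue
        summary.n_accounts += 1
        summary.reserve_ids.append(acc.reserve_id)
        if acc.averted_ha >= 0:
            summary.gains_ha += acc.averted_ha
            summary.gains_tco2e += acc.avoided_tco2e
            summary.gains_scc_kusd += acc.scc_value_kusd
            summary.gains_offset_kusd += acc.offset_value_kusd
            summary.gains_unc_tco2e += acc.avoided_tco2e_uncertainty
        else:
            summary.losses_ha += -acc.averted_ha
            summary.losses_tco2e += -acc.avoided_tco2e
            summary.losses_scc_kusd += -acc.scc_value_kusd
            summary.losses_offset_kusd += -acc.offset_value_kusd
            summary.losses_unc_tco2e += acc.avoided_tco2e_uncertainty
    return summary


def load_reference_table() -> pd.DataFrame:
    """Packaged reference table of published per-reserve avoided
    deforestation results (averted hectares, avoided emissions in
    ktCO2e with uncertainty, and both valuations in thousand US$) for
    the 11 reserves with significant avoided deforestation; used as a
    regression fixture for the valuation arithmetic."""
    with resources.files("tigersynth.data").joinpath("reference_accounts.csv").open() as fh:
        return pd.read_csv(fh)
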