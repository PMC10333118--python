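"""Study-level orchestration and summary reporting.

``run_pipeline`` composes the stages in analysis order: load ->
treatment-window filter -> per-reserve synthetic-control fit -> placebo
inference -> anticipation exclusion -> donor-pool trimming with
concordance scoring -> carbon accounting -> portfolio aggregation.
Machine-readable outputs (report.json, effects.csv, carbon.csv,
robustness.csv) are written to the output directory; progress is
logged to stderr only.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .carbon import CarbonAccount, PortfolioSummary, PriceConfig, account_for_reserve, aggregate_portfolio
from .errors import TigersynthError
from .inference import bootstrap_group_test, placebo_distribution
from .panel import StudyDataset, filter_treatment_window, load_study
from .robustness import anticipation_check, concordance, trim_donor_pool, verdicts_to_frame
from .synth import SynthConfig

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline configuration; defaults are the study's constants.

    The treatment window keeps interventions with at least six training
    years and an adequate post period (2007-2015); trims refit with
    donors at least 1/10 and 1/4 of the treated area; the backdated
    pseudo-intervention year is 2005.
    """

    outcomes: str = "outcomes.csv"
    covariates: str = "covariates.csv"
    treatments: str = "treatments.csv"
    carbon: str | None = None       # carbon accounting skipped when absent
    window: tuple[int, int] = (2007, 2015)
    min_placebos: int = 20
    alpha: float = 0.05
    trim_factors: tuple[float, ...] = (0.1, 0.25)
    bootstrap_iterations: int = 9999
    pseudo_year: int = 2005
    prices: PriceConfig = field(default_factory=PriceConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)
    seed: int = 0
    outdir: str = "results"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["window"] = list(self.window)
        d["trim_factors"] = list(self.trim_factors)
        return d


def summarize_losses(study: StudyDataset) -> dict:
    """Descriptive totals and per-reserve means of cumulative loss.

    Per-year average is total loss divided by the number of panel
    years; group means carry t-distribution 95% confidence intervals
    (undefined, reported as None, for groups with fewer than 2
    reserves).
    """
    final = study.outcome_matrix().iloc[-1]
    treated = set(study.treated_ids)
    donors = set(study.donor_ids)
    excluded = set(study.exclusions)

    def group_stats(ids: set[str]) -> dict:
        vals = final[final.index.isin(ids)].to_numpy(float)
        n = len(vals)
        out = {"n": n, "total_ha": float(vals.sum()) if n else 0.0}
        if n >= 2:
            mean = float(vals.mean())
            half = float(
                stats.t.ppf(0.975, n - 1) * vals.std(ddof=1) / math.sqrt(n)
            )
            out.update(mean_ha=mean, ci95=[mean - half, mean + half])
        elif n == 1:
            out.update(mean_ha=float(vals[0]), ci95=None)
        else:
            out.update(mean_ha=0.0, ci95=None)
        return out

    total = float(final.sum())
    n_years = study.n_years
    by_group = {
        "treated": group_stats(treated),
        "donor": group_stats(donors),
        "excluded": group_stats(excluded),
    }
    shares = {
        k: (100.0 * v["total_ha"] / total if total > 0 else 0.0)
        for k, v in by_group.items()
    }
    return {
        "n_reserves": len(final),
        "panel_years": [study.start_year, study.end_year],
        "total_loss_ha": total,
        "per_year_loss_ha": total / n_years,
        "groups": by_group,
        "group_share_pct": shares,
    }


@dataclass
class ReserveResult:
    treated_id: str
    intervention_year: int
    effect_final: float
    mspe_pre: float
    mspe_post: float
    mspe_ratio: float
    p_value: float
    n_placebos: int
    cannot_reach_alpha: bool
    significant: bool
    anticipation_excluded: bool = False
    anticipation_p: float = math.nan
    excluded_reason: str = ""


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full evaluation; returns the study report dict and
    writes report.json / effects.csv / carbon.csv / robustness.csv."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    logger.info("loading study tables")
    try:
        study = load_study(cfg.outcomes, cfg.covariates, cfg.treatments, cfg.carbon)
    except FileNotFoundError as exc:
        raise TigersynthError(f"stage load: missing input file {exc.filename!r}") from exc

    study = filter_treatment_window(study, *cfg.window)
    summary = summarize_losses(study)

    results: list[ReserveResult] = []
    accounts: list[CarbonAccount] = []
    verdicts = []
    carbon_by_id = (
        study.carbon.set_index("reserve_id") if study.carbon is not None else None
    )

    for i, rid in enumerate(study.treated_ids, 1):
        iy = study.intervention_year(rid)
        logger.info("reserve %s (%d/%d): placebo inference", rid, i, len(study.treated_ids))
        ensemble = placebo_distribution(
            study, rid, config=cfg.synth, min_placebos=cfg.min_placebos,
            keep_fits=True,
        )
        fit = ensemble.fits[rid]
        significant = (not ensemble.cannot_reach_alpha) and ensemble.p_value < cfg.alpha
        res = ReserveResult(
            treated_id=rid,
            intervention_year=iy,
            effect_final=fit.effect_final,
            mspe_pre=fit.mspe_pre,
            mspe_post=fit.mspe_post,
            mspe_ratio=ensemble.treated_ratio,
            p_value=ensemble.p_value,
            n_placebos=ensemble.n_placebos,
            cannot_reach_alpha=ensemble.cannot_reach_alpha,
            significant=significant,
        )

        if significant:
            logger.info("reserve %s: anticipation check (pseudo %d)", rid, cfg.pseudo_year)
            ant = anticipation_check(
                study, rid, cfg.pseudo_year, config=cfg.synth,
                alpha=cfg.alpha, min_placebos=cfg.min_placebos,
            )
            res.anticipation_p = ant.p_value
            res.anticipation_excluded = ant.excluded
            if ant.excluded:
                res.significant = False
                res.excluded_reason = f"anticipation effect (p={ant.p_value:.4f})"

        if res.significant:
            trimmed: dict[float, tuple[float, float, int]] = {}
            for factor in cfg.trim_factors:
                pool = trim_donor_pool(study, rid, factor)
                if len(pool) < 2:
                    logger.info("reserve %s: trim %.2f leaves <2 donors, skipped", rid, factor)
                    continue
                trim_cfg = (
                    cfg.synth
                    if len(pool) >= cfg.synth.min_donors
                    else SynthConfig(
                        **{**asdict(cfg.synth), "allow_small_donor_pool": True}
                    )
                )
                tens = placebo_distribution(
                    study, rid, donor_ids=pool, config=trim_cfg,
                    min_placebos=cfg.min_placebos, keep_fits=True,
                )
                trimmed[factor] = (
                    tens.fits[rid].effect_final, tens.p_value, tens.n_placebos
                )
            verdicts.append(
                concordance(
                    rid, fit.effect_final, ensemble.p_value, trimmed,
                    alpha=cfg.alpha, min_placebos=cfg.min_placebos,
                    anticipation_excluded=res.anticipation_excluded,
                )
            )
            if carbon_by_id is not None and rid in carbon_by_id.index:
                effect = pd.Series(fit.effect_series, index=fit.years)
                accounts.append(
                    account_for_reserve(
                        rid, effect, carbon_by_id.loc[rid], iy, prices=cfg.prices
                    )
                )
        results.append(res)

    portfolio = aggregate_portfolio(accounts)

    sig_mspe = [r.mspe_pre for r in results if r.significant]
    insig_mspe = [r.mspe_pre for r in results if not r.significant]
    fit_comparison = None
    if sig_mspe and insig_mspe:
        fit_comparison = {
            "n_significant": len(sig_mspe),
            "n_insignificant": len(insig_mspe),
            "p_value": bootstrap_group_test(
                np.array(sig_mspe), np.array(insig_mspe),
                iterations=cfg.bootstrap_iterations, seed=cfg.seed,
            ),
            "iterations": cfg.bootstrap_iterations,
        }

    effects = pd.DataFrame([asdict(r) for r in results])
    effects.to_csv(outdir / "effects.csv", index=False)
    carbon_df = pd.DataFrame([a.to_row() for a in accounts])
    carbon_df.to_csv(outdir / "carbon.csv", index=False)
    robustness_df = verdicts_to_frame(verdicts)
    robustness_df.to_csv(outdir / "robustness.csv", index=False)

    report = {
        "version": __version__,
        "config": cfg.to_dict(),
        "loss_summary": summary,
        "n_treated": len(study.treated_ids),
        "n_donors": len(study.donor_ids),
        "n_excluded_by_window": len(study.exclusions),
        "reserves": [
            {
                k: (None if isinstance(v, float) and math.isnan(v) else v)
                for k, v in asdict(r).items()
            }
            for r in results
        ],
        "pre_mspe_group_comparison": fit_comparison,
        "portfolio": portfolio.to_dict(cfg.prices),
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=_json_default))
    logger.info("report written to %s", outdir / "report.json")
    return report


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def portfolio_from_report(report: dict) -> PortfolioSummary:
    """Rebuild a PortfolioSummary object from a written report dict."""
    p = report["portfolio"]
    s = PortfolioSummary()
    s.n_accounts = p["n_accounts"]
    s.reserve_ids = list(p["reserve_ids"])
    s.gains_ha = p["gains"]["ha"]
    s.losses_ha = p["losses"]["ha"]
    s.gains_tco2e = p["gains"]["tco2e"]
    s.losses_tco2e = p["losses"]["tco2e"]
    s.gains_scc_kusd = p["gains"]["scc_kusd"]
    s.losses_scc_kusd = p["losses"]["scc_kusd"]
    s.gains_offset_kusd = p["gains"]["offset_kusd"]
    s.losses_offset_kusd = p["losses"]["offset_kusd"]
    s.gains_unc_tco2e = p["gains"]["tco2e_uncertainty"]
    s.losses_unc_tco2e = p["losses"]["tco2e_uncertainty"]
    return s
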