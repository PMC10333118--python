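"""Robustness battery: anticipation backdating, area-based donor
trimming, and concordance scoring of trimmed refits.

Anticipation check: reserves may have responded before the official
gazettement year (e.g. once the national authority was constituted in
2005).  The pre-intervention window is split into a training period
(years before the backdated pseudo-intervention) and a testing period
(pseudo year up to, excluding, the true intervention year); a reserve
whose backdated placebo test comes out significant is excluded as
anticipating.

Donor trimming: treated reserves tend to be larger than donors, so the
main results are refit with donor pools restricted to reserves at
least 1/10 (and, more conservatively, 1/4) of the treated area, and the
refits scored for direction, +/-20% magnitude and significance
concordance with the untrimmed result.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import pandas as pd

from .inference import PlaceboEnsemble, placebo_distribution
from .panel import StudyDataset
from .synth import SynthConfig


@dataclass
class AnticipationResult:
    treated_id: str
    pseudo_year: int
    p_value: float              # NaN when the check was skipped
    excluded: bool
    skipped: bool = False
    reason: str = ""
    ensemble: PlaceboEnsemble | None = None


@dataclass
class TrimOutcome:
    factor: float
    n_donors: int
    effect_final: float
    p_value: float
    direction_match: bool
    within_20pct: bool
    still_significant: bool | None   # None = not assessable (<=20 donors)


@dataclass
class RobustnessVerdict:
    treated_id: str
    effect_full: float
    p_full: float
    anticipation_excluded: bool = False
    trim_results: dict[float, TrimOutcome] = field(default_factory=dict)

    def to_records(self) -> list[dict]:
        rows = []
        for factor, t in sorted(self.trim_results.items()):
            rows.append(
                {
                    "treated_id": self.treated_id,
                    "trim_factor": factor,
                    "n_donors": t.n_donors,
                    "effect_full_ha": self.effect_full,
                    "effect_trimmed_ha": t.effect_final,
                    "p_value": t.p_value,
                    "direction_match": t.direction_match,
                    "within_20pct": t.within_20pct,
                    "still_significant": (
                        "not_assessable" if t.still_significant is None
                        else bool(t.still_significant)
                    ),
                    "anticipation_excluded": self.anticipation_excluded,
                }
            )
        return rows


def trim_donor_pool(
    study: StudyDataset,
    treated_id: str,
    factor: float,
    donor_ids: list[str] | None = None,
) -> list[str]:
    """Donors whose area is at least ``factor`` times the treated area
    (inclusive boundary: 'at least a tenth' means >=)."""
    if not 0 <= factor <= 1:
        raise ValueError(f"factor must be in [0, 1], got {factor}")
    if donor_ids is None:
        donor_ids = study.group_donors(treated_id)
    treated_area = float(study.covariate_row(treated_id)["area_ha"])
    areas = study.covariates.set_index("reserve_id")["area_ha"]
    return sorted(
        rid for rid in donor_ids if float(areas[rid]) >= factor * treated_area
    )


def anticipation_check(
    study: StudyDataset,
    treated_id: str,
    pseudo_year: int,
    config: SynthConfig = SynthConfig(),
    alpha: float = 0.05,
    min_placebos: int = 20,
    donor_ids: list[str] | None = None,
) -> AnticipationResult:
    """Backdated pseudo-intervention test confined to the true
    pre-intervention window.

    The panel is truncated to years strictly before the true
    intervention year, so the genuine post-intervention response never
    contaminates the check; the synthetic control trains on years
    before ``pseudo_year`` and is evaluated on the pseudo-post years.
    ``excluded`` is True when the backdated placebo p-value is below
    ``alpha``.
    """
    true_year = study.intervention_year(treated_id)
    if pseudo_year >= true_year:
        raise ValueError(
            f"pseudo_year {pseudo_year} must precede the true intervention "
            f"year {true_year}"
        )
    n_train = pseudo_year - study.start_year
    if n_train < config.min_pre_years:
        warnings.warn(
            f"{treated_id!r}: only {n_train} year(s) before pseudo_year "
            f"{pseudo_year}; anticipation check skipped"
        )
        return AnticipationResult(
            treated_id, pseudo_year, math.nan, excluded=False, skipped=True,
            reason=f"only {n_train} pre-pseudo years",
        )
    if pseudo_year >= true_year - 1:
        warnings.warn(
            f"{treated_id!r}: no testing years between pseudo_year and the "
            "true intervention; anticipation check skipped"
        )
        return AnticipationResult(
            treated_id, pseudo_year, math.nan, excluded=False, skipped=True,
            reason="empty testing window",
        )

    truncated = replace(
        study,
        outcomes=study.outcomes.loc[study.outcomes["year"] < true_year].copy(),
    )
    ensemble = placebo_distribution(
        truncated,
        treated_id,
        donor_ids=donor_ids,
        intervention_year=pseudo_year,
        config=config,
        min_placebos=min_placebos,
    )
    excluded = ensemble.p_value < alpha
    return AnticipationResult(
        treated_id, pseudo_year, ensemble.p_value, excluded=excluded,
        ensemble=ensemble,
    )


def _sign(x: float) -> int:
    return 0 if x == 0 else (1 if x > 0 else -1)


def concordance(
    treated_id: str,
    effect_full: float,
    p_full: float,
    trimmed: dict[float, tuple[float, float, int]],
    alpha: float = 0.05,
    min_placebos: int = 20,
    anticipation_excluded: bool = False,
) -> RobustnessVerdict:
    """Score trimmed refits against the untrimmed result.

    ``trimmed`` maps trim factor -> (effect_final, p_value, n_placebos).
    ``within_20pct`` is |effect_trimmed - effect_full| <= 0.2|effect_full|
    (recorded False when effect_full is 0); ``still_significant`` is
    None (not assessable) when the trimmed pool cannot attain
    ``alpha`` (n_placebos <= 20 at the conventional 0.05).
    """
    verdict = RobustnessVerdict(
        treated_id=treated_id,
        effect_full=effect_full,
        p_full=p_full,
        anticipation_excluded=anticipation_excluded,
    )
    for factor, (effect, p, n_placebos) in trimmed.items():
        if effect_full == 0:
            within = False
        else:
            within = abs(effect - effect_full) <= 0.2 * abs(effect_full)
        significant: bool | None
        if n_placebos < min_placebos + 1:  # <=20 donors: floor above alpha
            significant = None
        else:
            significant = p < alpha
        verdict.trim_results[factor] = TrimOutcome(
            factor=factor,
            n_donors=n_placebos,
            effect_final=effect,
            p_value=p,
            direction_match=_sign(effect) == _sign(effect_full),
            within_20pct=within,
            still_significant=significant,
        )
    return verdict


def verdicts_to_frame(verdicts: list[RobustnessVerdict]) -> pd.DataFrame:
    """Flat table: one row per treated reserve x trim threshold."""
    rows: list[dict] = []
    for v in verdicts:
        rows.extend(v.to_records())
    return pd.DataFrame(rows)
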