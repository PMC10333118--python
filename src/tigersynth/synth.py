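"""The synthetic-control estimator.

For a treated reserve the counterfactual cumulative-loss trajectory is a
convex combination of donor reserves from the same landscape grouping.
Donor weights w (on the J-simplex) minimise the predictor discrepancy

    (X1 - X0 w)' diag(v) (X1 - X0 w)

for given predictor weights v (on the k-simplex); the outer problem
chooses v to minimise the mean squared prediction error (MSPE) of the
implied counterfactual over the pre-intervention years — the standard
nested synthetic-control formulation.

Predictors are the reserve-level deforestation drivers (including total
area) plus the mean pre-intervention cumulative loss, standardised to
zero mean / unit variance over the treated unit and its donors.

The inner simplex-constrained quadratic programme is solved via
non-negative least squares on a penalty-augmented system (the
sum-to-one constraint enters as a heavily weighted extra row), which is
deterministic and fast enough to sit inside placebo ensembles; the
outer search is a derivative-free Nelder-Mead over a softmax
reparameterisation of v, started at uniform v with best-so-far
tracking, so the reported pre-MSPE never exceeds the uniform-v value.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import minimize, nnls

from .errors import ConfigError, FitError, InsufficientDonorsError
from .panel import NUMERIC_COVARIATES, StudyDataset

#: floor multiplier for a degenerate (zero) pre-intervention MSPE when it
#: is used as a ratio denominator: floor = RATIO_FLOOR_SCALE * var(pre).
RATIO_FLOOR_SCALE = 1e-8


@dataclass(frozen=True)
class SynthConfig:
    """Fitting options. Defaults are the package contract.

    outer_maxiter : Nelder-Mead iteration cap for the predictor-weight
        search (500 by default; smaller budgets trade accuracy for
        speed inside large placebo ensembles).
    outer_tol : convergence tolerance on the (variance-normalised)
        outer objective.
    min_pre_years : minimum number of pre-intervention years required.
    min_donors : donor-pool size below which fitting refuses unless
        ``allow_small_donor_pool`` (21 enforces the >20-donor rule that
        makes p < 0.05 attainable in the placebo test).
    inner_penalty : relative weight of the sum-to-one row in the inner
        NNLS system.
    """

    outer_maxiter: int = 500
    outer_tol: float = 1e-8
    min_pre_years: int = 3
    min_donors: int = 21
    allow_small_donor_pool: bool = False
    inner_penalty: float = 1e6

    def __post_init__(self):
        if self.outer_maxiter < 0 or self.outer_tol <= 0 or self.min_pre_years < 1:
            raise ConfigError("invalid SynthConfig")


@dataclass
class PredictorMatrix:
    """Standardised predictor block for one treated unit and its donors."""

    predictor_names: list[str]
    x_treated: np.ndarray            # (k,)
    x_donors: np.ndarray             # (k, J)
    donor_ids: list[str]
    center: np.ndarray               # per-predictor centering constants
    scale: np.ndarray                # per-predictor scaling constants

    @property
    def k(self) -> int:
        return len(self.predictor_names)

    @property
    def n_donors(self) -> int:
        return self.x_donors.shape[1]


@dataclass
class SyntheticWeights:
    v: np.ndarray  # (k,) predictor weights on the simplex
    w: np.ndarray  # (J,) donor weights on the simplex

    def validate(self, atol: float = 1e-8) -> None:
        for name, vec in [("v", self.v), ("w", self.w)]:
            if np.any(vec < -atol):
                raise ValueError(f"{name} has negative entries")
            if abs(vec.sum() - 1.0) > atol:
                raise ValueError(f"{name} does not sum to 1 (sum={vec.sum()!r})")


@dataclass
class SyntheticFit:
    """Complete synthetic-control result for one treated unit."""

    treated_id: str
    donor_ids: list[str]
    intervention_year: int
    years: np.ndarray
    observed: np.ndarray
    counterfactual: np.ndarray
    weights: SyntheticWeights
    predictor_names: list[str]
    mspe_pre: float                 # ha^2, years strictly before intervention
    mspe_post: float                # ha^2, intervention year onwards
    pre_variance: float             # variance of treated pre-period series
    n_outer_evals: int = 0
    converged: bool = True

    @property
    def effect_series(self) -> np.ndarray:
        """Counterfactual minus observed; positive = averted loss (ha)."""
        return self.counterfactual - self.observed

    @property
    def effect_final(self) -> float:
        return float(self.effect_series[-1])

    def to_dict(self, weight_cutoff: float = 1e-4) -> dict:
        w = {
            rid: float(wi)
            for rid, wi in zip(self.donor_ids, self.weights.w)
            if wi >= weight_cutoff
        }
        return {
            "treated_id": self.treated_id,
            "intervention_year": self.intervention_year,
            "donor_weights": w,
            "predictor_weights": {
                name: float(vi)
                for name, vi in zip(self.predictor_names, self.weights.v)
            },
            "years": [int(y) for y in self.years],
            "observed": [float(x) for x in self.observed],
            "counterfactual": [float(x) for x in self.counterfactual],
            "effect": [float(x) for x in self.effect_series],
            "effect_final": self.effect_final,
            "mspe_pre": self.mspe_pre,
            "mspe_post": self.mspe_post,
        }

    def to_json(self, path: str | Path, weight_cutoff: float = 1e-4) -> None:
        Path(path).write_text(json.dumps(self.to_dict(weight_cutoff), indent=2))


def build_predictors(
    study: StudyDataset,
    unit_id: str,
    donor_ids: list[str],
    intervention_year: int,
) -> PredictorMatrix:
    """Assemble and standardise the predictor block.

    Predictors are the numeric reserve covariates plus the mean
    cumulative loss over the pre-intervention years.  Each predictor is
    centred and scaled to unit sample variance over {unit} + donors;
    predictors with no spread across the pooled units are dropped with
    a warning.
    """
    if len(donor_ids) < 2:
        raise InsufficientDonorsError(
            f"{unit_id!r}: need at least 2 donors, got {len(donor_ids)}"
        )
    donor_ids = sorted(donor_ids)
    ids = [unit_id, *donor_ids]

    cov = study.covariates.set_index("reserve_id").loc[ids, NUMERIC_COVARIATES]
    wide = study.outcome_matrix(ids)
    pre = wide.loc[wide.index < intervention_year]
    if pre.empty:
        raise FitError(f"{unit_id!r}: no pre-intervention years before {intervention_year}")
    raw = cov.to_numpy(float).T                       # (k_cov, n)
    pre_mean = pre.mean(axis=0).to_numpy(float)       # (n,)
    raw = np.vstack([raw, pre_mean])
    names = [*NUMERIC_COVARIATES, "pre_loss_mean"]

    center = raw.mean(axis=1)
    scale = raw.std(axis=1, ddof=1)
    keep = scale > 0
    dropped = [n for n, k in zip(names, keep) if not k]
    if dropped:
        warnings.warn(
            f"{unit_id!r}: dropping constant predictor(s) {dropped} "
            "(no spread across pooled units)"
        )
    raw, center, scale = raw[keep], center[keep], scale[keep]
    names = [n for n, k in zip(names, keep) if k]
    if not names:
        raise FitError(f"{unit_id!r}: every predictor is constant across units")
    std = (raw - center[:, None]) / scale[:, None]
    if not np.isfinite(std).all():
        raise FitError(f"{unit_id!r}: non-finite predictor values after scaling")
    return PredictorMatrix(
        predictor_names=names,
        x_treated=std[:, 0],
        x_donors=std[:, 1:],
        donor_ids=donor_ids,
        center=center,
        scale=scale,
    )


def inner_weights(
    pm: PredictorMatrix, v: np.ndarray, penalty: float = 1e6
) -> tuple[np.ndarray, float]:
    """Solve the inner simplex-constrained quadratic programme.

    Returns the donor weights w minimising
    ``(x1 - X0 w)' diag(v) (x1 - X0 w)`` over the simplex, and the
    attained objective value.
    """
    v = np.asarray(v, float)
    if v.shape != (pm.k,):
        raise ValueError(f"v has shape {v.shape}, expected ({pm.k},)")
    if not np.isfinite(v).all() or np.any(v < -1e-12):
        raise FloatingPointError("v must be finite and non-negative")
    if not (np.isfinite(pm.x_treated).all() and np.isfinite(pm.x_donors).all()):
        raise FloatingPointError("non-finite predictor values")

    sv = np.sqrt(np.clip(v, 0.0, None))
    A = sv[:, None] * pm.x_donors
    b = sv * pm.x_treated
    # sum-to-one constraint as a heavily weighted extra row
    mu = penalty * max(1.0, float(np.abs(A).max()))
    A_aug = np.vstack([A, np.full((1, pm.n_donors), mu)])
    b_aug = np.append(b, mu)
    w, _ = nnls(A_aug, b_aug)
    total = w.sum()
    if total <= 0:  # pragma: no cover - nnls cannot return all-zero here
        w = np.full(pm.n_donors, 1.0 / pm.n_donors)
    else:
        w = w / total
    resid = pm.x_treated - pm.x_donors @ w
    objective = float(resid @ (v * resid))
    return w, objective


def _softmax(theta: np.ndarray) -> np.ndarray:
    z = np.append(theta, 0.0)
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def fit_synthetic(
    study: StudyDataset,
    treated_id: str,
    donor_ids: list[str] | None = None,
    intervention_year: int | None = None,
    config: SynthConfig = SynthConfig(),
) -> SyntheticFit:
    """Fit the nested synthetic control for one treated reserve.

    ``donor_ids`` defaults to the donor reserves of the treated unit's
    landscape grouping; ``intervention_year`` defaults to the recorded
    treatment year.  Deterministic: fixed donor ordering (sorted ids),
    fixed uniform initialisation, no randomness.
    """
    if intervention_year is None:
        intervention_year = study.intervention_year(treated_id)
    if donor_ids is None:
        donor_ids = study.group_donors(treated_id)
    donor_ids = sorted(donor_ids)
    if len(donor_ids) < config.min_donors and not config.allow_small_donor_pool:
        raise InsufficientDonorsError(
            f"{treated_id!r}: {len(donor_ids)} donors < min_donors={config.min_donors}; "
            "set allow_small_donor_pool to override"
        )

    wide = study.outcome_matrix([treated_id, *donor_ids])
    years = wide.index.to_numpy(int)
    pre_mask = years < intervention_year
    if pre_mask.sum() < config.min_pre_years:
        raise FitError(
            f"{treated_id!r}: {int(pre_mask.sum())} pre-intervention years "
            f"< min_pre_years={config.min_pre_years}"
        )
    observed = wide[treated_id].to_numpy(float)
    Z0_all = wide[donor_ids].to_numpy(float)          # (T, J)
    z1_pre = observed[pre_mask]
    Z0_pre = Z0_all[pre_mask]

    pm = build_predictors(study, treated_id, donor_ids, intervention_year)

    pre_var = float(np.var(z1_pre))
    obj_scale = pre_var if pre_var > 0 else 1.0  # makes the search scale-free

    best: dict = {"obj": np.inf, "v": None, "w": None}
    n_evals = 0

    def outer_objective(theta: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        v = _softmax(theta)
        w, _ = inner_weights(pm, v, penalty=config.inner_penalty)
        resid = z1_pre - Z0_pre @ w
        obj = float(resid @ resid) / len(z1_pre) / obj_scale
        if obj < best["obj"]:
            best.update(obj=obj, v=v, w=w)
        return obj

    theta0 = np.zeros(pm.k - 1)
    f_uniform = outer_objective(theta0)  # baseline; best-so-far never worse
    converged = True
    if pm.k > 1 and config.outer_maxiter > 0:
        # second candidate start: v concentrated on the pre-period loss
        # predictor, whose inner match directly targets the outer
        # objective; the search starts from whichever candidate scores
        # better (the uniform baseline stays in the best-so-far record)
        start = theta0
        if "pre_loss_mean" in pm.predictor_names:
            v_pre = np.full(pm.k, 0.1 / max(pm.k - 1, 1))
            v_pre[pm.predictor_names.index("pre_loss_mean")] = 0.9
            theta_pre = np.log(v_pre[:-1] / v_pre[-1])
            if outer_objective(theta_pre) < f_uniform:
                start = theta_pre
        with np.errstate(over="ignore"):
            res = minimize(
                outer_objective,
                start,
                method="Nelder-Mead",
                options={
                    "maxiter": config.outer_maxiter,
                    "fatol": config.outer_tol,
                    "xatol": 1e-6,
                    "adaptive": pm.k > 9,
                },
            )
        converged = bool(res.success) or best["obj"] <= config.outer_tol
    if best["v"] is None:  # pragma: no cover
        raise FitError(f"{treated_id!r}: outer optimisation produced no iterate",
                       diagnostics={"n_evals": n_evals})

    weights = SyntheticWeights(v=best["v"], w=best["w"])
    weights.validate(atol=1e-6)
    counterfactual = Z0_all @ weights.w

    # convexity: the counterfactual must lie inside the donor envelope
    lo = Z0_all.min(axis=1)
    hi = Z0_all.max(axis=1)
    tol = 1e-8 * max(1.0, float(np.abs(Z0_all).max()))
    if np.any(counterfactual < lo - tol) or np.any(counterfactual > hi + tol):
        raise FitError(f"{treated_id!r}: counterfactual escapes the donor envelope")

    gap = observed - counterfactual
    mspe_pre = float(np.mean(gap[pre_mask] ** 2))
    mspe_post = float(np.mean(gap[~pre_mask] ** 2))
    return SyntheticFit(
        treated_id=treated_id,
        donor_ids=donor_ids,
        intervention_year=int(intervention_year),
        years=years,
        observed=observed,
        counterfactual=counterfactual,
        weights=weights,
        predictor_names=pm.predictor_names,
        mspe_pre=mspe_pre,
        mspe_post=mspe_post,
        pre_variance=pre_var,
        n_outer_evals=n_evals,
        converged=converged,
    )
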