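"""Placebo-based significance testing and fit diagnostics.

The placebo (in-space permutation) test refits the synthetic control
once per donor, with that donor cast as the pseudo-treated unit and the
true treated reserve added to its donor pool.  The test statistic is
the post/pre MSPE ratio; the exact permutation p-value is the
descending rank of the treated unit's ratio among all treated+placebo
ratios divided by their count, so with n placebos the attainable floor
is 1/(n+1) — hence more than 20 donors per grouping are needed before a
p-value below 0.05 is possible at all.

Also provided: a two-sample bootstrap test of equal mean pre-MSPE
between reserve groups, and covariate-balance diagnostics (pairwise
Pearson screening plus an ANOSIM permutation test on standardised
covariate distances).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .errors import FitError
from .panel import NUMERIC_COVARIATES, StudyDataset
from .synth import RATIO_FLOOR_SCALE, SynthConfig, SyntheticFit, fit_synthetic

logger = logging.getLogger(__name__)


def mspe_ratio(fit: SyntheticFit) -> float:
    """Post/pre MSPE ratio with the documented degenerate-denominator floor.

    A pre-MSPE of (numerically) zero is floored at
    ``1e-8 * var(treated pre-period series)`` (or 1e-8 if that variance
    is itself zero) so perfect pre-fits yield a large, finite ratio.
    """
    floor = RATIO_FLOOR_SCALE * (fit.pre_variance if fit.pre_variance > 0 else 1.0)
    return fit.mspe_post / max(fit.mspe_pre, floor)


def ratio_was_floored(fit: SyntheticFit) -> bool:
    floor = RATIO_FLOOR_SCALE * (fit.pre_variance if fit.pre_variance > 0 else 1.0)
    return fit.mspe_pre < floor


@dataclass
class PlaceboEnsemble:
    """MSPE ratios for the treated unit and its placebos, with the
    rank-based permutation p-value."""

    treated_id: str
    treated_ratio: float
    unit_ratios: dict[str, float]        # includes the treated unit
    p_value: float
    n_placebos: int
    cannot_reach_alpha: bool = False     # too few placebos for p < alpha
    failed_units: list[str] = field(default_factory=list)
    floored_units: list[str] = field(default_factory=list)
    fits: dict[str, SyntheticFit] | None = None

    @property
    def p_floor(self) -> float:
        return 1.0 / (self.n_placebos + 1)

    def to_dict(self) -> dict:
        return {
            "treated_id": self.treated_id,
            "treated_ratio": self.treated_ratio,
            "unit_ratios": {k: float(v) for k, v in self.unit_ratios.items()},
            "p_value": self.p_value,
            "n_placebos": self.n_placebos,
            "cannot_reach_alpha": self.cannot_reach_alpha,
            "failed_units": self.failed_units,
            "floored_units": self.floored_units,
        }


def rank_p_value(treated_ratio: float, placebo_ratios: np.ndarray) -> float:
    """Descending-rank permutation p-value, ties taking the worst rank."""
    rank = 1 + int(np.sum(placebo_ratios > treated_ratio)) \
             + int(np.sum(placebo_ratios == treated_ratio))
    return rank / (len(placebo_ratios) + 1)


def placebo_distribution(
    study: StudyDataset,
    treated_id: str,
    donor_ids: list[str] | None = None,
    intervention_year: int | None = None,
    config: SynthConfig = SynthConfig(),
    min_placebos: int = 20,
    mspe_pre_filter: float | None = None,
    keep_fits: bool = False,
) -> PlaceboEnsemble:
    """Fit the treated unit and one placebo per donor; return the ensemble.

    ``mspe_pre_filter``, when set to c, drops placebos whose pre-MSPE
    exceeds c times the treated unit's (off by default).  Placebos whose
    fit fails are recorded in ``failed_units`` and excluded from the
    rank with a warning.
    """
    if intervention_year is None:
        intervention_year = study.intervention_year(treated_id)
    if donor_ids is None:
        donor_ids = study.group_donors(treated_id)
    donor_ids = sorted(donor_ids)

    treated_fit = fit_synthetic(study, treated_id, donor_ids, intervention_year, config)
    treated_ratio = mspe_ratio(treated_fit)
    ratios: dict[str, float] = {treated_id: treated_ratio}
    pre_mspes: dict[str, float] = {treated_id: treated_fit.mspe_pre}
    floored = [treated_id] if ratio_was_floored(treated_fit) else []
    failed: list[str] = []
    fits = {treated_id: treated_fit} if keep_fits else None

    for pseudo in donor_ids:
        pool = sorted(set(donor_ids) - {pseudo} | {treated_id})
        try:
            fit = fit_synthetic(study, pseudo, pool, intervention_year, config)
        except (FitError, ValueError) as exc:
            warnings.warn(f"placebo fit failed for {pseudo!r}: {exc}")
            failed.append(pseudo)
            continue
        ratios[pseudo] = mspe_ratio(fit)
        pre_mspes[pseudo] = fit.mspe_pre
        if ratio_was_floored(fit):
            floored.append(pseudo)
        if keep_fits:
            fits[pseudo] = fit

    placebo_units = [u for u in ratios if u != treated_id]
    if mspe_pre_filter is not None:
        placebo_units = [
            u for u in placebo_units
            if pre_mspes[u] <= mspe_pre_filter * treated_fit.mspe_pre
        ]
    placebo_ratios = np.array([ratios[u] for u in placebo_units])

    n_placebos = len(placebo_ratios)
    p = rank_p_value(treated_ratio, placebo_ratios)
    cannot = n_placebos < min_placebos
    if cannot:
        warnings.warn(
            f"{treated_id!r}: only {n_placebos} placebos; the attainable p-value "
            f"floor {1 / (n_placebos + 1):.3f} cannot reach 0.05"
        )
    return PlaceboEnsemble(
        treated_id=treated_id,
        treated_ratio=treated_ratio,
        unit_ratios=ratios,
        p_value=p,
        n_placebos=n_placebos,
        cannot_reach_alpha=cannot,
        failed_units=failed,
        floored_units=floored,
        fits=fits,
    )


def minimum_donors_for_alpha(alpha: float) -> int:
    """Smallest placebo count n such that the attainable p-value floor
    1/(n+1) falls below ``alpha`` (20 at the conventional 0.05)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    n = 1
    while 1.0 / (n + 1) >= alpha:
        n += 1
    return n


def bootstrap_group_test(
    mspe_group_a: np.ndarray,
    mspe_group_b: np.ndarray,
    iterations: int = 9999,
    seed: int = 0,
) -> float:
    """Two-sample bootstrap test of equal means, resampling with
    replacement from the pooled, mean-aligned sample.

    The statistic is the studentised absolute mean difference
    (the standard two-independent-sample bootstrap hypothesis test;
    studentising keeps the test calibrated at small group sizes where
    the raw mean difference over-rejects).
    p = (1 + #{null statistic >= observed}) / (iterations + 1).
    """
    a = np.asarray(mspe_group_a, float)
    b = np.asarray(mspe_group_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")

    def tstat(xa, xb, axis=None):
        ma, mb = xa.mean(axis=axis), xb.mean(axis=axis)
        va = xa.var(ddof=1, axis=axis) / xa.shape[-1]
        vb = xb.var(ddof=1, axis=axis) / xb.shape[-1]
        return np.abs(ma - mb) / np.sqrt(np.maximum(va + vb, 1e-300))

    observed = float(tstat(a, b))
    pooled_mean = np.concatenate([a, b]).mean()
    pooled = np.concatenate([a - a.mean() + pooled_mean, b - b.mean() + pooled_mean])
    rng = np.random.default_rng(seed)
    draws_a = pooled[rng.integers(0, pooled.size, size=(iterations, a.size))]
    draws_b = pooled[rng.integers(0, pooled.size, size=(iterations, b.size))]
    null = tstat(draws_a, draws_b, axis=1)
    return float((1 + np.sum(null >= observed)) / (iterations + 1))


# ---------------------------------------------------------------------------
# covariate balance
# ---------------------------------------------------------------------------

@dataclass
class BalanceReport:
    predictor_names: list[str]
    pearson_matrix: pd.DataFrame
    flagged_pairs: list[tuple[str, str, float]]
    anosim_R: float
    anosim_p: float
    permutations: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "predictor_names": self.predictor_names,
            "pearson_matrix": self.pearson_matrix.round(6).to_dict(),
            "flagged_pairs": [
                {"a": a, "b": b, "r": float(r)} for a, b, r in self.flagged_pairs
            ],
            "anosim_R": self.anosim_R,
            "anosim_p": self.anosim_p,
            "permutations": self.permutations,
            "seed": self.seed,
        }


def _anosim_R(rank_matrix: np.ndarray, labels: np.ndarray) -> float:
    """ANOSIM statistic from a square matrix of dissimilarity ranks:
    (mean between-group rank - mean within-group rank) / (n(n-1)/4)."""
    n = len(labels)
    iu = np.triu_indices(n, 1)
    same = labels[iu[0]] == labels[iu[1]]
    r = rank_matrix[iu]
    r_within = r[same].mean()
    r_between = r[~same].mean()
    return float((r_between - r_within) / (n * (n - 1) / 4.0))


def anosim(
    X: np.ndarray,
    labels: np.ndarray,
    permutations: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Analysis of similarities on Euclidean distances of ``X`` rows.

    Returns (R, permutation p-value); R in [-1, 1], positive when
    between-group dissimilarities exceed within-group ones.
    """
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("anosim needs at least two groups")
    for lab in set(labels.tolist()):
        if np.sum(labels == lab) < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 units")
    d = pdist(np.asarray(X, float))
    ranks = squareform(rankdata(d))
    r_obs = _anosim_R(ranks, labels)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(permutations):
        perm = rng.permutation(labels)
        if _anosim_R(ranks, perm) >= r_obs:
            count += 1
    p = (1 + count) / (permutations + 1)
    return r_obs, float(p)


def balance_report(
    covariates: pd.DataFrame,
    treated_ids: list[str],
    donor_ids: list[str],
    pearson_threshold: float = 0.8,
    permutations: int = 999,
    seed: int = 0,
) -> BalanceReport:
    """Collinearity screen and treated-vs-donor ANOSIM balance test.

    Pearson correlations are computed over all units pooled; pairs at
    |r| >= threshold are flagged.  ANOSIM runs on Euclidean distances
    of the standardised covariates with a seeded permutation p-value.
    """
    ids = [*treated_ids, *donor_ids]
    if len(treated_ids) < 2 or len(donor_ids) < 2:
        raise ValueError("need at least 2 units per group")
    sub = covariates.set_index("reserve_id").loc[ids, NUMERIC_COVARIATES]
    X = sub.to_numpy(float)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = [n for n, k in zip(NUMERIC_COVARIATES, keep) if not k]
    if dropped:
        warnings.warn(f"balance_report: excluding zero-variance covariate(s) {dropped}")
    names = [n for n, k in zip(NUMERIC_COVARIATES, keep) if k]
    X = X[:, keep]
    corr = np.corrcoef(X, rowvar=False)
    corr_df = pd.DataFrame(corr, index=names, columns=names)
    flagged = [
        (names[i], names[j], float(corr[i, j]))
        for i in range(len(names))
        for j in range(i + 1, len(names))
        if abs(corr[i, j]) >= pearson_threshold
    ]
    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    labels = np.array(["treated"] * len(treated_ids) + ["donor"] * len(donor_ids))
    R, p = anosim(Xs, labels, permutations=permutations, seed=seed)
    return BalanceReport(
        predictor_names=names,
        pearson_matrix=corr_df,
        flagged_pairs=flagged,
        anosim_R=R,
        anosim_p=p,
        permutations=permutations,
        seed=seed,
    )
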