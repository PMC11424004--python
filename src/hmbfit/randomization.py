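"""Numerator-shuffling null and OO/OR/RR comparisons.

The null asks: what would rate-versus-time look like if the amount of
change carried no information about elapsed time?  Shuffling the
numerators across observations and re-dividing by the unshuffled
times/denominators preserves both marginal distributions while
destroying any true rate trend.  Comparing the coefficient of
determination of the original data under its own fit (OO), under fits
to shuffled data (OR), and of shuffled data under fits to *different*
shuffled data (RR) shows how much of the apparent pattern is
reproducible from pure noise.

p-values are percentile-based to keep the OO-OR and OR-RR comparisons
on equal sample-size footing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import RateDataset, RateObservation, apply_transform
from .errors import UndefinedStatisticError, ValidationError
from .model import HMBParameters, ModelSelection, OptimizerConfig, fit_all, predict_rate

__all__ = [
    "RandomizedReplicate",
    "ComparisonResult",
    "shuffle_numerators",
    "tree_rate_components",
    "r_squared",
    "run_comparison",
    "percentile_pvalue",
    "or_rr_pvalue",
]


def shuffle_numerators(dataset: RateDataset, seed: int | np.random.Generator = 0) -> RateDataset:
    """Shuffle numerators across observations; divide by unshuffled denominators.

    The multiset of numerators and the time vector are preserved
    exactly.  Tree-derived datasets must carry their total-branch-length
    denominators (see :func:`tree_rate_components`).
    """
    if dataset.source_kind == "tree-derived" and np.array_equal(
        dataset.denominator, dataset.time
    ):
        raise ValidationError(
            "tree-derived dataset lacks total-branch-length denominators; "
            "build observations with tree_rate_components so numerators are "
            "event counts over total branch length"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(len(dataset))
    return dataset.with_rates(dataset.numerator[perm], name=f"{dataset.name}:shuffled")


def tree_rate_components(
    n_events: float, total_branch_length: float, age: float
) -> RateObservation:
    """Observation for a tree-derived rate.

    The numerator (event count) is divided by the total branch length
    to give the rate, while the stored plotting/fitting time is the
    clade age.  For trees started from two lineages the total branch
    length can never be less than twice the age.
    """
    if age <= 0:
        raise ValidationError(f"age must be positive, got {age}")
    if total_branch_length < 2 * age * (1 - 1e-9):
        raise ValidationError(
            f"total branch length {total_branch_length} inconsistent with two "
            f"lineages over age {age}"
        )
    if n_events < 0:
        raise ValidationError("event count must be >= 0")
    rate = n_events / total_branch_length
    return RateObservation(
        numerator=float(n_events),
        time=float(age),
        rate=float(rate),
        denominator=float(total_branch_length),
    )


def r_squared(dataset: RateDataset, params: HMBParameters) -> float:
    """Coefficient of determination on the dataset's transformed scale.

    1 - SSres/SStot with SStot about the mean transformed observed
    rate.  Negative values are possible (and meaningful) for bad
    cross-fits.  Raises for constant observed rates (SStot == 0).
    """
    y = dataset.transformed_rate
    pred = predict_rate(params, dataset.time)
    pred = np.atleast_1d(np.asarray(pred, dtype=float))
    lower = 0.0 if dataset.transform == "log" else -1.0
    if np.any(pred <= lower):
        return -np.inf  # model predicts outside the transform's domain
    yhat = apply_transform(pred, dataset.transform)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise UndefinedStatisticError("R^2 undefined: observed rates are constant")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass
class RandomizedReplicate:
    replicate_id: int
    dataset: RateDataset
    selection: ModelSelection


@dataclass
class ComparisonResult:
    """R^2 values for the OO/OR/RR comparison framework."""

    r2_oo: float
    r2_or: np.ndarray  # one per replicate
    r2_rr: np.ndarray  # one per ordered pair (i, j), i != j
    rr_pairs: np.ndarray  # (n_pairs, 2) ordered (data i, fit j)
    p_oo_or: float
    p_or_rr: float
    n_rand: int

    def to_long_frame(self) -> pd.DataFrame:
        rows = [{"comparison_type": "OO", "r_squared": self.r2_oo}]
        rows += [{"comparison_type": "OR", "r_squared": v} for v in self.r2_or]
        rows += [{"comparison_type": "RR", "r_squared": v} for v in self.r2_rr]
        return pd.DataFrame(rows)


def percentile_pvalue(
    value: float, null_values: np.ndarray, form: str = "min"
) -> float:
    """Two-sided percentile p-value of ``value`` against a null sample.

    The percentile uses mid-ranks for ties and an (N+1) denominator;
    p = 2*min(q, 1-q), floored at 2/(N+1) so a value below every null
    scores the same as one above every null, and capped at 1.
    ``form="printed"`` instead returns 2*max(q, 1-q) verbatim.
    """
    nulls = np.asarray(null_values, dtype=float)
    if nulls.size == 0:
        raise ValidationError("null_values must be non-empty")
    n = nulls.size
    c = float(np.sum(nulls < value) + 0.5 * np.sum(nulls == value))
    q = c / (n + 1)
    if form == "printed":
        return 2.0 * max(q, 1.0 - q)
    if form != "min":
        raise ValidationError(f"unknown p-value form {form!r}")
    p = 2.0 * min(q, 1.0 - q)
    return float(min(1.0, max(p, 2.0 / (n + 1))))


def or_rr_pvalue(
    result: "ComparisonResult | tuple[np.ndarray, np.ndarray]",
    n_draws: int = 1000,
    seed: int = 0,
    form: str = "min",
) -> float:
    """Mean percentile p-value of random RR draws against the OR distribution.

    Averaging over ``n_draws`` draws reduces the variance from picking a
    single RR representative.
    """
    if isinstance(result, ComparisonResult):
        or_vals, rr_vals = result.r2_or, result.r2_rr
    else:
        or_vals, rr_vals = result
    or_vals = np.asarray(or_vals, dtype=float)
    rr_vals = np.asarray(rr_vals, dtype=float)
    if or_vals.size == 0 or rr_vals.size == 0:
        raise ValidationError("OR and RR collections must be non-empty")
    rng = np.random.default_rng(seed)
    draws = rng.choice(rr_vals, size=n_draws, replace=True)
    return float(np.mean([percentile_pvalue(d, or_vals, form=form) for d in draws]))


def run_comparison(
    dataset: RateDataset,
    n_rand: int = 100,
    seed: int = 0,
    config: OptimizerConfig | None = None,
    n_draws: int = 1000,
) -> ComparisonResult:
    """Full OO/OR/RR comparison with ``n_rand`` shuffled replicates.

    OO: R^2 of the original data under its own best-AIC fit.
    OR: R^2 of the original data under each replicate's best fit.
    RR: R^2 of replicate i's data under replicate j's fit, i != j
    ((n_rand - 1) * n_rand ordered pairs).
    """
    if n_rand < 2:
        raise ValidationError("n_rand must be >= 2")
    master = np.random.SeedSequence(seed)
    fit_seed, *child_seeds = master.spawn(n_rand + 1)

    original = fit_all(dataset, config=config, seed=int(fit_seed.generate_state(1)[0] % 2**31))
    r2_oo = r_squared(dataset, original.best.params)

    replicates: list[RandomizedReplicate] = []
    for i, child in enumerate(child_seeds):
        shuffle_rng = np.random.default_rng(child)
        shuffled = shuffle_numerators(dataset, shuffle_rng)
        sel = fit_all(
            shuffled, config=config, seed=int(child.generate_state(1)[0] % 2**31)
        )
        replicates.append(RandomizedReplicate(i, shuffled, sel))

    r2_or = np.array([r_squared(dataset, rep.selection.best.params) for rep in replicates])
    rr_vals, rr_pairs = [], []
    for i, rep_i in enumerate(replicates):
        for j, rep_j in enumerate(replicates):
            if i == j:
                continue
            try:
                rr_vals.append(r_squared(rep_i.dataset, rep_j.selection.best.params))
                rr_pairs.append((i, j))
            except UndefinedStatisticError:
                continue
    r2_rr = np.asarray(rr_vals)
    rr_pairs_arr = np.asarray(rr_pairs, dtype=int).reshape(-1, 2)

    p_seed = int(master.generate_state(1)[0] % 2**31)
    p_oo_or = percentile_pvalue(r2_oo, r2_or)
    p_or_rr = or_rr_pvalue((r2_or, r2_rr), n_draws=n_draws, seed=p_seed)
    return ComparisonResult(
        r2_oo=r2_oo,
        r2_or=r2_or,
        r2_rr=r2_rr,
        rr_pairs=rr_pairs_arr,
        p_oo_or=p_oo_or,
        p_or_rr=p_or_rr,
        n_rand=n_rand,
    )
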