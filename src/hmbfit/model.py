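"""The hmb model family: r(t) = h/t + m*t + b.

A rate observed over an interval t is modelled as the sum of a
hyperbolic component h/t (the signature of time-independent noise in
the numerator divided by elapsed time), a linear trend m*t, and a
constant base rate b.  Fixing any subset of {h, m, b} to zero yields
the seven nested variants (hmb, hm0, h0b, 0mb, h00, 0m0, 00b); the
simplest, 00b, is a constant rate through time as expected from a
clock-like process.

Fitting minimizes the residual sum of squares between transformed
observed and transformed predicted rates (natural log, or log1p when
zero rates are present).  The RSS converts to a log-likelihood via the
MLE of the residual variance, sigma2 = RSS/n, giving
log L = -0.5 * n * log(sigma2), and then to an AIC for model
selection.  Optimization is multi-start and derivative-free, cycling
three local methods over staged start points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .data import RateDataset, Transform, apply_transform
from .errors import FitFailureError, ValidationError

__all__ = [
    "HMBParameters",
    "ModelVariant",
    "ModelFit",
    "ModelSelection",
    "OptimizerConfig",
    "VARIANT_LABELS",
    "predict_rate",
    "objective",
    "loglik_from_rss",
    "aic",
    "enumerate_variants",
    "fit_variant",
    "fit_all",
    "loglog_slope",
]

#: Floor for sigma2 when the fit is perfect (RSS == 0).
_SIGMA2_FLOOR = 1e-300

#: Finite stand-in for an infeasible objective, for optimizers that
#: dislike inf.
_PENALTY = 1e30

VARIANT_LABELS = ("hmb", "hm0", "h0b", "0mb", "h00", "0m0", "00b")


@dataclass(frozen=True)
class HMBParameters:
    """Parameter vector of the hmb model.

    h: hyperbolic component, trait units, >= 0.
    m: linear slope, trait units per time^2, any sign.
    b: base rate, trait units per time, any sign (fitted predictions
       are kept inside the transform's domain by the objective).
    """

    h: float
    m: float
    b: float

    def __post_init__(self) -> None:
        if self.h < 0:
            raise ValidationError(f"h must be >= 0, got {self.h}")

    def as_array(self) -> np.ndarray:
        return np.array([self.h, self.m, self.b], dtype=float)


@dataclass(frozen=True)
class ModelVariant:
    """Which of {h, m, b} are free; canonical label like 'h0b'."""

    label: str
    free_h: bool
    free_m: bool
    free_b: bool

    @property
    def free_mask(self) -> np.ndarray:
        return np.array([self.free_h, self.free_m, self.free_b])

    @property
    def k(self) -> int:
        return int(self.free_h) + int(self.free_m) + int(self.free_b)

    def constrain(self, params: np.ndarray) -> np.ndarray:
        out = np.asarray(params, dtype=float).copy()
        out[~self.free_mask] = 0.0
        return out


def _variant_from_label(label: str) -> ModelVariant:
    if len(label) != 3 or label[0] not in "h0" or label[1] not in "m0" or label[2] not in "b0":
        raise ValidationError(f"unknown variant label {label!r}")
    return ModelVariant(label, label[0] == "h", label[1] == "m", label[2] == "b")


def enumerate_variants() -> tuple[ModelVariant, ...]:
    """The seven non-empty subsets of {h, m, b}, canonically labelled."""
    return tuple(_variant_from_label(lbl) for lbl in VARIANT_LABELS)


def get_variant(label: str) -> ModelVariant:
    return _variant_from_label(label)


def predict_rate(params: HMBParameters, t: float | np.ndarray) -> float | np.ndarray:
    """h/t + m*t + b; t must be strictly positive."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr <= 0):
        raise ValidationError("prediction times must be positive")
    out = params.h / t_arr + params.m * t_arr + params.b
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def _rss(theta: np.ndarray, t: np.ndarray, y: np.ndarray, transform: Transform) -> float:
    """RSS on the transformed scale; inf when the point is infeasible."""
    h, m, b = theta
    if h < 0:
        return math.inf
    pred = h / t + m * t + b
    lower = 0.0 if transform == "log" else -1.0
    if np.any(pred <= lower):
        return math.inf
    resid = y - apply_transform(pred, transform)
    return float(resid @ resid)


def objective(params: HMBParameters, dataset: RateDataset) -> float:
    """Residual sum of squares of transformed rates; inf if any
    prediction leaves the transform's domain."""
    return _rss(params.as_array(), dataset.time, dataset.transformed_rate, dataset.transform)


def loglik_from_rss(rss: float, n: int) -> float:
    """log L = -0.5 n log(sigma2) with sigma2 = RSS/n (floored near 0)."""
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    if rss < 0:
        raise ValidationError(f"rss must be >= 0, got {rss}")
    sigma2 = max(rss / n, _SIGMA2_FLOOR)
    return -0.5 * n * math.log(sigma2)


def aic(loglik: float, k: int) -> float:
    """Akaike information criterion, 2k - 2 log L."""
    if k not in (1, 2, 3):
        raise ValidationError(f"k must be in {{1, 2, 3}}, got {k}")
    return 2.0 * k - 2.0 * loglik


@dataclass(frozen=True)
class ModelFit:
    """A fitted model variant with its selection statistics."""

    variant: ModelVariant
    params: HMBParameters
    rss: float
    n: int
    transform: Transform

    @property
    def sigma2_hat(self) -> float:
        return self.rss / self.n

    @property
    def loglik(self) -> float:
        return loglik_from_rss(self.rss, self.n)

    @property
    def k(self) -> int:
        return self.variant.k

    @property
    def aic(self) -> float:
        return aic(self.loglik, self.k)

    @property
    def degenerate(self) -> bool:
        """True when the fit is (numerically) perfect and the likelihood
        rests on the sigma2 floor."""
        return self.rss / self.n < 1e-250

    def to_dict(self) -> dict:
        return {
            "variant": self.variant.label,
            "h": self.params.h,
            "m": self.params.m,
            "b": self.params.b,
            "rss": self.rss,
            "loglik": self.loglik,
            "k": self.k,
            "aic": self.aic,
            "n": self.n,
            "transform": self.transform,
        }


@dataclass
class OptimizerConfig:
    """Multi-start derivative-free search protocol.

    Stage 1 runs a fixed grid of heuristic starts, stage 2 the same grid
    rescaled, stage 3 ``n_random`` restarts drawn around the incumbent.
    Every start is polished by each method in ``methods`` in turn.
    """

    n_random: int = 20
    methods: tuple[str, ...] = ("nelder-mead", "powell", "cobyqa")
    ftol: float = 1e-10
    maxeval: int = 10_000
    bound: float = 1e6
    log_objective: bool = False  # minimize log(RSS) instead of RSS

    @classmethod
    def fast(cls) -> "OptimizerConfig":
        """Reduced-effort protocol for large batch runs."""
        return cls(n_random=4, methods=("nelder-mead", "powell"), maxeval=2000)


def _heuristic_starts(dataset: RateDataset) -> list[np.ndarray]:
    t, r = dataset.time, dataset.rate
    b0 = float(np.median(r))
    h0 = float(np.median(r * t))
    med_t = float(np.median(t))
    # OLS slope of rate on time
    tc = t - t.mean()
    denom = float(tc @ tc)
    m0 = float(tc @ (r - r.mean()) / denom) if denom > 0 else 0.0
    base = [
        np.array([h0, m0, b0]),
        np.array([h0, 0.0, b0]),
        np.array([0.0, 0.0, b0]),
        np.array([h0, 0.0, 0.0]),
        np.array([0.0, m0, b0]),
        np.array([max(h0, b0 * med_t), 0.0, 0.0]),
        np.array([0.0, b0 / med_t if med_t > 0 else 0.0, 0.0]),
        np.array([0.0, 0.0, max(float(np.mean(r)), 1e-8)]),
    ]
    return base


def _minimize_one(
    fun, x0: np.ndarray, bounds: list[tuple[float, float]], method: str, config: OptimizerConfig
):
    options: dict = {}
    if method == "nelder-mead":
        options = {"fatol": config.ftol, "xatol": 1e-12, "maxfev": config.maxeval}
    elif method == "powell":
        options = {"ftol": config.ftol, "maxfev": config.maxeval}
    elif method == "cobyqa":
        options = {"maxfev": config.maxeval}
    try:
        return optimize.minimize(fun, x0, method=method, bounds=bounds, options=options)
    except Exception:  # a method failing on one start is non-fatal
        return None


def fit_variant(
    dataset: RateDataset,
    variant: ModelVariant | str,
    config: OptimizerConfig | None = None,
    seed: int = 0,
) -> ModelFit:
    """Fit one variant by staged multi-start derivative-free search.

    The returned fit's objective is never worse than the objective at
    any tried start point.  Fixed parameters are exactly zero.  Raises
    ``FitFailureError`` when every start point is infeasible.
    """
    if isinstance(variant, str):
        variant = _variant_from_label(variant)
    config = config or OptimizerConfig()
    t = dataset.time
    y = dataset.transformed_rate
    transform = dataset.transform
    mask = variant.free_mask
    free_idx = np.flatnonzero(mask)

    def full(theta_free: np.ndarray) -> np.ndarray:
        full_theta = np.zeros(3)
        full_theta[free_idx] = theta_free
        return full_theta

    def obj_free(theta_free: np.ndarray) -> float:
        val = _rss(full(np.asarray(theta_free, dtype=float)), t, y, transform)
        if not math.isfinite(val):
            return _PENALTY
        if config.log_objective:
            return math.log(val) if val > 0 else -800.0
        return val

    bounds = []
    for i in free_idx:
        lo = 0.0 if i == 0 else -config.bound
        bounds.append((lo, config.bound))

    starts = [variant.constrain(s)[free_idx] for s in _heuristic_starts(dataset)]
    starts += [s * 0.3 for s in starts] + [s * 3.0 for s in starts]
    # dedupe
    seen: set[tuple] = set()
    stage12 = []
    for s in starts:
        key = tuple(np.round(s, 12))
        if key not in seen:
            seen.add(key)
            stage12.append(np.clip(s, [b[0] for b in bounds], [b[1] for b in bounds]))

    best_x: np.ndarray | None = None
    best_f = math.inf
    start_objs = []

    def consider(x: np.ndarray, fval: float) -> None:
        nonlocal best_x, best_f
        if fval < best_f:
            best_f, best_x = fval, np.asarray(x, dtype=float).copy()

    def polish(x0: np.ndarray) -> None:
        for method in config.methods:
            res = _minimize_one(obj_free, x0, bounds, method, config)
            if res is not None and np.all(np.isfinite(res.x)):
                consider(np.clip(res.x, [b[0] for b in bounds], [b[1] for b in bounds]),
                         obj_free(np.clip(res.x, [b[0] for b in bounds], [b[1] for b in bounds])))

    for s in stage12:
        f0 = obj_free(s)
        start_objs.append(f0)
        consider(s, f0)
        if f0 < _PENALTY:
            polish(s)

    if best_f >= _PENALTY:
        raise FitFailureError(
            f"all start points infeasible for variant {variant.label!r} "
            f"under {transform} transform"
        )

    rng = np.random.default_rng(seed)
    for _ in range(config.n_random):
        scale = 0.5 * (np.abs(best_x) + 0.05)
        x0 = best_x + rng.normal(0.0, scale)
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        consider(x0, obj_free(x0))
        polish(x0)

    theta = full(best_x)
    params = HMBParameters(*theta)
    rss = _rss(theta, t, y, transform)
    assert all(best_f <= f + 1e-12 for f in start_objs), "monotone improvement violated"
    return ModelFit(variant=variant, params=params, rss=rss, n=len(dataset), transform=transform)


@dataclass
class ModelSelection:
    """All seven variant fits ranked by AIC (ties toward fewer params)."""

    fits: list[ModelFit]
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def best(self) -> ModelFit:
        return self.fits[0]

    def within(self, delta: float = 2.0) -> list[ModelFit]:
        """Fits within ``delta`` AIC units of the best fit."""
        best_aic = self.best.aic
        return [f for f in self.fits if f.aic - best_aic <= delta]

    def to_frame(self):
        import pandas as pd

        rows = [f.to_dict() for f in self.fits]
        df = pd.DataFrame(rows)
        df["delta_aic"] = df["aic"] - df["aic"].min()
        return df


def fit_all(
    dataset: RateDataset,
    config: OptimizerConfig | None = None,
    seed: int = 0,
) -> ModelSelection:
    """Fit all seven variants; per-variant failures are recorded, not fatal."""
    fits: list[ModelFit] = []
    failures: dict[str, str] = {}
    for i, variant in enumerate(enumerate_variants()):
        try:
            fits.append(fit_variant(dataset, variant, config=config, seed=seed + i))
        except FitFailureError as exc:
            failures[variant.label] = str(exc)
    if not fits:
        raise FitFailureError(f"no variant could be fitted for dataset {dataset.name!r}")
    fits.sort(key=lambda f: (f.aic, f.k))
    return ModelSelection(fits=fits, failures=failures)


@dataclass(frozen=True)
class SlopeFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float


def loglog_slope(dataset: RateDataset, transform: Transform = "log") -> SlopeFit:
    """OLS of transformed rate on ln(time) — the slope-vs-(-1) baseline.

    A constant numerator forces a slope of exactly -1 on the log-log
    scale; departures from -1 are the baseline method's evidence of a
    genuine rate trend.  Zero rates require ``transform="log1p"``.
    """
    if transform == "log" and np.any(dataset.rate <= 0):
        raise ValidationError(
            "log-log slope undefined for zero rates; pass transform='log1p'"
        )
    x = np.log(dataset.time)
    y_vals = apply_transform(dataset.rate, transform)
    res = stats.linregress(x, y_vals)
    return SlopeFit(float(res.slope), float(res.intercept), float(res.rvalue**2),
                    float(res.pvalue))


def denoised_prediction(params: HMBParameters, t: float | np.ndarray) -> float | np.ndarray:
    """Predicted rate with the hyperbolic (noise) term deleted: m*t + b.

    May be negative; reported as-is.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr <= 0):
        raise ValidationError("prediction times must be positive")
    out = params.m * t_arr + params.b
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out
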