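"""Model fitting by basin-hopping RMSE minimisation and ensembling.

Each phenology model is fitted to observed flowering dates by minimising
the calibration RMSE with scipy's basin-hopping global optimiser.  The
objective is piecewise constant in the integer flowering day, so the
local search inside each hop is a bounded derivative-free Nelder-Mead;
the hop step of 0.5 acts on parameters standardised to their bound
ranges (every parameter scaled to [0, 1]), since the raw parameters span
incomparable magnitudes (days, degC, accumulated units).

A site-year the model cannot bring to flowering contributes a penalised
pseudo-prediction of day 365 + 100, steering the optimiser away from
degenerate corners of parameter space.

Member models are combined with normalised inverse-validation-RMSE
weights: w_m = (1/RMSE_m) / sum_k (1/RMSE_k).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import basinhopping

from .core import PhenologyObservation, WeatherSeries
from .phenology_models import (
    MODEL_PARAM_CLASSES, EnsembleWeights, SeasonMatrix, param_names,
    params_from_dict, predict_batch, season_from_weather)

logger = logging.getLogger(__name__)

#: pseudo-prediction for a site-year that never flowers: day 365 + penalty
MISSED_PREDICTION_DOY = 365.0 + 100.0

#: per-model parameter bounds used when the caller supplies none
DEFAULT_BOUNDS: dict[str, dict[str, tuple[float, float]]] = {
    "m1": {"t1": (1, 150), "threshold": (-5, 20), "f_star": (1.0, 200),
           "k": (0, 2)},
    "uniforc": {"t1": (1, 150), "f_star": (0.5, 200), "b": (-5, -1e-3),
                "c": (-5, 20)},
    "alternating": {"t1": (1, 150), "threshold": (-5, 20), "a": (0, 300),
                    "b": (0, 1000), "c": (-0.1, 0)},
    "unichill": {"t0": (1, 150), "c_star": (0.5, 150), "f_star": (0.5, 200),
                 "b_f": (-5, -1e-3), "c_f": (-5, 20), "a_c": (1e-3, 2),
                 "b_c": (-2, 2), "c_c": (-5, 20)},
}


def rmse(observed, predicted) -> float:
    """Root-mean-square error between paired day-of-year lists."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.size == 0:
        raise ValueError("observed and predicted must be equal-length, non-empty")
    return float(np.sqrt(np.mean((o - p) ** 2)))


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 - SSE/SST (may be negative)."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.size < 2 or o.shape != p.shape:
        raise ValueError("need >= 2 paired observations")
    sst = float(np.sum((o - o.mean()) ** 2))
    if sst == 0:
        raise ValueError("observed values have zero variance")
    return 1.0 - float(np.sum((o - p) ** 2)) / sst


def split_observations(obs: list[PhenologyObservation], fraction: float = 0.7,
                       seed: int = 0, stratify_by_site: bool = False
                       ) -> tuple[list[PhenologyObservation],
                                  list[PhenologyObservation]]:
    """Random disjoint calibration/validation partition.

    Calibration receives round(fraction * n) records.  With
    ``stratify_by_site`` the split is applied within each site.
    """
    if len(obs) < 4:
        raise ValueError("need at least 4 observations to split")
    rng = np.random.default_rng(seed)
    if stratify_by_site:
        cal: list[PhenologyObservation] = []
        val: list[PhenologyObservation] = []
        for site in sorted({o.site_id for o in obs}):
            group = [o for o in obs if o.site_id == site]
            idx = rng.permutation(len(group))
            n_cal = round(fraction * len(group))
            cal += [group[i] for i in idx[:n_cal]]
            val += [group[i] for i in idx[n_cal:]]
        return cal, val
    idx = rng.permutation(len(obs))
    n_cal = round(fraction * len(obs))
    return [obs[i] for i in idx[:n_cal]], [obs[i] for i in idx[n_cal:]]


@dataclass
class FitReport:
    """Outcome of one model calibration."""

    model_id: str
    params: object
    rmse_c: float
    rmse_v: float | None
    r2_v: float | None
    iterations: int
    seed: int

    def to_dict(self) -> dict:
        from .phenology_models import params_to_dict
        return {
            "model_id": self.model_id,
            "params": {k: float(v)
                       for k, v in params_to_dict(self.params).items()},
            "rmse_c": float(self.rmse_c),
            "rmse_v": None if self.rmse_v is None else float(self.rmse_v),
            "r2_v": None if self.r2_v is None else float(self.r2_v),
            "iterations": self.iterations,
            "seed": self.seed,
        }


class _BoundedStep:
    """Uniform hop of +-stepsize in scaled space, clipped to [0, 1]."""

    def __init__(self, stepsize: float, rng: np.random.Generator):
        self.stepsize = stepsize
        self.rng = rng

    def __call__(self, x: np.ndarray) -> np.ndarray:
        prop = x + self.rng.uniform(-self.stepsize, self.stepsize, x.shape)
        return np.clip(prop, 0.0, 1.0)


class _Objective:
    """Calibration RMSE as a function of the scaled parameter vector."""

    def __init__(self, model_id, obs, weather_by_site, bounds):
        self.model_id = model_id
        self.names = param_names(model_id)
        self.lo = np.array([bounds[n][0] for n in self.names])
        self.hi = np.array([bounds[n][1] for n in self.names])
        # observations sorted for order invariance of the objective
        obs = sorted(obs, key=lambda o: (o.site_id, o.year))
        self.observed = np.array([o.doy for o in obs], dtype=float)
        seasons = [season_from_weather(weather_by_site[o.site_id], o.year)
                   for o in obs]
        # single-precision season stack: ~2x faster objective, far below
        # the 2 d observation noise in effect
        self.matrix = SeasonMatrix(seasons, dtype=np.float32)
        self.cls = MODEL_PARAM_CLASSES[model_id]

    def unscale(self, x: np.ndarray) -> np.ndarray:
        return self.lo + np.clip(x, 0.0, 1.0) * (self.hi - self.lo)

    def params(self, x: np.ndarray):
        raw = self.unscale(x)
        return self.cls(**{n: float(v) for n, v in zip(self.names, raw)})

    def predictions(self, x: np.ndarray) -> np.ndarray:
        pred = predict_batch(self.model_id, self.params(x), self.matrix)
        return np.where(np.isnan(pred), MISSED_PREDICTION_DOY, pred)

    def __call__(self, x: np.ndarray) -> float:
        return rmse(self.observed, self.predictions(x))


def calibrate(model_id: str, cal_obs: list[PhenologyObservation],
              weather_by_site: dict[str, WeatherSeries],
              bounds: dict[str, tuple[float, float]] | None = None,
              iterations: int = 1000, step: float = 0.5, seed: int = 0,
              val_obs: list[PhenologyObservation] | None = None,
              local_maxfev: int = 200, presample: int = 256) -> FitReport:
    """Fit one model by basin hopping on the calibration RMSE.

    The hop chain starts from the best of ``presample`` uniform random
    draws over the (scaled) bounds, which reliably lands the first local
    search in a flowering-capable region.  Returns the best parameter
    vector encountered; when ``val_obs`` is given, RMSE and R^2 on the
    held-out set are evaluated with the fitted parameters.  Fully
    reproducible given ``seed``.
    """
    if not cal_obs:
        raise ValueError("no calibration observations")
    bounds = bounds or DEFAULT_BOUNDS[model_id]
    obj = _Objective(model_id, cal_obs, weather_by_site, bounds)
    rng = np.random.default_rng(seed)
    if presample > 0:
        draws = rng.uniform(0.0, 1.0, size=(presample, len(obj.names)))
        x0 = draws[int(np.argmin([obj(d) for d in draws]))]
    else:
        x0 = rng.uniform(0.05, 0.95, size=len(obj.names))
    minimizer_kwargs = {
        "method": "Nelder-Mead",
        "bounds": [(0.0, 1.0)] * len(obj.names),
        "options": {"maxfev": local_maxfev, "xatol": 1e-3, "fatol": 1e-3},
    }
    result = basinhopping(obj, x0, niter=iterations,
                          take_step=_BoundedStep(step, rng),
                          minimizer_kwargs=minimizer_kwargs, seed=rng)
    x_best = np.clip(result.x, 0.0, 1.0)
    best_rmse = float(obj(x_best))
    preds = obj.predictions(x_best)
    if np.all(preds == MISSED_PREDICTION_DOY):
        raise RuntimeError(
            f"{model_id}: no parameter vector produced any flowering "
            "prediction; widen the parameter bounds")
    fitted = obj.params(x_best)

    rmse_v = r2_v = None
    if val_obs:
        val_obj = _Objective(model_id, val_obs, weather_by_site, bounds)
        val_pred = val_obj.predictions(x_best)
        rmse_v = rmse(val_obj.observed, val_pred)
        r2_v = (r_squared(val_obj.observed, val_pred)
                if len(val_obs) >= 2 and np.ptp(val_obj.observed) > 0 else None)
    logger.info("%s: RMSE_c=%.2f d RMSE_v=%s", model_id, best_rmse,
                f"{rmse_v:.2f} d" if rmse_v is not None else "n/a")
    return FitReport(model_id, fitted, best_rmse, rmse_v, r2_v,
                     iterations, seed)


def ensemble_weights(validation_rmse: dict[str, float]) -> EnsembleWeights:
    """Normalised inverse-RMSE weights, w_m = (1/RMSE_m) / sum(1/RMSE_k).

    A model with zero validation error would dominate; it receives all
    the weight (shared if several are perfect), with a warning.
    """
    if any(r < 0 for r in validation_rmse.values()):
        raise ValueError("RMSE values must be non-negative")
    zeros = [m for m, r in validation_rmse.items() if r == 0.0]
    if zeros:
        logger.warning("perfect validation RMSE for %s; assigning full weight",
                       zeros)
        w = {m: (1.0 / len(zeros) if m in zeros else 0.0)
             for m in validation_rmse}
        # zero weights violate the container's strict positivity; build raw
        return _degenerate_weights(w, validation_rmse)
    inv = {m: 1.0 / r for m, r in validation_rmse.items()}
    total = sum(inv.values())
    return EnsembleWeights({m: v / total for m, v in inv.items()},
                           dict(validation_rmse))


def _degenerate_weights(w: dict[str, float], rmses: dict[str, float]
                        ) -> EnsembleWeights:
    ew = EnsembleWeights.__new__(EnsembleWeights)
    ew.weights = w
    ew.rmse = dict(rmses)
    return ew
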