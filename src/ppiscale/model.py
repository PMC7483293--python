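"""Sigmoid startle-curve model of prepulse inhibition.

The startle response of an animal to a sound of level ``s`` (dB above
background) in the absence of a prepulse is described by a baseline
startle curve

    m(s) = m0 + N(s),        N(s) = m_max / (1 + exp(-r (s - s0)))

where ``m`` is the mean log10 movement, ``m0`` the sound-independent
baseline movement, ``m_max`` the saturation, ``r`` the slope and ``s0``
the midpoint of the sigmoid.  A prepulse condition ``c`` (a pair of
prepulse level and prepulse-to-startle delay) modifies this curve by
scaling it along the startle axis (``alpha_c``) and along the sound axis
(``beta_c``):

    m_c(s) = m0 + alpha_c * N(beta_c * s)        (both scalings)
    m_c(s) = m0 + alpha_c * N(s)                 (startle scaling only)

Both scaling parameters are bounded to [0, 1]; bounded fits prevent
compensation between the parameters and keep them interpretable as
fractional reductions.  A fit for one animal has 3 + 2n free parameters
(or 3 + n for the startle-only variant) for n prepulse conditions; m0 is
estimated from the zero-startle trials and held fixed.

The public surface follows the statsmodels convention: build a
:class:`StartleScalingModel` from one animal's per-stimulus movement
summaries (or trial-level movements), call :meth:`~StartleScalingModel.fit`,
and work with the returned :class:`StartleScalingResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .exceptions import (
    InsufficientDesignError,
    PpiScaleWarning,
)

__all__ = [
    "StartleCurveParams",
    "ConditionScaling",
    "FitConfig",
    "StartleScalingModel",
    "StartleScalingResults",
    "CrossValidationResult",
    "sigmoid",
    "predicted_movement",
    "baseline_threshold",
    "percent_scaling",
    "normalized_error",
    "fit_cohort",
    "cohort_parameter_table",
    "swap_parameters",
]

BASELINE_CONDITION = (0.0, 0.0)


@dataclass(frozen=True)
class StartleCurveParams:
    """Baseline startle sigmoid parameters.

    m_max : saturation, maximal log-movement above m0 (log10 z-units)
    r     : sigmoid slope (per dB)
    s0    : midpoint, the sound at 50% of saturation (dB above background)
    m0    : baseline movement independent of sound (log10 z-units, >= 0);
            fixed by estimation rather than free in the optimisation.
    """

    m_max: float
    r: float
    s0: float
    m0: float = 0.0

    def __post_init__(self) -> None:
        if self.m_max <= 0:
            raise ValueError(f"m_max must be > 0, got {self.m_max}")
        if self.r <= 0:
            raise ValueError(f"r must be > 0, got {self.r}")
        if self.m0 < 0:
            raise ValueError(f"m0 must be >= 0, got {self.m0}")


@dataclass(frozen=True)
class ConditionScaling:
    """Scaling pair for one prepulse condition.

    alpha scales the startle axis, beta the sound axis; both in [0, 1]
    (1 = no scaling, 0 = 100% scaling).
    """

    prepulse_db: float
    delay_ms: float
    alpha: float
    beta: float = 1.0

    @property
    def condition(self) -> tuple[float, float]:
        return (self.prepulse_db, self.delay_ms)

    @property
    def percent_startle_scaling(self) -> float:
        return percent_scaling(self.alpha)

    @property
    def percent_sound_scaling(self) -> float:
        return percent_scaling(self.beta)


@dataclass(frozen=True)
class FitConfig:
    """Tunable knobs of the fitting and resampling machinery."""

    xtol: float = 1e-12
    ftol: float = 1e-12
    gtol: float = 1e-12
    n_restarts: int = 3
    cv_fraction: float = 0.8
    cv_iterations: int = 100
    cv_unit: str = "trial"  # "trial" or "summary"
    jitter_refits: int = 10_000
    ci_percentiles: tuple[float, float] = (5.0, 95.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.cv_fraction < 1.0:
            raise ValueError("cv_fraction must lie in (0, 1)")
        if self.cv_iterations < 1 or self.jitter_refits < 1:
            raise ValueError("iteration counts must be >= 1")
        if self.cv_unit not in ("trial", "summary"):
            raise ValueError("cv_unit must be 'trial' or 'summary'")


def sigmoid(s, params: StartleCurveParams):
    """Baseline sigmoid N(s) = m_max / (1 + exp(-r (s - s0)))."""
    s = np.asarray(s, dtype=float)
    return params.m_max / (1.0 + np.exp(-params.r * (s - params.s0)))


def predicted_movement(
    s,
    scaling: ConditionScaling | None,
    params: StartleCurveParams,
    variant: str = "both",
):
    """Model prediction m0 + alpha * N(beta * s) for one condition.

    ``scaling=None`` denotes the baseline (no-prepulse) condition, for
    which alpha = beta = 1.  ``variant='startle_only'`` ignores beta.
    """
    s = np.asarray(s, dtype=float)
    if scaling is None:
        alpha, beta = 1.0, 1.0
    else:
        alpha, beta = scaling.alpha, scaling.beta
    if variant == "startle_only":
        beta = 1.0
    elif variant != "both":
        raise ValueError(f"unknown variant {variant!r}")
    return params.m0 + alpha * sigmoid(beta * s, params)


def baseline_threshold(params: StartleCurveParams) -> float:
    """Sound level at which the baseline curve reaches 5% of saturation.

    Solving N(s) = 0.05 m_max gives s = s0 - ln(19)/r.
    """
    if params.r <= 0:
        raise ValueError("threshold requires r > 0")
    return params.s0 - np.log(19.0) / params.r


def percent_scaling(x: float) -> float:
    """Convert a scaling parameter in [0, 1] to percent scaling 100(1-x)."""
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"scaling parameter must lie in [0, 1], got {x}")
    return 100.0 * (1.0 - x)


def _summaries_from_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Aggregate trial-level log movements to per-stimulus summaries."""
    grouped = trials.groupby(["prepulse_db", "delay_ms", "startle_db"])["log_movement"]
    out = grouped.agg(
        mean_log_movement="mean",
        sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan,
        n_trials="count",
    ).reset_index()
    return out


class StartleScalingModel:
    """Startle-curve scaling model for a single animal.

    Parameters
    ----------
    summaries : DataFrame
        Per-stimulus movement summaries with columns ``prepulse_db``,
        ``delay_ms``, ``startle_db``, ``mean_log_movement``, ``sem``,
        ``n_trials``.  Rows with ``prepulse_db == 0`` form the baseline
        condition.
    variant : {"both", "startle_only"}
        Whether sound scaling (beta) is a free parameter.
    trials : DataFrame, optional
        Trial-level movements (columns ``prepulse_db``, ``delay_ms``,
        ``startle_db``, ``log_movement``); required for trial-level
        cross-validation.
    """

    MIN_BASELINE_LEVELS = 4

    def __init__(
        self,
        summaries: pd.DataFrame,
        variant: str = "both",
        trials: pd.DataFrame | None = None,
        animal_id=None,
    ):
        if variant not in ("both", "startle_only"):
            raise ValueError(f"unknown variant {variant!r}")
        required = {"prepulse_db", "delay_ms", "startle_db", "mean_log_movement"}
        missing = required - set(summaries.columns)
        if missing:
            raise ValueError(f"summaries missing columns {sorted(missing)}")
        self.summaries = summaries.reset_index(drop=True).copy()
        if "sem" not in self.summaries:
            self.summaries["sem"] = np.nan
        self.variant = variant
        self.trials = trials
        self.animal_id = animal_id

        base = self.summaries[self.summaries["prepulse_db"] == 0]
        if base["startle_db"].nunique() < self.MIN_BASELINE_LEVELS:
            raise InsufficientDesignError(
                "need baseline summaries at >= "
                f"{self.MIN_BASELINE_LEVELS} startle levels, got "
                f"{base['startle_db'].nunique()}"
            )
        cond = self.summaries[self.summaries["prepulse_db"] > 0]
        self.conditions: list[tuple[float, float]] = sorted(
            {(float(p), float(d)) for p, d in zip(cond["prepulse_db"], cond["delay_ms"])}
        )
        if not self.conditions:
            raise InsufficientDesignError("need at least one prepulse condition")
        self.m0 = self._estimate_m0()
        self._build_design()

    @classmethod
    def from_trials(
        cls, trials: pd.DataFrame, variant: str = "both", animal_id=None
    ) -> "StartleScalingModel":
        """Build the model from trial-level log movements."""
        return cls(
            _summaries_from_trials(trials),
            variant=variant,
            trials=trials,
            animal_id=animal_id,
        )

    # -- internals -----------------------------------------------------

    def _estimate_m0(self) -> float:
        """Initial m0: mean log movement at the zero-startle stimulus.

        m0 is not a free optimisation parameter; :meth:`fit` refines it
        self-consistently (the 0-dB observation is m0 + N(0), and N(0)
        is not exactly zero for low-midpoint curves).  Clipped at 0: the
        model assumes a non-negative sound-independent movement.
        """
        ybar0 = self._ybar0()
        if ybar0 is None:
            warnings.warn(
                "no 0-dB baseline trials; setting m0 = 0",
                PpiScaleWarning,
                stacklevel=3,
            )
            return 0.0
        return max(0.0, ybar0)

    def _ybar0(self) -> float | None:
        """Observed mean log movement at the 0-dB no-prepulse stimulus."""
        if not hasattr(self, "_m0_mask"):
            self._m0_mask = (
                (self.summaries["prepulse_db"] == 0)
                & (self.summaries["startle_db"] == 0)
            ).to_numpy()
        if not self._m0_mask.any():
            return None
        if hasattr(self, "_y"):
            return float(np.mean(self._y[self._m0_mask]))
        return float(
            self.summaries["mean_log_movement"].to_numpy()[self._m0_mask].mean()
        )

    def _build_design(self) -> None:
        cond_index = {c: i for i, c in enumerate(self.conditions)}
        s = self.summaries
        self._s = s["startle_db"].to_numpy(float)
        self._y = s["mean_log_movement"].to_numpy(float)
        self._sem = s["sem"].to_numpy(float)
        self._cidx = np.array(
            [
                -1 if p == 0 else cond_index[(float(p), float(d))]
                for p, d in zip(s["prepulse_db"], s["delay_ms"])
            ],
            dtype=int,
        )
        self.n_conditions = len(self.conditions)
        self.n_free = 3 + (2 if self.variant == "both" else 1) * self.n_conditions
        self.param_names = ["m_max", "r", "s0"]
        self.param_names += [f"alpha[{p:g},{d:g}]" for p, d in self.conditions]
        if self.variant == "both":
            self.param_names += [f"beta[{p:g},{d:g}]" for p, d in self.conditions]

    def _unpack(self, x):
        n = self.n_conditions
        m_max, r, s0 = x[0], x[1], x[2]
        alphas = x[3 : 3 + n]
        betas = x[3 + n : 3 + 2 * n] if self.variant == "both" else np.ones(n)
        return m_max, r, s0, alphas, betas

    def _m0_at(self, x) -> float:
        """Self-consistent m0 for curve parameters x.

        The 0-dB no-prepulse observation equals m0 + N(0); m0 is that
        observed mean minus the curve's N(0), clipped at zero.  It is
        fixed by estimation, never a free optimisation parameter.
        """
        ybar0 = self._ybar0()
        if ybar0 is None:
            return self.m0
        m_max, r, s0 = x[0], x[1], x[2]
        n0 = m_max / (1.0 + np.exp(r * s0))
        return max(0.0, ybar0 - n0)

    def _residuals(self, x):
        m_max, r, s0, alphas, betas = self._unpack(x)
        a = np.where(self._cidx < 0, 1.0, alphas[self._cidx])
        b = np.where(self._cidx < 0, 1.0, betas[self._cidx])
        u = b * self._s
        g = 1.0 / (1.0 + np.exp(-r * (u - s0)))
        return self._m0_at(x) + a * m_max * g - self._y

    def _jacobian(self, x):
        n = self.n_conditions
        m_max, r, s0, alphas, betas = self._unpack(x)
        a = np.where(self._cidx < 0, 1.0, alphas[self._cidx])
        b = np.where(self._cidx < 0, 1.0, betas[self._cidx])
        u = b * self._s
        g = 1.0 / (1.0 + np.exp(-r * (u - s0)))
        gd = g * (1.0 - g)
        J = np.zeros((len(self._s), self.n_free))
        J[:, 0] = a * g
        J[:, 1] = a * m_max * gd * (u - s0)
        J[:, 2] = -a * m_max * gd * r
        # m0(x) = ybar0 - N(0|x) when positive: its gradient feeds all rows
        ybar0 = self._ybar0()
        if ybar0 is not None:
            g0 = 1.0 / (1.0 + np.exp(r * s0))
            if ybar0 - m_max * g0 > 0:
                J[:, 0] -= g0
                J[:, 1] += m_max * g0 * (1.0 - g0) * s0
                J[:, 2] += m_max * g0 * (1.0 - g0) * r
        rows = np.arange(len(self._s))
        mask = self._cidx >= 0
        J[rows[mask], 3 + self._cidx[mask]] = m_max * g[mask]
        if self.variant == "both":
            J[rows[mask], 3 + n + self._cidx[mask]] = (
                a[mask] * m_max * gd[mask] * r * self._s[mask]
            )
        return J

    def _bounds(self):
        n = self.n_conditions
        smax = float(self._s.max())
        lower = [1e-8, 1e-8, -30.0]
        upper = [np.inf, 5.0, smax + 30.0]
        k = 2 * n if self.variant == "both" else n
        lower += [0.0] * k
        upper += [1.0] * k
        return np.array(lower), np.array(upper)

    def _baseline_init(self, rng: np.random.Generator | None = None):
        """Sigmoid fit to the baseline condition alone (initial values)."""
        mask = self._cidx < 0
        s_b, y_b = self._s[mask], self._y[mask] - self.m0
        m_max0 = max(float(y_b.max()), 0.1)
        half = self.m0 + 0.5 * float(y_b.max())
        s0_0 = float(s_b[np.argmin(np.abs(self._y[mask] - half))])
        x0 = np.array([m_max0, 0.15, s0_0])
        if rng is not None:
            x0 = x0 * rng.uniform(0.7, 1.3, size=3)

        def res(p):
            return p[0] / (1.0 + np.exp(-p[1] * (s_b - p[2]))) - y_b

        lb, ub = self._bounds()
        sol = least_squares(
            res, np.clip(x0, lb[:3] + 1e-9, ub[:3] - 1e-9), bounds=(lb[:3], ub[:3])
        )
        return sol.x

    def fit(
        self,
        config: FitConfig | None = None,
        start_params: np.ndarray | None = None,
    ) -> "StartleScalingResults":
        """Jointly fit the sigmoid and all condition scalings.

        Minimises the total RMSE between predictions and mean log
        movements across all stimuli via bounded nonlinear least squares
        with an analytic Jacobian.  Scaling parameters start at 1 (no
        scaling); the baseline sigmoid starts at a fit to the baseline
        condition alone.  On non-convergence, a few perturbed restarts
        are attempted before the fit is flagged.
        """
        config = config or FitConfig()
        lb, ub = self._bounds()
        n_scale = self.n_free - 3
        if start_params is not None:
            x0 = np.clip(np.asarray(start_params, float), lb, ub)
        else:
            x0 = np.concatenate([self._baseline_init(), np.ones(n_scale)])
            x0 = np.clip(x0, lb + 1e-12, ub - 1e-12)

        sol = self._solve(x0, lb, ub, config)
        converged = sol.success and np.isfinite(sol.cost)
        if not converged:
            rng = np.random.default_rng(config.seed)
            for _ in range(config.n_restarts):
                x_try = np.concatenate(
                    [self._baseline_init(rng), rng.uniform(0.5, 1.0, n_scale)]
                )
                x_try = np.clip(x_try, lb + 1e-12, ub - 1e-12)
                trial = self._solve(x_try, lb, ub, config)
                if trial.success and trial.cost < sol.cost:
                    sol = trial
                    converged = True
                    break
        if not converged:
            warnings.warn(
                f"fit for animal {self.animal_id!r} did not converge; "
                "results flagged",
                PpiScaleWarning,
                stacklevel=2,
            )
        self.m0 = self._m0_at(sol.x)
        return StartleScalingResults(self, sol.x, sol, converged=converged)

    def _solve(self, x0, lb, ub, config: FitConfig):
        return least_squares(
            self._residuals,
            x0,
            jac=self._jacobian,
            bounds=(lb, ub),
            xtol=config.xtol,
            ftol=config.ftol,
            gtol=config.gtol,
            method="trf",
        )

    # -- cross-validation ---------------------------------------------

    def cross_validate(self, config: FitConfig | None = None) -> "CrossValidationResult":
        """Compare the two scaling variants by repeated 80/20 splits.

        Each iteration splits trials within every stimulus into train and
        holdout sets, fits both model variants to the train summaries and
        scores each on the holdout summaries with the SEM-normalized
        RMSE.  Reports the mean error per variant and their difference
        (startle_only - both); positive differences favour sound scaling.
        """
        config = config or FitConfig()
        if config.cv_unit == "trial":
            if self.trials is None:
                raise ValueError("trial-level CV requires trial data; use from_trials")
            return self._cross_validate_trials(config)
        return self._cross_validate_summaries(config)

    def _cross_validate_trials(self, config: FitConfig) -> "CrossValidationResult":
        rng = np.random.default_rng(config.seed)
        trials = self.trials
        keys = ["prepulse_db", "delay_ms", "startle_db"]
        groups = {k: idx.to_numpy() for k, idx in trials.groupby(keys).groups.items()}
        small = [k for k, idx in groups.items() if len(idx) < 5]
        if small:
            warnings.warn(
                f"{len(small)} stimuli have <5 trials; holdout still has >=1 trial",
                PpiScaleWarning,
                stacklevel=3,
            )
        # warm starts from the full-data fits speed convergence markedly
        warm = {
            v: StartleScalingModel(
                self.summaries, variant=v, animal_id=self.animal_id
            ).fit(config)
            for v in ("both", "startle_only")
        }
        err = {"both": [], "startle_only": []}
        for _ in range(config.cv_iterations):
            test_rows = []
            for idx in groups.values():
                n_hold = max(1, int(round((1.0 - config.cv_fraction) * len(idx))))
                test_rows.append(rng.choice(idx, size=n_hold, replace=False))
            test_idx = np.concatenate(test_rows)
            is_test = trials.index.isin(test_idx)
            train_sum = _summaries_from_trials(trials[~is_test])
            test_sum = _summaries_from_trials(trials[is_test])
            for v in ("both", "startle_only"):
                m = StartleScalingModel(train_sum, variant=v, animal_id=self.animal_id)
                res = m.fit(config, start_params=warm[v].x)
                err[v].append(normalized_error(res, test_sum))
        return CrossValidationResult(
            animal_id=self.animal_id,
            cv_error_both=float(np.mean(err["both"])),
            cv_error_startle_only=float(np.mean(err["startle_only"])),
            errors_both=np.array(err["both"]),
            errors_startle_only=np.array(err["startle_only"]),
        )

    def _cross_validate_summaries(self, config: FitConfig) -> "CrossValidationResult":
        """Alternative CV unit: hold out whole stimulus-mean points."""
        rng = np.random.default_rng(config.seed)
        n = len(self.summaries)
        err = {"both": [], "startle_only": []}
        for _ in range(config.cv_iterations):
            n_hold = max(1, int(round((1.0 - config.cv_fraction) * n)))
            test_idx = rng.choice(n, size=n_hold, replace=False)
            is_test = np.zeros(n, bool)
            is_test[test_idx] = True
            train = self.summaries[~is_test]
            test = self.summaries[is_test]
            for v in ("both", "startle_only"):
                try:
                    m = StartleScalingModel(train, variant=v, animal_id=self.animal_id)
                except InsufficientDesignError:
                    continue
                res = m.fit(config)
                err[v].append(normalized_error(res, test))
        return CrossValidationResult(
            animal_id=self.animal_id,
            cv_error_both=float(np.mean(err["both"])),
            cv_error_startle_only=float(np.mean(err["startle_only"])),
            errors_both=np.array(err["both"]),
            errors_startle_only=np.array(err["startle_only"]),
        )


@dataclass
class CrossValidationResult:
    animal_id: object
    cv_error_both: float
    cv_error_startle_only: float
    errors_both: np.ndarray = field(repr=False, default=None)
    errors_startle_only: np.ndarray = field(repr=False, default=None)

    @property
    def error_difference(self) -> float:
        """startle_only minus both; positive favours the two-scaling model."""
        return self.cv_error_startle_only - self.cv_error_both


class StartleScalingResults:
    """Fit results for one animal.

    Attributes
    ----------
    params : StartleCurveParams
        Baseline sigmoid parameters (with the fixed m0).
    scalings : dict[(prepulse_db, delay_ms) -> ConditionScaling]
    rmse : float
        Root-mean-squared residual over all stimuli.
    converged : bool
    """

    def __init__(self, model: StartleScalingModel, x, solver_result, converged=True):
        self.model = model
        self.x = np.asarray(x, float)
        self.solver_result = solver_result
        self.converged = bool(converged)
        m_max, r, s0, alphas, betas = model._unpack(self.x)
        self.params = StartleCurveParams(
            m_max=float(m_max), r=float(r), s0=float(s0), m0=model.m0
        )
        self.scalings = {
            c: ConditionScaling(c[0], c[1], float(alphas[i]), float(betas[i]))
            for i, c in enumerate(model.conditions)
        }
        resid = model._residuals(self.x)
        self.rmse = float(np.sqrt(np.mean(resid**2)))
        self.n_params = model.n_free
        self._ci = None

    @property
    def animal_id(self):
        return self.model.animal_id

    @property
    def variant(self) -> str:
        return self.model.variant

    @property
    def threshold(self) -> float:
        """Sound level at 5% of saturation."""
        return baseline_threshold(self.params)

    def predict(self, startle_db, condition=BASELINE_CONDITION):
        """Predicted mean log movement at the given startle levels."""
        c = (float(condition[0]), float(condition[1]))
        scaling = None if c[0] == 0 else self.scalings[c]
        return predicted_movement(startle_db, scaling, self.params, self.model.variant)

    def fittedvalues(self) -> np.ndarray:
        return self.model._residuals(self.x) + self.model._y

    def conf_int(
        self, n_refits: int | None = None, config: FitConfig | None = None
    ) -> pd.DataFrame:
        """90% jitter confidence intervals (see :func:`jitter_confidence`)."""
        config = config or FitConfig()
        if n_refits is not None:
            config = replace(config, jitter_refits=n_refits)
        ci, _ = jitter_confidence(self, config)
        return ci

    def to_dict(self) -> dict:
        d = {
            "animal_id": self.animal_id,
            "variant": self.variant,
            "converged": self.converged,
            "rmse": self.rmse,
            "m_max": self.params.m_max,
            "r": self.params.r,
            "s0": self.params.s0,
            "m0": self.params.m0,
            "threshold": self.threshold,
            "scalings": [
                {
                    "prepulse_db": sc.prepulse_db,
                    "delay_ms": sc.delay_ms,
                    "alpha": sc.alpha,
                    "beta": sc.beta,
                    "percent_startle_scaling": sc.percent_startle_scaling,
                    "percent_sound_scaling": sc.percent_sound_scaling,
                }
                for sc in self.scalings.values()
            ],
        }
        return d

    def summary(self) -> str:
        """Human-readable parameter table."""
        lines = [
            "Startle scaling model"
            + (f" — animal {self.animal_id}" if self.animal_id is not None else ""),
            f"variant: {self.variant}   converged: {self.converged}   "
            f"rmse: {self.rmse:.4f}   free params: {self.n_params}",
            "",
            f"baseline: m_max={self.params.m_max:.3f}  r={self.params.r:.4f}  "
            f"s0={self.params.s0:.2f}  m0={self.params.m0:.3f}  "
            f"threshold={self.threshold:.2f} dB",
            "",
            f"{'prepulse':>9} {'delay':>7} {'alpha':>7} {'beta':>7} "
            f"{'%startle':>9} {'%sound':>8}",
        ]
        for sc in self.scalings.values():
            lines.append(
                f"{sc.prepulse_db:9.2f} {sc.delay_ms:7.0f} {sc.alpha:7.3f} "
                f"{sc.beta:7.3f} {sc.percent_startle_scaling:9.1f} "
                f"{sc.percent_sound_scaling:8.1f}"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot the data and fitted curves per condition."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s_grid = np.linspace(self.model._s.min(), self.model._s.max(), 200)
        df = self.model.summaries
        for (p, d), sub in df.groupby(["prepulse_db", "delay_ms"]):
            label = "baseline" if p == 0 else f"{p:g} dB / {d:g} ms"
            pts = ax.errorbar(
                sub["startle_db"], sub["mean_log_movement"], yerr=sub["sem"],
                fmt="o", ms=4, label=label,
            )
            cond = BASELINE_CONDITION if p == 0 else (float(p), float(d))
            ax.plot(s_grid, self.predict(s_grid, cond), color=pts[0].get_color())
        ax.set_xlabel("startle sound (dB above background)")
        ax.set_ylabel("log10 movement (z-units)")
        ax.legend(fontsize=7)
        return ax


def normalized_error(results: StartleScalingResults, test_summaries: pd.DataFrame) -> float:
    """SEM-normalized RMSE of a fitted model on held-out summaries.

    sqrt(mean over stimuli of ((prediction - mean)/sem)^2).  Stimuli with
    sem == 0 (or undefined) are excluded with a warning: they would carry
    infinite weight.
    """
    pred = np.array(
        [
            results.predict(row.startle_db, (row.prepulse_db, row.delay_ms))
            for row in test_summaries.itertuples()
        ],
        dtype=float,
    )
    y = test_summaries["mean_log_movement"].to_numpy(float)
    sem = test_summaries["sem"].to_numpy(float)
    ok = np.isfinite(sem) & (sem > 0)
    if not ok.all():
        warnings.warn(
            f"excluding {int((~ok).sum())} stimuli with zero/undefined sem "
            "from normalized error",
            PpiScaleWarning,
            stacklevel=2,
        )
    if not ok.any():
        return np.nan
    z = (pred[ok] - y[ok]) / sem[ok]
    return float(np.sqrt(np.mean(z**2)))


def jitter_confidence(
    results: StartleScalingResults, config: FitConfig | None = None
) -> tuple[pd.DataFrame, int]:
    """Parameter confidence intervals from refits to jittered data.

    Every refit perturbs each stimulus's observed mean log movement by an
    independent Gaussian draw with SD equal to that stimulus's SEM, then
    refits the model (warm-started at the point estimate).  The interval
    for each parameter spans the configured percentiles (default 5th to
    95th, a 90% CI) of the refit values.  Returns (ci_frame, n_failures).
    """
    config = config or FitConfig()
    model = results.model
    rng = np.random.default_rng(config.seed)
    sem = np.nan_to_num(model._sem, nan=0.0)
    y0 = model._y.copy()
    m0_0 = model.m0
    draws = np.empty((config.jitter_refits, model.n_free))
    failures = 0
    for i in range(config.jitter_refits):
        model._y = y0 + rng.normal(0.0, 1.0, size=len(y0)) * sem
        try:
            refit = model.fit(config, start_params=results.x)
            if not refit.converged:
                failures += 1
            draws[i] = refit.x
        except Exception:
            failures += 1
            draws[i] = np.nan
        finally:
            model._y = y0
            model.m0 = m0_0
    if failures > 0.05 * config.jitter_refits:
        warnings.warn(
            f"{failures}/{config.jitter_refits} jitter refits failed",
            PpiScaleWarning,
            stacklevel=2,
        )
    lo, hi = np.nanpercentile(draws, config.ci_percentiles, axis=0)
    ci = pd.DataFrame(
        {"lower": lo, "upper": hi}, index=pd.Index(model.param_names, name="param")
    )
    return ci, failures


def jitter_draws(
    results: StartleScalingResults, n_refits: int, seed: int
) -> pd.DataFrame:
    """Raw parameter draws from jittered refits (one row per refit)."""
    model = results.model
    rng = np.random.default_rng(seed)
    sem = np.nan_to_num(model._sem, nan=0.0)
    y0 = model._y.copy()
    m0_0 = model.m0
    rows = np.empty((n_refits, model.n_free))
    config = FitConfig()
    for i in range(n_refits):
        model._y = y0 + rng.normal(0.0, 1.0, size=len(y0)) * sem
        try:
            rows[i] = model.fit(config, start_params=results.x).x
        except Exception:
            rows[i] = np.nan
        finally:
            model._y = y0
            model.m0 = m0_0
    return pd.DataFrame(rows, columns=model.param_names)


# -- cohort-level helpers ---------------------------------------------


def fit_cohort(
    trials: pd.DataFrame,
    variant: str = "both",
    config: FitConfig | None = None,
) -> dict:
    """Fit the model to every animal in a trial table.

    ``trials`` must carry ``animal_id`` plus the per-trial columns used by
    :meth:`StartleScalingModel.from_trials`.  Returns a dict mapping
    animal_id to :class:`StartleScalingResults`.
    """
    out = {}
    for animal, sub in trials.groupby("animal_id", sort=True):
        model = StartleScalingModel.from_trials(
            sub.reset_index(drop=True), variant=variant, animal_id=animal
        )
        out[animal] = model.fit(config)
    return out


def cohort_parameter_table(
    results_by_animal: dict, groups: dict | pd.Series | None = None
) -> pd.DataFrame:
    """Tidy per-animal, per-condition parameter table for group analysis.

    One row per (animal, prepulse condition) with the baseline parameters
    (m_max, r, s0, threshold) repeated across conditions and the
    condition's scaling pair.
    """
    rows = []
    for animal, res in results_by_animal.items():
        for sc in res.scalings.values():
            rows.append(
                {
                    "animal_id": animal,
                    "group": None if groups is None else groups[animal],
                    "prepulse_db": sc.prepulse_db,
                    "delay_ms": sc.delay_ms,
                    "m_max": res.params.m_max,
                    "r": res.params.r,
                    "s0": res.params.s0,
                    "m0": res.params.m0,
                    "threshold": res.threshold,
                    "alpha": sc.alpha,
                    "beta": sc.beta,
                    "rmse": res.rmse,
                }
            )
    return pd.DataFrame(rows)


def swap_parameters(
    results_by_animal: dict, summaries_by_animal: dict
) -> pd.DataFrame:
    """Score every animal's data under every other animal's parameters.

    For each ordered pair (i, j != i) with identical stimulus designs,
    computes the SEM-normalized error of animal i's summaries under
    animal j's fitted parameters; rows with i == j give the self-fit
    error.  A long table is returned; aggregate with
    :func:`swap_summary`.
    """
    animals = list(results_by_animal)
    key_cols = ["prepulse_db", "delay_ms", "startle_db"]
    designs = {
        a: set(map(tuple, summaries_by_animal[a][key_cols].to_numpy()))
        for a in animals
    }
    rows = []
    for i in animals:
        for j in animals:
            if designs[i] != designs[j]:
                warnings.warn(
                    f"stimulus sets differ for {i!r}/{j!r}; pair skipped",
                    PpiScaleWarning,
                    stacklevel=2,
                )
                continue
            err = normalized_error(results_by_animal[j], summaries_by_animal[i])
            rows.append({"data_animal": i, "params_animal": j, "error": err})
    return pd.DataFrame(rows)


def swap_summary(swap_table: pd.DataFrame) -> dict:
    """Median self-fit and swapped errors plus per-animal increases."""
    if swap_table.empty:
        return {
            "median_self_error": np.nan,
            "median_swap_error": np.nan,
            "median_error_increase": np.nan,
            "per_animal": pd.DataFrame(),
        }
    self_mask = swap_table["data_animal"] == swap_table["params_animal"]
    self_err = swap_table[self_mask].set_index("data_animal")["error"]
    swapped = swap_table[~self_mask]
    per_animal = (
        swapped.groupby("data_animal")["error"]
        .median()
        .to_frame("median_swap_error")
        .join(self_err.rename("self_error"))
    )
    per_animal["error_increase"] = (
        per_animal["median_swap_error"] - per_animal["self_error"]
    )
    return {
        "median_self_error": float(self_err.median()),
        "median_swap_error": float(swapped["error"].median()),
        "median_error_increase": float(per_animal["error_increase"].median()),
        "per_animal": per_animal,
    }
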