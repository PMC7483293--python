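"""Synthetic startle cohorts with the structure the analysis assumes.

Animals carry a sigmoid baseline startle curve plus per-condition
scaling pairs; per-trial log10 movement is Gaussian around the model
mean (so raw movements are log-normal, matching what rat startle data
show).  Across animals, the scaling parameters are coupled to the
baseline curve through a latent jointly-Gaussian construction mapped
through bounded (logistic) transforms, reproducing the empirical
correlations between startle scaling and saturation, and between sound
scaling and threshold.

The default cohort mirrors a realistic design: startle levels 0-60 dB
above background in 10 dB steps, 13 prepulse conditions spanning
2-18 dB at a 100 ms delay, 60 trials per stimulus, and trial noise
sigma = 0.15 log10-units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .exceptions import SpecError
from .model import StartleCurveParams, sigmoid
from .preprocessing import AccelerometerTrace, Stimulus

__all__ = [
    "CohortSpec",
    "sample_animal_params",
    "simulate_trials",
    "simulate_cohort",
    "simulate_traces",
]

_LN19 = float(np.log(19.0))


def _default_conditions() -> tuple:
    """13 prepulse levels spanning 2-18 dB at a constant 100 ms delay."""
    return tuple((round(p, 2), 100.0) for p in np.linspace(2.0, 18.0, 13))


def delay_conditions(prepulse_db: float = 14.0) -> tuple:
    """Delay-varying condition set at a fixed prepulse level."""
    return tuple((prepulse_db, d) for d in (50.0, 100.0, 150.0, 200.0))


def _alpha_mean(prepulse_db: float, delay_ms: float) -> float:
    """Default startle-scaling mean: stronger for louder, earlier prepulses."""
    a = 0.97 - 0.013 * prepulse_db + 0.0006 * (delay_ms - 100.0)
    return float(np.clip(a, 0.05, 0.98))


def _beta_mean(prepulse_db: float, delay_ms: float) -> float:
    """Default sound-scaling mean."""
    b = 0.995 - 0.0065 * prepulse_db + 0.0003 * (delay_ms - 100.0)
    return float(np.clip(b, 0.05, 0.995))


@dataclass(frozen=True)
class CohortSpec:
    """Generative description of a synthetic cohort.

    Baseline parameters are drawn per animal: saturation m_max and slope
    r from Gaussians, the threshold (sound at 5% of saturation) from a
    Gaussian, with the midpoint derived as s0 = threshold + ln(19)/r so
    that correlation targets on the threshold are exact.  Scaling pairs
    are logistic transforms of animal-level latents; ``rho_alpha_mmax``
    and ``rho_beta_threshold`` set the latent correlations (negative by
    default, as observed empirically).  ``group_offsets`` maps a group
    label to additive offsets on named parameters (``alpha``/``beta``
    offsets are applied on the natural scale and clipped to [0, 1]).
    """

    groups: tuple = (("wt", 20),)
    conditions: tuple = field(default_factory=_default_conditions)
    startle_levels: tuple = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0)
    trials_per_stimulus: int = 60
    trial_sigma: float = 0.15  # SD of per-trial log10 movement
    m_max_mean: float = 2.0
    m_max_sd: float = 0.35
    r_mean: float = 0.20
    r_sd: float = 0.03
    threshold_mean: float = 10.0
    threshold_sd: float = 4.0
    m0_mean: float = 0.10
    m0_sd: float = 0.03
    alpha_means: tuple | None = None  # per condition; default from _alpha_mean
    beta_means: tuple | None = None
    alpha_latent_sd: float = 0.5  # on the logit scale
    beta_latent_sd: float = 0.4
    rho_alpha_mmax: float = -0.5
    rho_beta_threshold: float = -0.65
    rho_alpha_beta: float = 0.0
    group_offsets: tuple = ()  # ((label, param, offset), ...)
    n_sessions: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "m_max_sd",
            "r_sd",
            "threshold_sd",
            "m0_sd",
            "alpha_latent_sd",
            "beta_latent_sd",
            "trial_sigma",
        ):
            if getattr(self, name) < 0:
                raise SpecError(f"{name} must be >= 0")
        if self.trials_per_stimulus < 1:
            raise SpecError("trials_per_stimulus must be >= 1")
        for label, n in self.groups:
            if n < 1:
                raise SpecError(f"group {label!r} must have >= 1 animal")
        for rho in (self.rho_alpha_mmax, self.rho_beta_threshold, self.rho_alpha_beta):
            if abs(rho) > 1:
                raise SpecError("correlation targets must lie in [-1, 1]")
        self.latent_cholesky()  # raises SpecError on a non-PSD matrix

    def latent_correlation(self) -> np.ndarray:
        """Correlation matrix of the latents (m_max, threshold, alpha, beta)."""
        r1, r2, r3 = self.rho_alpha_mmax, self.rho_beta_threshold, self.rho_alpha_beta
        return np.array(
            [
                [1.0, 0.0, r1, 0.0],
                [0.0, 1.0, 0.0, r2],
                [r1, 0.0, 1.0, r3],
                [0.0, r2, r3, 1.0],
            ]
        )

    def latent_cholesky(self) -> np.ndarray:
        corr = self.latent_correlation()
        try:
            return np.linalg.cholesky(corr + 1e-12 * np.eye(4))
        except np.linalg.LinAlgError as exc:
            raise SpecError(
                "correlation targets form a non-positive-semidefinite matrix"
            ) from exc

    def condition_alpha_means(self) -> np.ndarray:
        if self.alpha_means is not None:
            return np.asarray(self.alpha_means, float)
        return np.array([_alpha_mean(p, d) for p, d in self.conditions])

    def condition_beta_means(self) -> np.ndarray:
        if self.beta_means is not None:
            return np.asarray(self.beta_means, float)
        return np.array([_beta_mean(p, d) for p, d in self.conditions])

    def offsets_for(self, label: str) -> dict:
        return {p: o for g, p, o in self.group_offsets if g == label}

    def to_json(self) -> str:
        return json.dumps(asdict(self), default=list, indent=2)


def sample_animal_params(
    spec: CohortSpec, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw jointly distributed per-animal true parameters.

    Returns ``(animals, scalings)``: one row per animal with the baseline
    parameters and the latent draws, and one row per (animal, condition)
    with the true alpha/beta.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    chol = spec.latent_cholesky()
    a_means, b_means = spec.condition_alpha_means(), spec.condition_beta_means()
    animals, scalings = [], []
    idx = 0
    for label, n in spec.groups:
        off = spec.offsets_for(label)
        for _ in range(n):
            z = chol @ rng.standard_normal(4)  # (m_max, threshold, alpha, beta)
            z_m0 = rng.standard_normal()
            m_max = max(0.2, spec.m_max_mean + spec.m_max_sd * z[0] + off.get("m_max", 0.0))
            r = max(0.02, spec.r_mean + spec.r_sd * rng.standard_normal() + off.get("r", 0.0))
            thr = spec.threshold_mean + spec.threshold_sd * z[1] + off.get("threshold", 0.0)
            s0 = thr + _LN19 / r
            m0 = float(np.clip(spec.m0_mean + spec.m0_sd * z_m0 + off.get("m0", 0.0), 0.0, None))
            animal_id = f"{label}_{idx:03d}"
            animals.append(
                {
                    "animal_id": animal_id,
                    "group": label,
                    "m_max": m_max,
                    "r": r,
                    "s0": s0,
                    "threshold": thr,
                    "m0": m0,
                    "latent_alpha": z[2],
                    "latent_beta": z[3],
                }
            )
            alphas = expit(logit(a_means) + spec.alpha_latent_sd * z[2])
            betas = expit(logit(b_means) + spec.beta_latent_sd * z[3])
            alphas = np.clip(alphas + off.get("alpha", 0.0), 0.0, 1.0)
            betas = np.clip(betas + off.get("beta", 0.0), 0.0, 1.0)
            for (p, d), a, b in zip(spec.conditions, alphas, betas):
                scalings.append(
                    {
                        "animal_id": animal_id,
                        "group": label,
                        "prepulse_db": p,
                        "delay_ms": d,
                        "alpha": float(a),
                        "beta": float(b),
                    }
                )
            idx += 1
    return pd.DataFrame(animals), pd.DataFrame(scalings)


def _stimulus_grid(spec: CohortSpec):
    """Stimuli for one animal: baseline at all levels, conditions at s > 0."""
    stimuli = [(0.0, 0.0, s) for s in spec.startle_levels]
    for p, d in spec.conditions:
        stimuli += [(p, d, s) for s in spec.startle_levels if s > 0]
    return stimuli


def simulate_trials(
    animals: pd.DataFrame,
    scalings: pd.DataFrame,
    spec: CohortSpec,
    seed: int | None = None,
) -> pd.DataFrame:
    """Trial table with log-normal per-trial movement noise.

    Per stimulus, ``trials_per_stimulus`` draws of log10 movement ~
    Normal(m0 + alpha N(beta s), trial_sigma); ``max_reading`` is 10 to
    that power.  The 0-dB baseline stimulus is included so m0 is
    estimable downstream.  The schema matches the real-data input table.
    """
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    sc = scalings.set_index(["animal_id", "prepulse_db", "delay_ms"])
    stimuli = _stimulus_grid(spec)
    n_rep = spec.trials_per_stimulus
    rows = []
    for a in animals.itertuples():
        curve = StartleCurveParams(m_max=a.m_max, r=a.r, s0=a.s0, m0=a.m0)
        for p, d, s in stimuli:
            if p == 0:
                alpha = beta = 1.0
            else:
                pair = sc.loc[(a.animal_id, p, d)]
                alpha, beta = float(pair["alpha"]), float(pair["beta"])
            mean = a.m0 + alpha * float(sigmoid(beta * s, curve))
            draws = mean + spec.trial_sigma * rng.standard_normal(n_rep)
            sess = np.repeat(
                np.arange(1, spec.n_sessions + 1),
                int(np.ceil(n_rep / spec.n_sessions)),
            )[:n_rep]
            for t in range(n_rep):
                rows.append(
                    {
                        "animal_id": a.animal_id,
                        "group": a.group,
                        "session": int(sess[t]),
                        "trial": t + 1,
                        "startle_db": s,
                        "prepulse_db": p,
                        "delay_ms": d,
                        "max_reading": 10.0 ** draws[t],
                    }
                )
    return pd.DataFrame(rows)


def simulate_cohort(
    spec: CohortSpec, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Sample parameters and trials in one call.

    Returns ``(animals, scalings, trials)``; identical spec and seed give
    byte-identical tables.
    """
    base = spec.seed if seed is None else seed
    animals, scalings = sample_animal_params(spec, seed=base)
    trials = simulate_trials(animals, scalings, spec, seed=base + 1)
    return animals, scalings, trials


def simulate_traces(
    trials: pd.DataFrame,
    seed: int = 0,
    sample_rate: float = 1000.0,
    baseline_mu: float = 5.0,
    baseline_sigma: float = 2.0,
    startle_onset_ms: float = 150.0,
    duration_ms: float = 300.0,
) -> list:
    """Raw accelerometer traces whose preprocessing recovers the trials.

    Each trace is Gaussian baseline noise at the session's (mu, sigma)
    with a transient 40 ms after startle onset whose raw height encodes
    the trial's intended z-scored maximum (``max_reading``).  Intended
    maxima below the noise floor will be shadowed by noise peaks, which
    the preprocessing flags — that is the intended edge-case behaviour.
    """
    rng = np.random.default_rng(seed)
    n_samples = int(duration_ms * sample_rate / 1000.0)
    peak_idx = int((startle_onset_ms + 40.0) * sample_rate / 1000.0)
    traces = []
    for row in trials.itertuples():
        samples = baseline_mu + baseline_sigma * rng.standard_normal(n_samples)
        samples[peak_idx] = baseline_mu + baseline_sigma * float(row.max_reading)
        traces.append(
            AccelerometerTrace(
                animal_id=row.animal_id,
                session_id=row.session,
                trial_index=row.trial,
                samples=samples,
                sample_rate=sample_rate,
                startle_onset_ms=startle_onset_ms,
                stimulus=Stimulus(
                    startle_db=row.startle_db,
                    prepulse_db=row.prepulse_db,
                    delay_ms=row.delay_ms,
                ),
            )
        )
    return traces
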