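"""Raw startle-trial preprocessing.

Accelerometer traces are gain-normalized per (animal, session) by
z-scoring against a Gaussian fit to the pooled pre-startle readings (the
first 100 ms of every trial, always before the startle stimulus).  Each
trial's movement is the maximum z-scored reading in the 100 ms after
startle onset, carried on the log10 scale; per-trial movements are
averaged per (animal, stimulus) across all sessions of an experiment.

The distribution screen compares Gaussian and log-normal descriptions of
the raw per-stimulus movement distributions (Shapiro-Wilk on raw and
log10 values, and the log-likelihood difference at maximum likelihood).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    DegenerateBaselineError,
    InsufficientDataError,
    InvalidNormalizerError,
    PpiScaleWarning,
)

__all__ = [
    "Stimulus",
    "AccelerometerTrace",
    "TrialMovement",
    "fit_session_baseline",
    "zscore_normalize",
    "extract_trial_movement",
    "trials_from_table",
    "process_traces",
    "summarize_movement",
    "distribution_screen",
    "distribution_screen_table",
]

TRIAL_TABLE_COLUMNS = [
    "animal_id",
    "group",
    "session",
    "trial",
    "startle_db",
    "prepulse_db",
    "delay_ms",
]


@dataclass(frozen=True)
class Stimulus:
    """One stimulus: startle level plus prepulse condition.

    Levels are dB above background.  ``delay_ms`` is prepulse onset to
    startle onset.  The baseline condition has no prepulse sound.
    """

    startle_db: float
    prepulse_db: float = 0.0
    delay_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.startle_db < 0 or self.prepulse_db < 0:
            raise ValueError("sound levels must be >= 0 dB above background")
        if self.prepulse_db > 0 and self.delay_ms <= 0:
            raise ValueError("delay_ms must be > 0 when a prepulse is present")

    @property
    def is_baseline(self) -> bool:
        return self.prepulse_db == 0


@dataclass(frozen=True)
class AccelerometerTrace:
    """Raw (or z-scored) accelerometer trace for one trial."""

    animal_id: object
    session_id: object
    trial_index: int
    samples: np.ndarray
    sample_rate: float  # Hz
    startle_onset_ms: float
    stimulus: Stimulus

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        object.__setattr__(
            self, "samples", np.asarray(self.samples, dtype=float)
        )

    def _window(self, start_ms: float, stop_ms: float) -> np.ndarray:
        i0 = int(np.floor(start_ms * self.sample_rate / 1000.0))
        i1 = int(np.ceil(stop_ms * self.sample_rate / 1000.0))
        return self.samples[max(i0, 0) : i1]

    @property
    def pre_startle(self) -> np.ndarray:
        """Readings in the first 100 ms of the trace (pre-stimulus)."""
        return self._window(0.0, 100.0)

    @property
    def post_startle(self) -> np.ndarray:
        """Readings in the 100 ms following startle onset."""
        return self._window(self.startle_onset_ms, self.startle_onset_ms + 100.0)


@dataclass(frozen=True)
class TrialMovement:
    """Max z-scored deflection of one trial, on raw and log10 scales."""

    animal_id: object
    stimulus: Stimulus
    max_startle: float
    log_movement: float  # log10(max_startle); NaN when max_startle <= 0
    session_id: object = None

    @property
    def usable(self) -> bool:
        return np.isfinite(self.log_movement)


def fit_session_baseline(traces) -> tuple[float, float]:
    """Gaussian fit (mean, sample SD) to pooled pre-startle readings.

    Pools the first 100 ms of every trial in one animal-session; these
    readings precede any stimulus and define the session's gain.
    """
    pooled = [t.pre_startle for t in traces]
    if not pooled:
        raise InsufficientDataError("no traces supplied")
    readings = np.concatenate(pooled)
    if readings.size < 2:
        raise InsufficientDataError(
            f"need >= 2 pooled pre-startle readings, got {readings.size}"
        )
    mu = float(np.mean(readings))
    sigma = float(np.std(readings, ddof=1))
    if sigma == 0.0:
        raise DegenerateBaselineError("pre-startle readings are constant")
    return mu, sigma


def zscore_normalize(trace: AccelerometerTrace, mu: float, sigma: float) -> AccelerometerTrace:
    """Return a copy of the trace with samples replaced by (x - mu)/sigma."""
    if sigma <= 0:
        raise InvalidNormalizerError(f"sigma must be > 0, got {sigma}")
    return replace(trace, samples=(trace.samples - mu) / sigma)


def extract_trial_movement(trace: AccelerometerTrace) -> TrialMovement:
    """Maximal z-scored value within 100 ms after startle onset.

    The log movement is log10 of that maximum; non-positive maxima leave
    it NaN (the trial is flagged, to be dropped and counted downstream).
    """
    window = trace.post_startle
    if window.size == 0:
        raise InsufficientDataError("post-startle window is empty")
    max_startle = float(window.max())
    log_movement = np.log10(max_startle) if max_startle > 0 else np.nan
    return TrialMovement(
        animal_id=trace.animal_id,
        stimulus=trace.stimulus,
        max_startle=max_startle,
        log_movement=log_movement,
        session_id=trace.session_id,
    )


def process_traces(traces, by_session: bool = True) -> pd.DataFrame:
    """Full trace pipeline: per-session baseline fit, z-score, extract.

    Returns a trial-movement table (one row per trial).  Trials whose
    post-onset maximum is non-positive keep a NaN ``log_movement`` and
    are counted in a warning.
    """
    rows = []
    keyfn = (lambda t: (t.animal_id, t.session_id)) if by_session else (lambda t: t.animal_id)
    sessions: dict = {}
    for t in traces:
        sessions.setdefault(keyfn(t), []).append(t)
    n_dropped = 0
    for sess_traces in sessions.values():
        mu, sigma = fit_session_baseline(sess_traces)
        for t in sess_traces:
            tm = extract_trial_movement(zscore_normalize(t, mu, sigma))
            if not tm.usable:
                n_dropped += 1
            rows.append(
                {
                    "animal_id": tm.animal_id,
                    "session": tm.session_id,
                    "trial": t.trial_index,
                    "startle_db": t.stimulus.startle_db,
                    "prepulse_db": t.stimulus.prepulse_db,
                    "delay_ms": t.stimulus.delay_ms,
                    "max_startle": tm.max_startle,
                    "log_movement": tm.log_movement,
                }
            )
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped}/{len(rows)} trials with non-positive "
            "post-startle maximum",
            PpiScaleWarning,
            stacklevel=2,
        )
    return pd.DataFrame(rows)


def trials_from_table(table: pd.DataFrame) -> pd.DataFrame:
    """Trial-movement table from a delimited trial table with max readings.

    The input must carry the standard columns (animal_id, group, session,
    trial, startle_db, prepulse_db, delay_ms) plus ``max_reading``, the
    precomputed gain-normalized maximum deflection.  Habituation trials
    (``is_habituation`` truthy) are retained in the output but flagged;
    summaries exclude them.  Non-positive readings get NaN log movement
    and are counted in a warning.
    """
    missing = [c for c in TRIAL_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trial table missing columns {missing}")
    if "max_reading" not in table.columns:
        raise ValueError("trial table needs a max_reading column (or use traces)")
    out = table.copy()
    reading = out["max_reading"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["log_movement"] = np.where(reading > 0, np.log10(reading), np.nan)
    if "is_habituation" not in out.columns:
        out["is_habituation"] = False
    n_bad = int((~(reading > 0)).sum())
    if n_bad:
        warnings.warn(
            f"dropped {n_bad}/{len(out)} trials with non-positive max reading "
            f"({n_bad / len(out):.1%})",
            PpiScaleWarning,
            stacklevel=2,
        )
    return out


def summarize_movement(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-(animal, stimulus) mean log movement with SEM and trial count.

    Trial repeats are pooled across all sessions of an experiment.
    Habituation-flagged and unusable (NaN log movement) trials are
    excluded.  Groups left empty after exclusion are omitted with a
    warning.  SEM uses the sample (n-1) SD and is NaN for n < 2.
    """
    t = trials
    if "is_habituation" in t.columns:
        t = t[~t["is_habituation"].astype(bool)]
    usable = t[np.isfinite(t["log_movement"])]
    n_empty = (
        t.groupby(["animal_id", "prepulse_db", "delay_ms", "startle_db"])
        .size()
        .shape[0]
        - usable.groupby(["animal_id", "prepulse_db", "delay_ms", "startle_db"])
        .size()
        .shape[0]
    )
    if n_empty:
        warnings.warn(
            f"{n_empty} (animal, stimulus) groups had no usable trials; omitted",
            PpiScaleWarning,
            stacklevel=2,
        )
    keys = ["animal_id", "prepulse_db", "delay_ms", "startle_db"]
    if "group" in usable.columns:
        keys = ["animal_id", "group", "prepulse_db", "delay_ms", "startle_db"]
    agg = usable.groupby(keys)["log_movement"].agg(
        mean_log_movement="mean",
        sd=lambda x: x.std(ddof=1),
        n_trials="count",
    )
    agg["sem"] = agg["sd"] / np.sqrt(agg["n_trials"])
    return agg.drop(columns="sd").reset_index()


def distribution_screen(values) -> tuple[float, float, float]:
    """Compare Gaussian vs log-normal descriptions of trial movements.

    Returns ``(p_raw, p_log, loglik_diff)``: Shapiro-Wilk p-values on the
    raw and log10-transformed values, and the difference in maximized
    log-likelihood between a log-normal and a Gaussian model (positive
    means the log-normal fits better).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise InsufficientDataError("need >= 3 values for the screen")
    if np.any(x <= 0):
        raise ValueError("log-normal screen requires strictly positive values")
    p_raw = float(stats.shapiro(x).pvalue)
    logx = np.log(x)
    p_log = float(stats.shapiro(logx).pvalue)
    # max-likelihood Gaussian: mean, population SD
    ll_gauss = float(np.sum(stats.norm.logpdf(x, x.mean(), x.std(ddof=0))))
    # max-likelihood log-normal via the normal fit on ln(x)
    ll_lognorm = float(
        np.sum(stats.norm.logpdf(logx, logx.mean(), logx.std(ddof=0))) - logx.sum()
    )
    return p_raw, p_log, ll_lognorm - ll_gauss


def distribution_screen_table(trials: pd.DataFrame, min_trials: int = 3) -> pd.DataFrame:
    """Distribution screen per (animal, stimulus) cell of a trial table."""
    rows = []
    keys = ["animal_id", "prepulse_db", "delay_ms", "startle_db"]
    for key, sub in trials.groupby(keys):
        x = sub["max_startle"] if "max_startle" in sub else sub["max_reading"]
        x = x.to_numpy(float)
        x = x[x > 0]
        if x.size < min_trials:
            continue
        p_raw, p_log, lld = distribution_screen(x)
        rows.append(dict(zip(keys, key), p_raw=p_raw, p_log=p_log, loglik_diff=lld))
    return pd.DataFrame(rows)
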