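"""The traditional PPI ratio metric and its diagnostics.

PPI_ratio = 1 - m_p / m_b compares the movement with a prepulse (m_p)
against the same-startle-level movement without one (m_b).  Under a
model in which a prepulse only scales the startle axis
(m = m0 + alpha N(s), with m0 >= 0 and 0 < alpha <= 1), PPI_ratio cannot
decrease with startle sound level; the observed systematic decrease is
the motivation for the sound-scaling parameter.  This module computes
the empirical ratio and its per-condition slope against sound level, and
the theoretical ratio under the startle-scaling-only model.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .exceptions import PpiScaleWarning, UndefinedRatioError
from .model import StartleCurveParams, sigmoid

__all__ = [
    "ppi_ratio",
    "ppi_ratio_table",
    "ppi_ratio_slopes",
    "theoretical_ppi_ratio",
]


def ppi_ratio(m_b: float, m_p: float) -> float:
    """PPI_ratio = 1 - m_p/m_b.

    m_b is the movement to the startle sound alone; m_p the movement to
    the same startle sound preceded by a prepulse.  A zero baseline is
    undefined; a negative baseline (possible for near-threshold
    log-scale movements) is allowed but warned about, since the ratio's
    sign convention inverts.
    """
    if m_b == 0:
        raise UndefinedRatioError("baseline movement m_b is zero")
    if m_b < 0:
        warnings.warn(
            "baseline movement m_b < 0; PPI ratio flagged",
            PpiScaleWarning,
            stacklevel=2,
        )
    return 1.0 - m_p / m_b


def ppi_ratio_table(summaries: pd.DataFrame) -> pd.DataFrame:
    """PPI ratios for every (animal, condition, startle level).

    The baseline m_b for a given m_p is the same-startle-level,
    no-prepulse summary from the same animal.  Levels without a matched
    baseline are skipped; rows with m_b <= 0 are kept but flagged.
    """
    rows = []
    for animal, sub in summaries.groupby("animal_id"):
        base = sub[sub["prepulse_db"] == 0].set_index("startle_db")[
            "mean_log_movement"
        ]
        cond = sub[sub["prepulse_db"] > 0]
        for row in cond.itertuples():
            if row.startle_db not in base.index:
                continue
            m_b = float(base.loc[row.startle_db])
            if m_b == 0:
                continue
            rows.append(
                {
                    "animal_id": animal,
                    "prepulse_db": row.prepulse_db,
                    "delay_ms": row.delay_ms,
                    "startle_db": row.startle_db,
                    "ppi_ratio": 1.0 - row.mean_log_movement / m_b,
                    "flagged": m_b < 0,
                }
            )
    return pd.DataFrame(rows)


def ppi_ratio_slopes(
    summaries: pd.DataFrame,
    min_levels: int = 2,
    min_startle_db: float | None = 20.0,
) -> pd.DataFrame:
    """OLS slope of PPI_ratio against startle level, per (animal, condition).

    The regression uses startle-eliciting levels only
    (``startle_db >= min_startle_db``, default 20 dB above background):
    at sub-threshold levels the denominator m_b collapses to the
    sound-independent floor m0 and the ratio carries no information
    about inhibition.  Pass ``min_startle_db=None`` to use every matched
    level.  Conditions with fewer than ``min_levels`` matched startle
    levels are skipped with a warning.  The collection of slopes across
    animals and conditions is the input to population-level sign tests.
    """
    if min_startle_db is not None:
        summaries = summaries[
            (summaries["startle_db"] >= min_startle_db)
            | (summaries["startle_db"] == 0)  # keep 0-dB rows; unused by pairing
        ]
    table = ppi_ratio_table(summaries)
    rows = []
    n_skipped = 0
    if table.empty:
        return pd.DataFrame(
            columns=["animal_id", "prepulse_db", "delay_ms", "slope", "n_levels"]
        )
    for (animal, p, d), sub in table.groupby(["animal_id", "prepulse_db", "delay_ms"]):
        if len(sub) < min_levels:
            n_skipped += 1
            continue
        slope = np.polyfit(sub["startle_db"], sub["ppi_ratio"], 1)[0]
        rows.append(
            {
                "animal_id": animal,
                "prepulse_db": p,
                "delay_ms": d,
                "slope": float(slope),
                "n_levels": len(sub),
            }
        )
    if n_skipped:
        warnings.warn(
            f"skipped {n_skipped} conditions with < {min_levels} matched "
            "baseline levels",
            PpiScaleWarning,
            stacklevel=2,
        )
    return pd.DataFrame(rows)


def theoretical_ppi_ratio(curve: StartleCurveParams, alpha: float, s):
    """PPI_ratio implied by the startle-scaling-only model.

    Returns 1 - (m0 + alpha N(s)) / (m0 + N(s)).  For m0 >= 0 and
    0 < alpha <= 1 this is non-decreasing in s, which is why a pure
    startle scaling cannot reproduce the observed decline of PPI_ratio
    with sound level.
    """
    if curve.m0 < 0:
        raise ValueError("theoretical ratio requires m0 >= 0")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("theoretical ratio requires 0 < alpha <= 1")
    n = sigmoid(s, curve)
    return 1.0 - (curve.m0 + alpha * n) / (curve.m0 + n)
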