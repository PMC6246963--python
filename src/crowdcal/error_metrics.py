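"""The four accuracy measures for calorie estimates.

For an estimate ``c_hat`` of a food with ground truth ``c`` (kcal):

* error            ``e = c_hat - c``       (kcal; positive = overestimate)
* percent error    ``eta = e / c``         (signed fraction; scale-free)
* absolute error   ``abs_e = |e|``         (kcal)
* discrete accuracy ``D``: the number of a participant's estimates within 20%
  of the truth (``|eta| <= 0.20``, boundary inclusive), out of the items they
  answered.

Percent error is stored as a fraction and rendered as percent only in
reports, so a 0.5 never silently becomes a 50.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .quiz_model import QuizSpec, Response, responses_to_frame

__all__ = [
    "CORRECT_THRESHOLD",
    "ParticipantSummary",
    "compute_metrics",
    "discrete_accuracy",
    "participant_summaries",
    "per_food_summary",
]

#: "Within 20% of the true calorie value", boundary inclusive.
CORRECT_THRESHOLD = 0.20

#: Columns of the metrics table returned by :func:`compute_metrics`.
METRIC_COLUMNS = [
    "participant_id",
    "food_id",
    "estimate_kcal",
    "truth_kcal",
    "e",
    "eta",
    "abs_e",
    "correct20",
]


@dataclass(frozen=True)
class ParticipantSummary:
    """Per-participant accuracy: discrete accuracy D and mean error sizes."""

    participant_id: str
    D: int
    n_answered: int
    mean_abs_e_kcal: float
    mean_abs_eta: float


def compute_metrics(
    responses: Sequence[Response] | pd.DataFrame, quiz: QuizSpec
) -> pd.DataFrame:
    """One metrics row per response: e, eta, |e| and the correctness flag.

    Raises ``KeyError`` naming the offending response if a ``food_id`` is not
    in the quiz.
    """
    df = responses_to_frame(responses).copy()
    truth = quiz.truth_kcal()
    unknown = set(df["food_id"]) - set(truth)
    if unknown:
        raise KeyError(f"responses reference unknown food_id(s): {sorted(unknown)}")
    df["truth_kcal"] = df["food_id"].map(truth)
    df["e"] = df["estimate_kcal"] - df["truth_kcal"]
    df["eta"] = df["e"] / df["truth_kcal"]
    df["abs_e"] = df["e"].abs()
    df["correct20"] = df["eta"].abs() <= CORRECT_THRESHOLD
    return df[METRIC_COLUMNS]


def discrete_accuracy(participant_id: str, metrics: pd.DataFrame) -> ParticipantSummary:
    """Summarise one participant's rows of a metrics table.

    ``D`` counts estimates within 20% of truth over the items actually
    answered; a participant with no rows gets ``D = 0, n_answered = 0``.
    """
    rows = metrics[metrics["participant_id"] == participant_id]
    n = len(rows)
    return ParticipantSummary(
        participant_id=participant_id,
        D=int(rows["correct20"].sum()),
        n_answered=n,
        mean_abs_e_kcal=float(rows["abs_e"].mean()) if n else float("nan"),
        mean_abs_eta=float(rows["eta"].abs().mean()) if n else float("nan"),
    )


def participant_summaries(metrics: pd.DataFrame) -> pd.DataFrame:
    """Vectorised :func:`discrete_accuracy` for every participant.

    Columns: participant_id, D, n_answered, mean_abs_e_kcal, mean_abs_eta.
    """
    g = metrics.assign(abs_eta=metrics["eta"].abs()).groupby("participant_id", sort=True)
    out = g.agg(
        D=("correct20", "sum"),
        n_answered=("correct20", "size"),
        mean_abs_e_kcal=("abs_e", "mean"),
        mean_abs_eta=("abs_eta", "mean"),
    ).reset_index()
    out["D"] = out["D"].astype(int)
    return out


def per_food_summary(metrics: pd.DataFrame, quiz: QuizSpec) -> pd.DataFrame:
    """Per-food response-distribution summary (quiz row order preserved).

    Mean and median of e, eta and |e|, plus 25/50/75% quantiles of the raw
    estimates.  Foods with no responses get ``n = 0`` and NaN statistics.
    """
    rows = []
    by_food = dict(tuple(metrics.groupby("food_id")))
    for item in quiz.foods:
        sub = by_food.get(item.food_id)
        if sub is None or sub.empty:
            rows.append(
                {
                    "food_id": item.food_id,
                    "truth_kcal": item.energy_kcal,
                    "n": 0,
                    **{
                        k: np.nan
                        for k in (
                            "mean_e", "median_e", "mean_eta", "median_eta",
                            "mean_abs_e", "estimate_q25", "estimate_q50", "estimate_q75",
                        )
                    },
                }
            )
            continue
        q25, q50, q75 = sub["estimate_kcal"].quantile([0.25, 0.5, 0.75])
        rows.append(
            {
                "food_id": item.food_id,
                "truth_kcal": item.energy_kcal,
                "n": len(sub),
                "mean_e": sub["e"].mean(),
                "median_e": sub["e"].median(),
                "mean_eta": sub["eta"].mean(),
                "median_eta": sub["eta"].median(),
                "mean_abs_e": sub["abs_e"].mean(),
                "estimate_q25": q25,
                "estimate_q50": q50,
                "estimate_q75": q75,
            }
        )
    return pd.DataFrame(rows)
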