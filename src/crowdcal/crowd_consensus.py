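"""Wisdom-of-the-crowd aggregation of calorie estimates.

A *crowd* of size ``k`` is a set of ``k`` distinct participants drawn at
random (one shared draw across all foods); its consensus estimate for a food
is the mean (or median) of the members' estimates.  This module provides the
consensus computation, convergence curves of the consensus as the crowd
grows, a bootstrap test comparing the accuracy of two crowd sizes, and the
crowd-versus-expert comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .error_metrics import CORRECT_THRESHOLD, compute_metrics
from .quiz_model import QuizSpec, Response, responses_to_frame

__all__ = [
    "CrowdResult",
    "BootstrapTestResult",
    "ExpertComparison",
    "crowd_estimate",
    "convergence_curve",
    "bootstrap_crowd_test",
    "expert_comparison",
]


@dataclass
class CrowdResult:
    """Consensus estimates of one sampled crowd and their accuracy."""

    k: int
    aggregator: str
    per_food_estimate: dict[str, float]
    crowd_D: int
    crowd_mean_abs_e_kcal: float
    crowd_mean_abs_eta: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class BootstrapTestResult:
    """Two-sided bootstrap comparison of crowd sizes ``k1`` and ``k2``.

    ``statistic_observed`` is the observed difference in crowd accuracy,
    size-k1 minus size-k2; positive means the k1 crowd had the larger error.
    """

    k1: int
    k2: int
    B: int
    statistic_observed: float
    p_value: float
    seed: int
    measure: str = "kcal"

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ExpertComparison:
    """Crowd-size sweep against the best-performing expert.

    ``minimal_k`` is the smallest crowd size whose average (over draws)
    consensus error falls strictly below the best expert's individual error;
    ``None`` (``beaten = False``) when no crowd size up to ``k_max`` does.
    """

    table: pd.DataFrame
    best_expert_id: str
    best_expert_error: float
    mean_expert_error: float
    minimal_k: int | None
    beaten: bool
    measure: str

    def to_dict(self) -> dict:
        return {
            "best_expert_id": self.best_expert_id,
            "best_expert_error": self.best_expert_error,
            "mean_expert_error": self.mean_expert_error,
            "minimal_k": self.minimal_k,
            "beaten": self.beaten,
            "measure": self.measure,
            "table": self.table.to_dict(orient="records"),
        }


def _response_matrix(
    responses: Sequence[Response] | pd.DataFrame, quiz: QuizSpec
) -> pd.DataFrame:
    """Participants-by-foods estimate matrix (NaN for unanswered items)."""
    df = responses_to_frame(responses)
    mat = df.pivot_table(
        index="participant_id", columns="food_id", values="estimate_kcal", aggfunc="mean"
    )
    return mat.reindex(columns=quiz.food_ids)


def _aggregate(block: np.ndarray, aggregator: str) -> np.ndarray:
    if aggregator == "mean":
        return np.nanmean(block, axis=0)
    if aggregator == "median":
        return np.nanmedian(block, axis=0)
    raise ValueError(f"unknown aggregator {aggregator!r}; use 'mean' or 'median'")


def _consensus_metrics(
    estimates: np.ndarray, quiz: QuizSpec
) -> tuple[int, float, float]:
    """Crowd accuracy of a per-food consensus vector, via the standard
    error-metric code path (single source of truth for D)."""
    frame = pd.DataFrame(
        {
            "participant_id": "crowd",
            "food_id": quiz.food_ids,
            "estimate_kcal": estimates,
        }
    ).dropna(subset=["estimate_kcal"])
    m = compute_metrics(frame, quiz)
    return int(m["correct20"].sum()), float(m["abs_e"].mean()), float(m["eta"].abs().mean())


def crowd_estimate(
    responses: Sequence[Response] | pd.DataFrame,
    quiz: QuizSpec,
    k: int,
    aggregator: str = "mean",
    seed: int = 0,
) -> CrowdResult:
    """Consensus of one random crowd of ``k`` distinct participants."""
    mat = _response_matrix(responses, quiz)
    n = len(mat)
    if k < 1 or k > n:
        raise ValueError(f"crowd size k={k} must be in [1, {n}] (participants available)")
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=k, replace=False)
    with np.errstate(invalid="ignore"):
        consensus = _aggregate(mat.to_numpy()[idx], aggregator)
    crowd_d, mean_abs_e, mean_abs_eta = _consensus_metrics(consensus, quiz)
    return CrowdResult(
        k=k,
        aggregator=aggregator,
        per_food_estimate={
            fid: float(v) for fid, v in zip(quiz.food_ids, consensus) if np.isfinite(v)
        },
        crowd_D=crowd_d,
        crowd_mean_abs_e_kcal=mean_abs_e,
        crowd_mean_abs_eta=mean_abs_eta,
    )


def convergence_curve(
    responses: Sequence[Response] | pd.DataFrame,
    quiz: QuizSpec,
    k_grid: Sequence[int],
    n_draws: int = 100,
    aggregator: str = "mean",
    seed: int = 0,
) -> pd.DataFrame:
    """Distribution of the consensus estimate as the crowd grows.

    For every food and every ``k`` in the increasing ``k_grid``, draws
    ``n_draws`` independent crowds and records the mean and SD (over draws) of
    the consensus estimate.  Columns: food_id, k, mean_estimate, sd_estimate.
    Plotted against log k this is the familiar rapid-convergence picture.
    """
    if list(k_grid) != sorted(set(k_grid)):
        raise ValueError("k_grid must be strictly increasing")
    mat = _response_matrix(responses, quiz).to_numpy()
    n = mat.shape[0]
    rng = np.random.default_rng(seed)
    rows = []
    for k in k_grid:
        if k > n:
            raise ValueError(f"k={k} exceeds the {n} participants available")
        draws = np.empty((n_draws, mat.shape[1]))
        for b in range(n_draws):
            idx = rng.choice(n, size=k, replace=False)
            with np.errstate(invalid="ignore"):
                draws[b] = _aggregate(mat[idx], aggregator)
        mean = np.nanmean(draws, axis=0)
        sd = np.nanstd(draws, axis=0, ddof=1) if n_draws > 1 else np.zeros(mat.shape[1])
        for j, fid in enumerate(quiz.food_ids):
            rows.append(
                {"food_id": fid, "k": k, "mean_estimate": mean[j], "sd_estimate": sd[j]}
            )
    return pd.DataFrame(rows)


def _crowd_error(
    mat: np.ndarray, truth: np.ndarray, idx: np.ndarray, aggregator: str, measure: str
) -> float:
    with np.errstate(invalid="ignore"):
        consensus = _aggregate(mat[idx], aggregator)
    err = np.abs(consensus - truth)
    if measure == "percent":
        err = err / truth
    elif measure != "kcal":
        raise ValueError(f"unknown measure {measure!r}; use 'kcal' or 'percent'")
    return float(np.nanmean(err))


def bootstrap_crowd_test(
    responses: Sequence[Response] | pd.DataFrame,
    quiz: QuizSpec,
    k1: int,
    k2: int,
    B: int = 500,
    aggregator: str = "mean",
    measure: str = "kcal",
    seed: int = 0,
) -> BootstrapTestResult:
    """Is a size-``k1`` crowd any more or less accurate than size ``k2``?

    One observed crowd of each size is drawn and their consensus mean absolute
    errors across foods differenced; ``B`` further iid crowd-pair differences,
    centred at their own mean, form the reference distribution for a two-sided
    Monte-Carlo p-value ``(1 + #{|centred ref| >= |observed|}) / (B + 1)``.
    When the two crowd sizes are genuinely interchangeable the observed
    difference is exchangeable with the reference draws, so the p-value is
    uniform (the test holds its nominal level); a degenerate dataset in which
    every crowd scores identically yields ``p = 1``.
    """
    if B < 100:
        raise ValueError("B must be >= 100 for a stable bootstrap p-value")
    mat = _response_matrix(responses, quiz).to_numpy()
    truth = np.array([f.energy_kcal for f in quiz.foods])
    n = mat.shape[0]
    if max(k1, k2) > n:
        raise ValueError(f"crowd sizes ({k1}, {k2}) exceed the {n} participants available")
    rng = np.random.default_rng(seed)

    def draw_diff() -> float:
        e1 = _crowd_error(mat, truth, rng.choice(n, k1, replace=False), aggregator, measure)
        e2 = _crowd_error(mat, truth, rng.choice(n, k2, replace=False), aggregator, measure)
        return e1 - e2

    observed = draw_diff()
    ref = np.array([draw_diff() for _ in range(B)])
    centered = ref - ref.mean()
    p = (1 + int(np.sum(np.abs(centered) >= abs(observed)))) / (B + 1)
    return BootstrapTestResult(
        k1=k1,
        k2=k2,
        B=B,
        statistic_observed=float(observed),
        p_value=float(p),
        seed=seed,
        measure=measure,
    )


def expert_comparison(
    responses_nonexpert: Sequence[Response] | pd.DataFrame,
    responses_expert: Sequence[Response] | pd.DataFrame,
    quiz: QuizSpec,
    k_max: int = 20,
    n_draws: int = 200,
    aggregator: str = "mean",
    measure: str = "kcal",
    seed: int = 0,
) -> ExpertComparison:
    """How many random nonexperts does it take to beat the best expert?

    Experts are scored as individuals (mean |e| over their own answers); the
    crowd is scored by its consensus (mean |e| of the aggregated estimate
    across foods, averaged over ``n_draws`` random crowds per size).  With
    ``measure='percent'`` both sides use |eta| instead of kcal.
    """
    expert_frame = responses_to_frame(responses_expert)
    if expert_frame.empty:
        raise ValueError("expert_comparison requires at least one expert response")
    m = compute_metrics(expert_frame, quiz)
    col = m["eta"].abs() if measure == "percent" else m["abs_e"]
    per_expert = col.groupby(m["participant_id"]).mean().sort_values(kind="stable")
    best_expert_id = str(per_expert.index[0])
    best_expert_error = float(per_expert.iloc[0])
    mean_expert_error = float(per_expert.mean())

    mat = _response_matrix(responses_nonexpert, quiz).to_numpy()
    truth = np.array([f.energy_kcal for f in quiz.foods])
    n = mat.shape[0]
    rng = np.random.default_rng(seed)
    rows = []
    minimal_k: int | None = None
    for k in range(1, min(k_max, n) + 1):
        errs = [
            _crowd_error(mat, truth, rng.choice(n, k, replace=False), aggregator, measure)
            for _ in range(n_draws)
        ]
        crowd_err = float(np.mean(errs))
        rows.append(
            {
                "k": k,
                "crowd_error": crowd_err,
                "best_expert_error": best_expert_error,
                "mean_expert_error": mean_expert_error,
            }
        )
        if minimal_k is None and crowd_err < best_expert_error:
            minimal_k = k
    return ExpertComparison(
        table=pd.DataFrame(rows),
        best_expert_id=best_expert_id,
        best_expert_error=best_expert_error,
        mean_expert_error=mean_expert_error,
        minimal_k=minimal_k,
        beaten=minimal_k is not None,
        measure=measure,
    )
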