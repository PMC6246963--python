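"""Synthetic respondent cohorts for the calorie-estimation quiz.

The original survey's raw responses were never deposited, so every analysis in
this package is exercised against generated cohorts carrying the statistical
structure the analyses assume: multiplicative lognormal estimation noise, a
bias linear in centred log energy density, additive demographic effects on the
log estimate, crossed random intercepts for participants and foods, and
truncation of estimates to the quiz's allowed range.

Generative model, for participant *i* and food *j* with ground truth ``c_j``
and energy density ``d_j``::

    log c_hat_ij = log c_j
                   + beta_density * cld_j
                   + beta_male * 1[male_i]
                   + beta_age * agebin_i
                   + beta_bmi_density * (bmi_i - 25) * cld_j
                   + u_i + v_j + eps_ij

with ``cld_j = log d_j - mean_j log d_j``, ``u_i ~ N(0, sd_participant^2)``,
``v_j ~ N(0, sd_food^2)`` and ``eps_ij ~ N(0, sigma_noise^2)``.  Estimates
falling outside the quiz bounds are redrawn (``eps`` only) up to
``max_resample`` times and then clipped, mirroring a quiz interface that
forces answers into range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .quiz_model import (
    AGE_BINS,
    Gender,
    Participant,
    QuizSpec,
    FoodItem,
    Response,
)

__all__ = [
    "SimulationConfig",
    "simulate_cohort",
    "perturb_duplicate_foods",
    "simulate_block_cohort",
]

#: Age-bin sampling weights for the default cohort.  Skewed young, mirroring a
#: social-media-recruited sample rather than the general population.
_AGE_BIN_WEIGHTS = (0.05, 0.38, 0.32, 0.13, 0.07, 0.03, 0.02)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Cohort-shape defaults (cohort size, expert count, female fraction, mean
    BMI) echo the original survey; all bias coefficients default to zero, so
    the default cohort is unbiased — individual analyses switch effects on
    explicitly.  ``p_invalid_bmi`` and ``p_missing_gender`` inject records that
    the QC stage is expected to remove.
    """

    n_participants: int = 2028
    n_experts: int = 5
    seed: int = 0
    sigma_noise: float = 0.55  # SD of log-scale estimation noise
    beta_density: float = 0.0  # bias per unit centred log energy density
    beta_male: float = 0.0  # additive male effect on log estimate
    beta_age: float = 0.0  # additive effect per age-bin step
    beta_bmi_density: float = 0.0  # (BMI - 25) x centred-log-density interaction
    sd_participant: float = 0.25  # SD of participant random intercept
    sd_food: float = 0.15  # SD of food random intercept
    p_female: float = 0.62
    bmi_mean: float = 27.5  # kg/m^2
    bmi_sd: float = 5.5
    p_invalid_bmi: float = 0.025
    p_missing_gender: float = 0.022
    max_resample: int = 100

    def __post_init__(self) -> None:
        for name in ("p_female", "p_invalid_bmi", "p_missing_gender"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for name in ("sigma_noise", "sd_participant", "sd_food", "bmi_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_participants < 0 or self.n_experts < 0:
            raise ValueError("cohort sizes must be non-negative")
        if self.max_resample < 1:
            raise ValueError("max_resample must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def _centered_log_density(quiz: QuizSpec) -> np.ndarray:
    logd = np.log([f.energy_kcal / f.mass_g for f in quiz.foods])
    return logd - logd.mean()


def simulate_cohort(
    quiz: QuizSpec, config: SimulationConfig
) -> tuple[list[Participant], list[Response]]:
    """Draw a synthetic cohort and its full response table.

    Every participant (experts included — the generative process is identical,
    only the flag differs) answers every quiz food.  Deterministic for a fixed
    ``config.seed``: independent substreams are spawned for demographics,
    random intercepts and noise, so e.g. enlarging the cohort does not disturb
    the food intercepts.
    """
    n_total = config.n_participants + config.n_experts
    if n_total == 0:
        return [], []

    ss = np.random.SeedSequence(config.seed)
    rng_demo, rng_re, rng_noise = (np.random.default_rng(s) for s in ss.spawn(3))
    n_foods = len(quiz)
    cld = _centered_log_density(quiz)
    log_truth = np.log([f.energy_kcal for f in quiz.foods])

    # --- demographics -----------------------------------------------------
    is_expert = np.arange(n_total) >= config.n_participants
    male = rng_demo.random(n_total) >= config.p_female
    gender_missing = rng_demo.random(n_total) < config.p_missing_gender
    age_idx = rng_demo.choice(len(AGE_BINS), size=n_total, p=_AGE_BIN_WEIGHTS)

    # Valid BMI is truncated-normal inside the plausible range; a small
    # fraction is overwritten with implausible values to exercise QC.
    bmi = _truncated_normal(rng_demo, config.bmi_mean, config.bmi_sd, 15.5, 49.5, n_total)
    invalid = rng_demo.random(n_total) < config.p_invalid_bmi
    low_side = rng_demo.random(n_total) < 0.5
    bmi = np.where(
        invalid,
        np.where(
            low_side,
            rng_demo.uniform(5.0, 14.8, n_total),
            rng_demo.uniform(50.2, 80.0, n_total),
        ),
        bmi,
    )

    # --- linear predictor -------------------------------------------------
    u = rng_re.normal(0.0, config.sd_participant, n_total)
    v = rng_re.normal(0.0, config.sd_food, n_foods)
    mu = (
        log_truth[None, :]
        + config.beta_density * cld[None, :]
        + config.beta_male * male[:, None]
        + config.beta_age * age_idx[:, None]
        + config.beta_bmi_density * (bmi[:, None] - 25.0) * cld[None, :]
        + u[:, None]
        + v[None, :]
    )

    # --- noise with rejection resampling at the quiz bounds ---------------
    lo, hi = quiz.estimate_floor_kcal, quiz.estimate_ceiling_kcal
    est = np.exp(mu + rng_noise.normal(0.0, config.sigma_noise, mu.shape))
    for _ in range(config.max_resample - 1):
        out = (est < lo) | (est > hi)
        if not out.any():
            break
        redraw = np.exp(mu + rng_noise.normal(0.0, config.sigma_noise, mu.shape))
        est = np.where(out, redraw, est)
    est = np.clip(est, lo, hi)

    # --- records ----------------------------------------------------------
    width = max(4, len(str(n_total)))
    participants = []
    for i in range(n_total):
        if is_expert[i]:
            pid = f"expert_{i - config.n_participants + 1:0{width}d}"
        else:
            pid = f"p{i + 1:0{width}d}"
        participants.append(
            Participant(
                participant_id=pid,
                gender=(
                    Gender.MISSING
                    if gender_missing[i]
                    else (Gender.MALE if male[i] else Gender.FEMALE)
                ),
                age_group=AGE_BINS[age_idx[i]],
                bmi_kg_m2=float(bmi[i]),
                is_expert=bool(is_expert[i]),
            )
        )
    food_ids = quiz.food_ids
    responses = [
        Response(participants[i].participant_id, food_ids[j], float(est[i, j]))
        for i in range(n_total)
        for j in range(n_foods)
    ]
    return participants, responses


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, n: int
) -> np.ndarray:
    if sd == 0:
        return np.full(n, np.clip(mean, lo, hi))
    out = rng.normal(mean, sd, n)
    for _ in range(1000):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, bad.sum())
    return np.clip(out, lo, hi)


def perturb_duplicate_foods(
    quiz: QuizSpec,
    responses: list[Response],
    food_id: str,
    copies: int,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[QuizSpec, list[Response]]:
    """Append near-duplicate foods sharing the source food's errors.

    Each copy inherits the source food's ground truth and, for every
    participant, an estimate equal to the source estimate times
    ``exp(N(0, noise_sd^2))`` — so percent errors are perfectly correlated at
    ``noise_sd = 0`` and strongly correlated for small noise.  A test fixture
    for the error-correlation network; copies are not range-truncated.

    Returns an extended quiz (copies named ``<food_id>__dupK``) and extended
    response list; ``copies = 0`` returns the inputs unchanged.
    """
    source = quiz[food_id]  # raises KeyError for unknown foods
    if copies == 0:
        return quiz, responses
    if copies < 0:
        raise ValueError("copies must be >= 0")

    rng = np.random.default_rng(seed)
    new_foods = [
        FoodItem(
            food_id=f"{food_id}__dup{k + 1}",
            name=f"{source.name} (duplicate {k + 1})",
            food_type=source.food_type,
            energy_kcal=source.energy_kcal,
            mass_g=source.mass_g,
            has_reference_object=source.has_reference_object,
        )
        for k in range(copies)
    ]
    new_quiz = QuizSpec(
        foods=quiz.foods + tuple(new_foods),
        estimate_floor_kcal=quiz.estimate_floor_kcal,
        estimate_ceiling_kcal=quiz.estimate_ceiling_kcal,
    )
    extra = []
    for item in new_foods:
        for r in responses:
            if r.food_id == food_id:
                factor = np.exp(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 1.0
                extra.append(
                    Response(r.participant_id, item.food_id, float(r.estimate_kcal * factor))
                )
    return new_quiz, responses + extra


def simulate_block_cohort(
    quiz: QuizSpec,
    n_participants: int = 200,
    n_blocks: int = 3,
    block_sd: float = 0.3,
    sigma_noise: float = 0.15,
    seed: int = 0,
    truncate: bool = False,
) -> tuple[list[Participant], list[Response], dict[str, int]]:
    """Planted-partition cohort: foods share per-participant block factors.

    Foods are assigned round-robin to ``n_blocks`` blocks; participant *i*
    carries one factor score per block, ``f_bi ~ N(0, block_sd^2)``, and
    ``log c_hat_ij = log c_j + f_{b(j),i} + eps_ij``.  Within-block percent
    errors therefore correlate at roughly ``block_sd^2 / (block_sd^2 +
    sigma_noise^2)`` while between-block errors are independent — the ground
    truth for cluster-recovery tests.  Estimates are left un-truncated unless
    ``truncate=True``, since bound-clipping censors the correlation structure
    this fixture exists to provide.

    Returns participants, responses and the planted ``food_id -> block`` map.
    """
    rng = np.random.default_rng(seed)
    n_foods = len(quiz)
    labels = {fid: j % n_blocks for j, fid in enumerate(quiz.food_ids)}
    log_truth = np.log([f.energy_kcal for f in quiz.foods])

    scores = rng.normal(0.0, block_sd, (n_participants, n_blocks))
    block_of = np.array([labels[fid] for fid in quiz.food_ids])
    est = np.exp(
        log_truth[None, :]
        + scores[:, block_of]
        + rng.normal(0.0, sigma_noise, (n_participants, n_foods))
    )
    if truncate:
        est = np.clip(est, quiz.estimate_floor_kcal, quiz.estimate_ceiling_kcal)

    width = max(4, len(str(n_participants)))
    participants = [
        Participant(participant_id=f"p{i + 1:0{width}d}", gender=Gender.FEMALE, bmi_kg_m2=25.0)
        for i in range(n_participants)
    ]
    responses = [
        Response(participants[i].participant_id, fid, float(est[i, j]))
        for i in range(n_participants)
        for j, fid in enumerate(quiz.food_ids)
    ]
    return participants, responses, labels
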