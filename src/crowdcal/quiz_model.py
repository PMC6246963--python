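"""Domain types and I/O for the calorie-estimation quiz.

A quiz is a fixed set of photographed food items with known ("ground truth")
energy content.  Participants submit one calorie estimate per food; their
demographics (gender, age group, BMI) are collected separately.  This module
defines the typed records for foods, participants and responses, CSV/JSON
readers and writers, and ships the 20-item quiz used throughout the package
as the built-in fixture ``"table1"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "FoodType",
    "Gender",
    "AGE_BINS",
    "AGE_BIN_MIDPOINTS",
    "FoodItem",
    "QuizSpec",
    "Participant",
    "Response",
    "QuizValidationError",
    "ResponseParseError",
    "load_quiz",
    "energy_density",
    "read_responses",
    "write_responses",
    "responses_to_frame",
]


class FoodType(str, Enum):
    DAIRY = "dairy"
    FRUIT = "fruit"
    GRAIN = "grain"
    MEAT = "meat"
    VEGETABLE = "vegetable"
    MIXED = "mixed"


class Gender(str, Enum):
    FEMALE = "female"
    MALE = "male"
    MISSING = "missing"


#: Ordinal age bins with numeric midpoints (years).  The quiz collected an age
#: *group*, not an exact age; regressions use the midpoint as the covariate.
#: The exact bin edges used in the original survey are not published, so these
#: bins are a package convention (documented in docs/methods.md).
AGE_BINS: tuple[str, ...] = ("13-17", "18-24", "25-34", "35-44", "45-54", "55-64", "65+")
AGE_BIN_MIDPOINTS: dict[str, float] = {
    "13-17": 15.0,
    "18-24": 21.0,
    "25-34": 29.5,
    "35-44": 39.5,
    "45-54": 49.5,
    "55-64": 59.5,
    "65+": 70.0,
}


class QuizValidationError(ValueError):
    """A quiz table failed validation; the message names the offending row."""


class ResponseParseError(ValueError):
    """A response table had malformed rows; ``.row_errors`` lists them."""

    def __init__(self, row_errors: list[str]):
        self.row_errors = row_errors
        super().__init__(
            f"{len(row_errors)} malformed row(s): " + "; ".join(row_errors[:10])
        )


@dataclass(frozen=True)
class FoodItem:
    """One quiz food: ground-truth energy, mass, type, reference-object flag."""

    food_id: str
    name: str
    food_type: FoodType
    energy_kcal: float
    mass_g: float
    has_reference_object: bool

    def __post_init__(self) -> None:
        if not self.food_id:
            raise QuizValidationError("food_id must be non-empty")
        if not self.energy_kcal > 0:
            raise QuizValidationError(
                f"food {self.food_id!r}: energy_kcal must be > 0, got {self.energy_kcal}"
            )
        if not self.mass_g > 0:
            raise QuizValidationError(
                f"food {self.food_id!r}: mass_g must be > 0, got {self.mass_g}"
            )

    @property
    def single_ingredient(self) -> bool:
        """True iff the item is not a mixed-ingredient food."""
        return self.food_type is not FoodType.MIXED

    @property
    def energy_density_kcal_g(self) -> float:
        return self.energy_kcal / self.mass_g


def energy_density(food: FoodItem) -> float:
    """Energy density of a food in kcal per gram."""
    return food.energy_kcal / food.mass_g


@dataclass(frozen=True)
class QuizSpec:
    """An ordered list of quiz foods plus the allowed estimate range (kcal).

    The quiz interface forced answers into ``[estimate_floor_kcal,
    estimate_ceiling_kcal]``; the same bounds drive response-level QC.
    """

    foods: tuple[FoodItem, ...]
    estimate_floor_kcal: float = 50.0
    estimate_ceiling_kcal: float = 800.0

    def __post_init__(self) -> None:
        if not self.estimate_ceiling_kcal > self.estimate_floor_kcal > 0:
            raise QuizValidationError(
                "require 0 < estimate_floor_kcal < estimate_ceiling_kcal"
            )
        seen: set[str] = set()
        for item in self.foods:
            if item.food_id in seen:
                raise QuizValidationError(f"duplicate food_id {item.food_id!r}")
            seen.add(item.food_id)

    def __len__(self) -> int:
        return len(self.foods)

    def __getitem__(self, food_id: str) -> FoodItem:
        for item in self.foods:
            if item.food_id == food_id:
                return item
        raise KeyError(food_id)

    @property
    def food_ids(self) -> list[str]:
        return [item.food_id for item in self.foods]

    def truth_kcal(self) -> dict[str, float]:
        """Map food_id -> ground-truth kcal."""
        return {item.food_id: item.energy_kcal for item in self.foods}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "food_id": [f.food_id for f in self.foods],
                "name": [f.name for f in self.foods],
                "type": [f.food_type.value for f in self.foods],
                "energy_kcal": [f.energy_kcal for f in self.foods],
                "mass_g": [f.mass_g for f in self.foods],
                "scaling": ["yes" if f.has_reference_object else "no" for f in self.foods],
            }
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "estimate_floor_kcal": self.estimate_floor_kcal,
            "estimate_ceiling_kcal": self.estimate_ceiling_kcal,
            "foods": self.to_frame().to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


@dataclass(frozen=True)
class Participant:
    """Demographic record for one respondent.

    ``bmi_kg_m2`` is ``None`` when not reported.  ``age_group`` must be one of
    :data:`AGE_BINS` or ``None``.
    """

    participant_id: str
    gender: Gender = Gender.MISSING
    age_group: str | None = None
    bmi_kg_m2: float | None = None
    is_expert: bool = False

    def __post_init__(self) -> None:
        if self.age_group is not None and self.age_group not in AGE_BIN_MIDPOINTS:
            raise ValueError(
                f"participant {self.participant_id!r}: unknown age_group "
                f"{self.age_group!r}; expected one of {AGE_BINS}"
            )

    @property
    def age_midpoint(self) -> float | None:
        if self.age_group is None:
            return None
        return AGE_BIN_MIDPOINTS[self.age_group]

    @staticmethod
    def bmi_from_height_weight(height_m: float, weight_kg: float) -> float:
        return weight_kg / height_m**2


@dataclass(frozen=True)
class Response:
    """One (participant, food, estimate) triple — the atomic observation."""

    participant_id: str
    food_id: str
    estimate_kcal: float

    def __post_init__(self) -> None:
        if not self.estimate_kcal > 0:
            raise ValueError(
                f"response ({self.participant_id}, {self.food_id}): "
                f"estimate_kcal must be > 0, got {self.estimate_kcal}"
            )


_QUIZ_COLUMNS = ["food_id", "name", "type", "energy_kcal", "mass_g", "scaling"]
_BUILTIN_QUIZZES = {"table1": "table1.csv"}


def load_quiz(source: str | Path = "table1") -> QuizSpec:
    """Load a quiz from a CSV path or a built-in fixture name.

    The built-in ``"table1"`` fixture is the 20-food quiz (12 single-ingredient
    and 8 mixed items, energies 100-720 kcal, 6 images containing a reference
    object for scale).

    The CSV must carry columns ``food_id, name, type, energy_kcal, mass_g,
    scaling`` where ``scaling`` is yes/no (presence of a reference object).
    Row order is preserved.
    """
    if isinstance(source, str) and source in _BUILTIN_QUIZZES:
        ref = resources.files("crowdcal.data") / _BUILTIN_QUIZZES[source]
        with resources.as_file(ref) as path:
            df = pd.read_csv(path)
    else:
        df = pd.read_csv(source)

    missing = [c for c in _QUIZ_COLUMNS if c not in df.columns]
    if missing:
        raise QuizValidationError(f"quiz table missing column(s): {missing}")

    foods = []
    for idx, row in df.iterrows():
        try:
            foods.append(
                FoodItem(
                    food_id=str(row["food_id"]),
                    name=str(row["name"]),
                    food_type=FoodType(str(row["type"]).strip().lower()),
                    energy_kcal=float(row["energy_kcal"]),
                    mass_g=float(row["mass_g"]),
                    has_reference_object=_parse_bool(row["scaling"]),
                )
            )
        except (ValueError, QuizValidationError) as exc:
            raise QuizValidationError(f"quiz row {idx}: {exc}") from exc
    return QuizSpec(foods=tuple(foods))


def _parse_bool(value: object) -> bool:
    text = str(value).strip().lower()
    if text in {"yes", "true", "1"}:
        return True
    if text in {"no", "false", "0"}:
        return False
    raise ValueError(f"cannot parse boolean from {value!r}")


# ---------------------------------------------------------------------------
# Response-table I/O
#
# Two dialects are accepted:
#   * long format: one CSV with participant_id, food_id, estimate_kcal plus
#     (repeated) demographic columns gender, age_group, bmi (or height_cm /
#     height_m + weight_kg), is_expert;
#   * two-file: a responses CSV (participant_id, food_id, estimate_kcal) and a
#     demographics CSV (participant_id, gender, age_group, bmi, is_expert).
# ---------------------------------------------------------------------------

_DEMOGRAPHIC_COLUMNS = (
    "gender",
    "age_group",
    "bmi",
    "height_cm",
    "height_m",
    "weight_kg",
    "is_expert",
)


def read_responses(
    path: str | Path,
    demographics_path: str | Path | None = None,
    quiz: QuizSpec | None = None,
) -> tuple[list[Participant], list[Response]]:
    """Read a response table (and optional demographics table) from CSV.

    With ``demographics_path`` the two-file dialect is used; otherwise the
    single file must be long format, with demographic columns repeated per row
    (missing demographic columns are tolerated and read as missing).  BMI is
    computed as weight_kg / height_m**2 when height/weight columns are present
    and ``bmi`` is absent or blank.

    Malformed numeric fields are collected and raised together as
    :class:`ResponseParseError` naming the offending rows; nothing is silently
    dropped.  If ``quiz`` is given, unknown ``food_id`` values are reported the
    same way.
    """
    resp_df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("participant_id", "food_id", "estimate_kcal"):
        if col not in resp_df.columns:
            raise ResponseParseError([f"responses file missing column {col!r}"])

    errors: list[str] = []
    known_foods = set(quiz.food_ids) if quiz is not None else None

    responses: list[Response] = []
    for idx, row in resp_df.iterrows():
        rowno = idx + 2  # 1-based, counting the header line
        try:
            estimate = float(row["estimate_kcal"])
        except ValueError:
            errors.append(f"row {rowno}: estimate_kcal {row['estimate_kcal']!r} is not a number")
            continue
        if known_foods is not None and row["food_id"] not in known_foods:
            errors.append(f"row {rowno}: unknown food_id {row['food_id']!r}")
            continue
        try:
            responses.append(Response(row["participant_id"], row["food_id"], estimate))
        except ValueError as exc:
            errors.append(f"row {rowno}: {exc}")

    if demographics_path is not None:
        demo_df = pd.read_csv(demographics_path, dtype=str, keep_default_na=False)
    else:
        demo_cols = [c for c in _DEMOGRAPHIC_COLUMNS if c in resp_df.columns]
        demo_df = (
            resp_df[["participant_id", *demo_cols]]
            .drop_duplicates(subset="participant_id")
            .reset_index(drop=True)
        )
    participants = _parse_participants(demo_df, errors)

    if errors:
        raise ResponseParseError(errors)
    return participants, responses


def _parse_participants(demo_df: pd.DataFrame, errors: list[str]) -> list[Participant]:
    participants = []
    for idx, row in demo_df.iterrows():
        rowno = idx + 2
        pid = str(row["participant_id"])
        gender = Gender.MISSING
        raw_gender = str(row.get("gender", "")).strip().lower()
        if raw_gender in {"female", "male"}:
            gender = Gender(raw_gender)
        elif raw_gender not in {"", "missing", "nan"}:
            errors.append(f"row {rowno}: unknown gender {raw_gender!r}")
            continue

        age_group = str(row.get("age_group", "")).strip() or None
        bmi = _parse_optional_float(row.get("bmi", ""), f"row {rowno}: bmi", errors)
        if bmi is None:
            height_m = _parse_optional_float(
                row.get("height_m", ""), f"row {rowno}: height_m", errors
            )
            height_cm = _parse_optional_float(
                row.get("height_cm", ""), f"row {rowno}: height_cm", errors
            )
            if height_m is None and height_cm is not None:
                height_m = height_cm / 100.0
            weight_kg = _parse_optional_float(
                row.get("weight_kg", ""), f"row {rowno}: weight_kg", errors
            )
            if height_m is not None and weight_kg is not None and height_m > 0:
                bmi = Participant.bmi_from_height_weight(height_m, weight_kg)

        raw_expert = str(row.get("is_expert", "")).strip().lower()
        is_expert = raw_expert in {"yes", "true", "1"}
        try:
            participants.append(
                Participant(
                    participant_id=pid,
                    gender=gender,
                    age_group=age_group,
                    bmi_kg_m2=bmi,
                    is_expert=is_expert,
                )
            )
        except ValueError as exc:
            errors.append(f"row {rowno}: {exc}")
    return participants


def _parse_optional_float(value: object, where: str, errors: list[str]) -> float | None:
    text = str(value).strip()
    if text in {"", "nan"}:
        return None
    try:
        return float(text)
    except ValueError:
        errors.append(f"{where}: {value!r} is not a number")
        return None


def write_responses(
    participants: Sequence[Participant],
    responses: Sequence[Response],
    path: str | Path,
    demographics_path: str | Path | None = None,
) -> None:
    """Write records to CSV so that ``read_responses`` round-trips them.

    With ``demographics_path`` the two-file dialect is written; otherwise a
    single long-format CSV with demographic columns repeated per response row
    (participants without responses still appear in the demographics of the
    two-file dialect; use that dialect to preserve them).
    """
    demo = pd.DataFrame(
        {
            "participant_id": [p.participant_id for p in participants],
            "gender": ["" if p.gender is Gender.MISSING else p.gender.value for p in participants],
            "age_group": [p.age_group or "" for p in participants],
            "bmi": ["" if p.bmi_kg_m2 is None else repr(float(p.bmi_kg_m2)) for p in participants],
            "is_expert": ["true" if p.is_expert else "false" for p in participants],
        }
    )
    resp = pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in responses],
            "food_id": [r.food_id for r in responses],
            "estimate_kcal": [repr(float(r.estimate_kcal)) for r in responses],
        }
    )
    if demographics_path is not None:
        resp.to_csv(path, index=False)
        demo.to_csv(demographics_path, index=False)
    else:
        merged = resp.merge(demo, on="participant_id", how="left")
        for col in ("gender", "age_group", "bmi", "is_expert"):
            merged[col] = merged[col].fillna("")
        merged.to_csv(path, index=False)


def responses_to_frame(responses: Iterable[Response] | pd.DataFrame) -> pd.DataFrame:
    """Coerce responses to the canonical long DataFrame.

    Columns: ``participant_id``, ``food_id``, ``estimate_kcal``.  Accepts a
    list of :class:`Response` or an already-shaped DataFrame (validated).
    """
    if isinstance(responses, pd.DataFrame):
        needed = {"participant_id", "food_id", "estimate_kcal"}
        missing = needed - set(responses.columns)
        if missing:
            raise ValueError(f"response frame missing column(s): {sorted(missing)}")
        return responses
    responses = list(responses)
    return pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in responses],
            "food_id": [r.food_id for r in responses],
            "estimate_kcal": [float(r.estimate_kcal) for r in responses],
        }
    )
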