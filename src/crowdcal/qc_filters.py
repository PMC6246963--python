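"""Participant- and response-level quality-control filters.

Rules applied before any analysis:

* participants reporting a BMI below 15 or above 50 kg/m^2 (implausible), or
  with BMI unreported, or who did not report their gender, are removed along
  with all their responses;
* individual estimates below the quiz floor or above the ceiling (50 and
  800 kcal for the packaged quiz) are removed, their owners retained.

Both rules use strict inequalities: a BMI of exactly 15 or 50 and an estimate
of exactly 50 or 800 kcal are kept.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from typing import Sequence

from .quiz_model import Gender, Participant, QuizSpec, Response

__all__ = ["QcReport", "filter_participants", "filter_responses", "apply_qc"]

logger = logging.getLogger(__name__)

BMI_MIN = 15.0
BMI_MAX = 50.0


@dataclass
class QcReport:
    """Counts of records seen and removed by the QC filters."""

    n_participants_in: int = 0
    n_participants_removed_bmi: int = 0
    n_participants_removed_gender: int = 0
    n_responses_in: int = 0
    n_responses_removed_range: int = 0
    n_responses_removed_participant: int = 0

    @property
    def n_participants_retained(self) -> int:
        return (
            self.n_participants_in
            - self.n_participants_removed_bmi
            - self.n_participants_removed_gender
        )

    @property
    def n_responses_retained(self) -> int:
        return (
            self.n_responses_in
            - self.n_responses_removed_range
            - self.n_responses_removed_participant
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["n_participants_retained"] = self.n_participants_retained
        d["n_responses_retained"] = self.n_responses_retained
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _bmi_invalid(p: Participant) -> bool:
    # Missing BMI counts as removable: the record is unusable for BMI models.
    return p.bmi_kg_m2 is None or p.bmi_kg_m2 < BMI_MIN or p.bmi_kg_m2 > BMI_MAX


def filter_participants(
    participants: Sequence[Participant],
) -> tuple[list[Participant], QcReport]:
    """Drop participants with implausible/missing BMI or missing gender.

    A participant failing both rules is counted once, under the BMI rule.
    """
    report = QcReport(n_participants_in=len(participants))
    retained = []
    for p in participants:
        if _bmi_invalid(p):
            report.n_participants_removed_bmi += 1
            logger.info("QC: removed participant %s (BMI %s)", p.participant_id, p.bmi_kg_m2)
        elif p.gender is Gender.MISSING:
            report.n_participants_removed_gender += 1
            logger.info("QC: removed participant %s (gender missing)", p.participant_id)
        else:
            retained.append(p)
    return retained, report


def filter_responses(
    responses: Sequence[Response], quiz: QuizSpec
) -> tuple[list[Response], QcReport]:
    """Drop responses outside the quiz's allowed estimate range (strictly)."""
    report = QcReport(n_responses_in=len(responses))
    lo, hi = quiz.estimate_floor_kcal, quiz.estimate_ceiling_kcal
    retained = []
    for r in responses:
        if r.estimate_kcal < lo or r.estimate_kcal > hi:
            report.n_responses_removed_range += 1
            logger.info(
                "QC: removed response (%s, %s) estimate %.1f kcal out of range",
                r.participant_id, r.food_id, r.estimate_kcal,
            )
        else:
            retained.append(r)
    return retained, report


def apply_qc(
    participants: Sequence[Participant],
    responses: Sequence[Response],
    quiz: QuizSpec,
) -> tuple[list[Participant], list[Response], QcReport]:
    """Run both filters and drop responses belonging to removed participants."""
    kept_p, p_report = filter_participants(participants)
    kept_ids = {p.participant_id for p in kept_p}
    owned = [r for r in responses if r.participant_id in kept_ids]
    kept_r, r_report = filter_responses(owned, quiz)
    report = QcReport(
        n_participants_in=p_report.n_participants_in,
        n_participants_removed_bmi=p_report.n_participants_removed_bmi,
        n_participants_removed_gender=p_report.n_participants_removed_gender,
        n_responses_in=len(responses),
        n_responses_removed_range=r_report.n_responses_removed_range,
        n_responses_removed_participant=len(responses) - len(owned),
    )
    return kept_p, kept_r, report
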