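"""Eligibility and completeness exclusions with an auditable ledger.

The analysis cohort is restricted to cognitively asymptomatic adults with a
complete tapping protocol and complete cognitive scores.  A participant is
excluded iff any of the following holds, and receives exactly **one** reason
code, assigned in this documented priority order:

1. ``cognitive_symptoms`` — answered "yes" to any of the three self-report
   screening questions (noticed memory change; told they have dementia; told
   they have memory impairment);
2. ``pd_dx`` — self-reported Parkinson's disease diagnosis;
3. ``ms_dx`` — self-reported multiple sclerosis diagnosis;
4. ``incomplete_tapping`` — fewer than 4 single-key blocks or missing an
   alternate-key hand;
5. ``missing_cognitive`` — any of the three cognitive counts absent.

Single-reason attribution with a fixed priority makes the per-reason counts
mutually exclusive and hence reconcilable: included + sum(reason counts) =
total.  A missing screening boolean is a validation error, never treated as
"no".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from tapcog.keystroke_io import Cohort, ParticipantRecord, protocol_complete

__all__ = ["EXCLUSION_REASONS", "ExclusionLedger", "apply_exclusions"]

#: Reason codes in priority order (earlier wins when several apply).
EXCLUSION_REASONS = (
    "cognitive_symptoms",
    "pd_dx",
    "ms_dx",
    "incomplete_tapping",
    "missing_cognitive",
)

_SYMPTOM_FIELDS = ("memory_change", "dementia_dx", "memory_impairment_dx")


@dataclass(slots=True)
class ExclusionLedger:
    """Per-participant inclusion status plus per-reason counts."""

    status: pd.DataFrame  # index participant_id; columns: included (bool), reason (str|"")
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_total(self) -> int:
        return len(self.status)

    @property
    def n_included(self) -> int:
        return int(self.status["included"].sum())

    @property
    def n_excluded(self) -> int:
        return self.n_total - self.n_included

    def reconciles(self) -> bool:
        return sum(self.counts.values()) == self.n_excluded

    def to_frame(self) -> pd.DataFrame:
        return self.status.reset_index()


def _exclusion_reason(p: ParticipantRecord) -> str | None:
    for name in _SYMPTOM_FIELDS + ("pd_dx", "ms_dx"):
        if getattr(p, name) is None:
            raise ValueError(
                f"participant {p.participant_id!r}: screening field {name!r} is missing; "
                "refusing to treat it as 'no'"
            )
    if any(getattr(p, name) for name in _SYMPTOM_FIELDS):
        return "cognitive_symptoms"
    if p.pd_dx:
        return "pd_dx"
    if p.ms_dx:
        return "ms_dx"
    if not protocol_complete(p):
        return "incomplete_tapping"
    if p.paltea6 is None or p.swmbe6 is None or p.swms is None:
        return "missing_cognitive"
    return None


def apply_exclusions(cohort: Cohort) -> tuple[Cohort, ExclusionLedger]:
    """Split a cohort into the analysis sample and an exclusion ledger."""
    included: list[ParticipantRecord] = []
    rows = []
    counts = {r: 0 for r in EXCLUSION_REASONS}
    for p in cohort.participants:
        reason = _exclusion_reason(p)
        if reason is None:
            included.append(p)
            rows.append((p.participant_id, True, ""))
        else:
            counts[reason] += 1
            rows.append((p.participant_id, False, reason))
    status = pd.DataFrame(
        rows, columns=["participant_id", "included", "reason"]
    ).set_index("participant_id")
    ledger = ExclusionLedger(status=status, counts=counts)
    filtered = Cohort(
        participants=included,
        provenance={**cohort.provenance, "filtered": True},
    )
    return filtered, ledger
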