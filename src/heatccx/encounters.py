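"""Claims-to-encounter grouping and daily stratum aggregation.

Claim lines for the same person that fall within 1 calendar day of the
previous claim in an open encounter are chained into a single encounter
(transitively, so a run of consecutive claim days collapses into one
encounter keyed by its first claim date).  An encounter containing only
emergency-department claims is an ED encounter; any inpatient claim
makes the whole encounter inpatient, matching how discharge datasets
record a visit that begins in the ED and ends in admission.

When claims within one encounter disagree on the cause label, the cause
of the earliest claim wins, ties broken by lexicographic order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date as _date

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ClaimRecord",
    "Encounter",
    "group_claims_to_encounters",
    "classify_encounter",
    "aggregate_daily_counts",
]

SETTINGS = ("ED", "INPATIENT")


@dataclass(frozen=True)
class ClaimRecord:
    person_id: str
    claim_date: _date
    setting: str       # "ED" or "INPATIENT"
    county: str
    age_group: str
    sex: str
    cause: str

    def __post_init__(self):
        if self.setting not in SETTINGS:
            raise ValueError(f"setting must be one of {SETTINGS}, got {self.setting!r}")
        if not isinstance(self.claim_date, _date):
            raise ValueError(f"claim_date must be a date, got {type(self.claim_date)}")


@dataclass(frozen=True)
class Encounter:
    person_id: str
    start_date: _date  # earliest constituent claim date
    type: str          # "ED" iff all claims ED, else "INPATIENT"
    county: str
    age_group: str
    sex: str
    cause: str
    n_claims: int = 1


def classify_encounter(settings) -> str:
    """ED iff every constituent claim is an ED claim; inpatient otherwise."""
    settings = list(settings)
    if not settings:
        raise ValueError("encounter has no claims")
    for s in settings:
        if s not in SETTINGS:
            raise ValueError(f"unknown setting {s!r}")
    return "ED" if all(s == "ED" for s in settings) else "INPATIENT"


def group_claims_to_encounters(claims) -> list[Encounter]:
    """Chain each person's claims into encounters.

    A claim joins the open encounter when its date is at most 1 day
    after the previous claim in that encounter; otherwise it opens a new
    encounter.  The encounter's start date is its first claim date and
    its stratum fields (county, age band, sex) are taken from that first
    claim; the cause is the earliest claim's cause with lexicographic
    tie-break among same-day claims.
    """
    claims = list(claims)
    for c in claims:
        if not isinstance(c.claim_date, _date):
            raise ValueError(f"malformed claim date {c.claim_date!r}")
    ordered = sorted(claims, key=lambda c: (c.person_id, c.claim_date, c.cause))

    encounters: list[Encounter] = []
    group: list[ClaimRecord] = []

    def _close(group):
        first = group[0]
        encounters.append(
            Encounter(
                person_id=first.person_id,
                start_date=first.claim_date,
                type=classify_encounter(c.setting for c in group),
                county=first.county,
                age_group=first.age_group,
                sex=first.sex,
                cause=first.cause,
                n_claims=len(group),
            )
        )

    for claim in ordered:
        if group and claim.person_id == group[-1].person_id and (
            (claim.claim_date - group[-1].claim_date).days <= 1
        ):
            group.append(claim)
        else:
            if group:
                _close(group)
            group = [claim]
    if group:
        _close(group)
    return encounters


def aggregate_daily_counts(
    encounters,
    dataset_label: str,
    strict: bool = False,
) -> pd.DataFrame:
    """Count encounters per (date, county, age band, sex, cause, type).

    Records with a missing stratum field are dropped with a logged tally
    (or abort the aggregation in strict mode).  The sum of counts equals
    the number of complete encounters.
    """
    rows = []
    n_bad = 0
    for e in encounters:
        fields = (e.start_date, e.county, e.age_group, e.sex, e.cause, e.type)
        if any(f is None or f == "" for f in fields):
            n_bad += 1
            if strict:
                raise ValueError(f"encounter with missing stratum field: {e}")
            continue
        rows.append(fields)
    if n_bad:
        logger.warning("dropped %d encounters with missing stratum fields", n_bad)

    cols = ["date", "county", "age_group", "sex", "cause", "encounter_type"]
    if not rows:
        return pd.DataFrame(columns=["dataset"] + cols + ["count"])
    df = pd.DataFrame(rows, columns=cols)
    df["date"] = pd.to_datetime(df["date"])
    out = df.groupby(cols, as_index=False).size().rename(columns={"size": "count"})
    out.insert(0, "dataset", dataset_label)
    return out
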