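"""Cognitive-aging pathway assignment from annual diagnosis sequences.

Subjects are classified from the totality of their cognitive diagnoses
(before, during and after sleep/rhythm data collection) into one of three
uni-directional pathways:

* ``normal`` — no dementia diagnosis and never two consecutive MCI years;
* ``stableMCI`` — two consecutive MCI diagnoses at some point, no dementia
  (the consecutive-pair rule filters the ~30-40% of single MCI diagnoses
  that revert to normal cognition);
* ``dementia`` — any dementia diagnosis; a preceding stable-MCI onset is
  recorded when present but is not required.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

DIAGNOSES = ("NCI", "MCI", "dementia")
#: Visits further apart than this do not count as "consecutive years".
MAX_CONSECUTIVE_GAP_YR = 1.5


@dataclass(frozen=True)
class PathwayLabel:
    """A subject's pathway plus the located onset age(s)."""

    pathway: str
    mci_onset_age: float | None = None
    dementia_onset_age: float | None = None
    #: A single MCI diagnosis at the last observed visit of an otherwise
    #: normal subject is classified normal by the literal rule but flagged,
    #: because follow-up may simply have been censored before a second year.
    lone_terminal_mci: bool = False

    def __post_init__(self) -> None:
        if self.pathway not in ("normal", "stableMCI", "dementia"):
            raise ValueError(f"unknown pathway: {self.pathway!r}")
        if self.pathway == "normal" and (
            self.mci_onset_age is not None or self.dementia_onset_age is not None
        ):
            raise ValueError("normal pathway carries no onset ages")
        if self.pathway == "stableMCI" and (
            self.mci_onset_age is None or self.dementia_onset_age is not None
        ):
            raise ValueError("stableMCI requires an MCI onset and no dementia onset")
        if self.pathway == "dementia" and self.dementia_onset_age is None:
            raise ValueError("dementia pathway requires a dementia onset age")


def _first_consecutive_mci(
    ages: Sequence[float],
    dx: Sequence[str],
    max_gap_yr: float,
    before_age: float | None = None,
) -> float | None:
    """Age at the first visit of the earliest consecutive-MCI visit pair."""
    for i in range(len(dx) - 1):
        if dx[i] == "MCI" and dx[i + 1] == "MCI" and ages[i + 1] - ages[i] <= max_gap_yr:
            if before_age is not None and ages[i + 1] >= before_age:
                continue
            return float(ages[i])
    return None


def assign_pathway(
    visits: Iterable[tuple[float, str]],
    max_gap_yr: float = MAX_CONSECUTIVE_GAP_YR,
) -> PathwayLabel:
    """Classify one subject from an ordered (age, diagnosis) sequence.

    The MCI onset is the age at the *first* visit of the earliest pair of
    consecutive MCI visits (visits more than ``max_gap_yr`` apart never form
    a pair).  On the dementia pathway the MCI onset is recorded only when a
    qualifying pair is completed before the first dementia diagnosis.
    """
    pairs = sorted((float(a), str(d)) for a, d in visits)
    if not pairs:
        raise ValueError("at least one visit is required")
    ages = [a for a, _ in pairs]
    dx = [d for _, d in pairs]
    bad = set(dx) - set(DIAGNOSES)
    if bad:
        raise ValueError(f"unknown diagnoses: {sorted(bad)}")

    if "dementia" in dx:
        dem_age = ages[dx.index("dementia")]
        mci = _first_consecutive_mci(ages, dx, max_gap_yr, before_age=dem_age)
        return PathwayLabel("dementia", mci_onset_age=mci, dementia_onset_age=dem_age)

    mci = _first_consecutive_mci(ages, dx, max_gap_yr)
    if mci is not None:
        return PathwayLabel("stableMCI", mci_onset_age=mci)

    return PathwayLabel(
        "normal",
        lone_terminal_mci=(dx[-1] == "MCI"),
    )


def assign_pathways(visits: pd.DataFrame, max_gap_yr: float = MAX_CONSECUTIVE_GAP_YR) -> pd.DataFrame:
    """Vectorise :func:`assign_pathway` over a visit table.

    ``visits`` needs columns ``subject``, ``age``, ``diagnosis``.  Returns one
    row per subject: pathway, onset ages, and the lone-terminal-MCI flag.
    """
    rows = []
    for subject, grp in visits.groupby("subject", sort=True):
        label = assign_pathway(
            zip(grp["age"], grp["diagnosis"]), max_gap_yr=max_gap_yr
        )
        rows.append(
            {
                "subject": subject,
                "pathway": label.pathway,
                "mci_onset_age": label.mci_onset_age,
                "dementia_onset_age": label.dementia_onset_age,
                "lone_terminal_mci": label.lone_terminal_mci,
            }
        )
    return pd.DataFrame(rows)
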