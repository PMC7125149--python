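"""Partition of isoforms into transcriptional/translational regulation states.

An isoform whose total (input) abundance changes between stages is
transcriptionally regulated and excluded from the translational classes.
Among input-stable isoforms, a drop in polysome association from stage A to
stage B marks translational repression and a gain marks derepression;
monosome-only changes form their own reporting class. Isoforms undetected
in total RNA remain eligible for the polysome-based classes — polysome
profiling is more sensitive at low expression than total RNA-seq — and are
flagged so the below-detection subset can be reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Collection, Iterable

import pandas as pd

from .diffexpr import ContrastResult
from .errors import ValidationError

#: Closed vocabulary of regulation states, in classification precedence
#: order (transcriptional first, steady last).
STATES = (
    "transcription_up",
    "transcription_down",
    "repressed",
    "derepressed",
    "monosome_shift",
    "steady",
)

STATE_TABLE_COLUMNS = (
    "input_direction", "monosome_direction", "polysome_direction",
    "detected_in_input", "state",
)


@dataclass(frozen=True)
class StateSummary:
    """Per-state counts plus the derived bookkeeping totals."""

    counts: dict[str, int]
    below_detection_derepressed: int

    @property
    def translationally_altered(self) -> int:
        """Input-stable isoforms whose polysome association changed
        (repressed + derepressed)."""
        return self.counts["repressed"] + self.counts["derepressed"]

    @property
    def n_total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        row = {state: self.counts[state] for state in STATES}
        row["translationally_altered"] = self.translationally_altered
        row["below_detection_derepressed"] = self.below_detection_derepressed
        row["n_total"] = self.n_total
        return pd.DataFrame([row])


def classify_states(input_res: ContrastResult, monosome_res: ContrastResult,
                    polysome_res: ContrastResult, alpha: float = 0.05) -> pd.DataFrame:
    """Assign one regulation state per isoform from three fraction contrasts.

    Decision rules, applied in order:

    1. input direction != none        -> transcription_up / transcription_down
    2. else polysome direction down   -> repressed
    3. else polysome direction up     -> derepressed
    4. else monosome direction != none-> monosome_shift
    5. else                           -> steady

    Transcriptional change takes precedence: an isoform significant in both
    input and polysome is transcriptional, never repressed/derepressed.
    Monosome direction never vetoes a polysome call; it is recorded for
    reporting. Returns a state table indexed by isoform id with columns
    input_direction, monosome_direction, polysome_direction,
    detected_in_input, state.
    """
    idx = input_res.table.index
    for other, name in ((monosome_res, "monosome"), (polysome_res, "polysome")):
        if not idx.equals(other.table.index):
            diff = set(idx).symmetric_difference(other.table.index)
            raise ValidationError(
                f"isoform sets differ between input and {name} contrasts; "
                f"symmetric difference ({len(diff)} ids): {sorted(diff)[:10]}"
            )
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")

    d_in = input_res.directions(alpha)
    d_mono = monosome_res.directions(alpha)
    d_poly = polysome_res.directions(alpha)
    # "detected in input" = detected at either stage of the total-RNA fraction
    detected = input_res.table["detected_A"] | input_res.table["detected_B"]

    state = pd.Series("steady", index=idx, name="state")
    state[d_mono != "none"] = "monosome_shift"
    state[d_poly == "up"] = "derepressed"
    state[d_poly == "down"] = "repressed"
    state[d_in == "up"] = "transcription_up"
    state[d_in == "down"] = "transcription_down"

    return pd.DataFrame(
        {
            "input_direction": d_in,
            "monosome_direction": d_mono,
            "polysome_direction": d_poly,
            "detected_in_input": detected,
            "state": state,
        },
        index=idx,
    )[list(STATE_TABLE_COLUMNS)]


def summarize_states(table: pd.DataFrame) -> StateSummary:
    """Count isoforms per state and derive the bookkeeping totals."""
    if "state" not in table.columns:
        raise ValidationError("state table must have a 'state' column")
    unknown = set(table["state"]) - set(STATES)
    if unknown:
        raise ValidationError(f"unknown states in table: {sorted(unknown)}")
    vc = table["state"].value_counts()
    counts = {state: int(vc.get(state, 0)) for state in STATES}
    if "detected_in_input" in table.columns:
        below = int(((table["state"] == "derepressed")
                     & ~table["detected_in_input"].astype(bool)).sum())
    else:
        below = 0
    return StateSummary(counts=counts, below_detection_derepressed=below)


def crossref_sets(ids: Iterable[str], annotation_set: Collection[str]) -> tuple[int, list[str]]:
    """Overlap bookkeeping between an isoform/gene id list and an annotation set.

    Case-sensitive exact matching; duplicates collapsed. Returns the overlap
    count and the sorted intersected ids.
    """
    members = sorted(set(ids) & set(annotation_set))
    return len(members), members
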