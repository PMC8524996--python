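"""Pre/post-CAD decision-transition analysis.

When a reader re-reads an image with the CAD output visible, the case
state can flip.  Four (CAD state, pre-CAD state) combinations are
discordant and therefore informative about the CAD's influence:

====================  ==================  =================
CAD case state        reader before CAD   tracked flip
====================  ==================  =================
TP                    FN                  FN -> TP
TN                    FP                  FP -> TN
FN                    TP                  TP -> FN
FP                    TN                  TN -> FP
====================  ==================  =================

Concordant combinations (reader and CAD agree in correctness) are tallied
in a single auxiliary count so that every image is conserved.  "Changed"
means the case state flipped; box edits that leave the state unchanged do
not count.  Group switch rates are changed/(changed+unchanged) on counts
summed within a reader group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .classify import AnnotationSet, CaseOutcome, ImageRecord, classify_study
from .geometry import MatchPolicy
from .metrics import round_half_up

__all__ = [
    "TRANSITION_CELLS",
    "TransitionTable",
    "cad_case_outcomes",
    "transition_table",
    "switch_rates",
    "transition_frame",
]

# (cad_state, before_state) -> the flipped after-state
TRANSITION_CELLS: dict[tuple[str, str], str] = {
    ("TP", "FN"): "TP",
    ("TN", "FP"): "TN",
    ("FN", "TP"): "FN",
    ("FP", "TN"): "FP",
}
# display order of the eight count columns
CELL_ORDER = (("TP", "FN"), ("TN", "FP"), ("FN", "TP"), ("FP", "TN"))


@dataclass(frozen=True)
class TransitionTable:
    """Per-reader transition counts conditioned on CAD case correctness.

    ``cells`` maps each tracked (cad_state, before_state) pair to
    ``(changed, unchanged)``; ``concordant`` counts all other combinations.
    """

    reader_id: str
    cells: dict[tuple[str, str], tuple[int, int]]
    concordant: int
    n_images: int

    def __post_init__(self) -> None:
        tallied = sum(c + u for c, u in self.cells.values()) + self.concordant
        if tallied != self.n_images:
            raise ValueError(
                f"{self.reader_id}: transition cells tally {tallied} "
                f"but the study has {self.n_images} images"
            )


def cad_case_outcomes(
    images: Sequence[ImageRecord],
    cad_annotations: AnnotationSet,
    policy: MatchPolicy = MatchPolicy(),
) -> list[CaseOutcome]:
    """Case-level outcomes for the standalone CAD arm."""
    if cad_annotations.arm != "cad":
        raise ValueError(
            f"expected a CAD annotation set, got arm {cad_annotations.arm!r}"
        )
    return classify_study(images, cad_annotations, policy)


def _states_by_image(outcomes: Sequence[CaseOutcome]) -> dict[str, str]:
    return {o.image_id: o.state for o in outcomes}


def transition_table(
    pre: Sequence[CaseOutcome],
    post: Sequence[CaseOutcome],
    cad: Sequence[CaseOutcome],
    reader_id: str,
) -> TransitionTable:
    """Tally one reader's decision transitions against the CAD's states.

    The three outcome lists must cover an identical image set.  An
    after-state that is neither the before-state nor its tracked flip is an
    input-consistency error (a case can only move between the two states
    admissible for its label).
    """
    pre_s, post_s, cad_s = map(_states_by_image, (pre, post, cad))
    if not (pre_s.keys() == post_s.keys() == cad_s.keys()):
        raise ValueError(
            f"{reader_id}: pre/post/CAD outcome lists cover different images"
        )
    cells = {pair: [0, 0] for pair in TRANSITION_CELLS}
    concordant = 0
    for image_id in sorted(pre_s):
        before, after, cad_state = pre_s[image_id], post_s[image_id], cad_s[image_id]
        flip = {"TP": "FN", "FN": "TP", "TN": "FP", "FP": "TN"}[before]
        if after not in (before, flip):
            raise ValueError(
                f"{reader_id}/{image_id}: inadmissible transition "
                f"{before} -> {after}"
            )
        pair = (cad_state, before)
        if pair in cells:
            if after == flip:
                cells[pair][0] += 1
            else:
                cells[pair][1] += 1
        else:
            concordant += 1
    return TransitionTable(
        reader_id=reader_id,
        cells={pair: (c, u) for pair, (c, u) in cells.items()},
        concordant=concordant,
        n_images=len(pre_s),
    )


@dataclass(frozen=True)
class SwitchRateCell:
    changed: int
    unchanged: int

    @property
    def total(self) -> int:
        return self.changed + self.unchanged

    @property
    def proportion(self) -> Optional[float]:
        return self.changed / self.total if self.total else None

    @property
    def proportion_2dp(self) -> Optional[float]:
        p = self.proportion
        return None if p is None else round_half_up(p, 2)


def switch_rates(
    tables: Sequence[TransitionTable],
    groups: Mapping[str, str],
) -> dict[str, dict[tuple[str, str], SwitchRateCell]]:
    """Group-level switch rates: summed counts and changed/(changed+unchanged).

    ``groups`` maps reader_id to group name.  A cell with an empty
    denominator yields a ``None`` proportion (undefined flag).
    """
    if not tables:
        raise ValueError("switch_rates needs at least one transition table")
    unknown = sorted({t.reader_id for t in tables} - set(groups))
    if unknown:
        raise ValueError(f"readers without a group assignment: {unknown}")
    out: dict[str, dict[tuple[str, str], SwitchRateCell]] = {}
    for g in sorted(set(groups[t.reader_id] for t in tables)):
        cells = {}
        for pair in TRANSITION_CELLS:
            changed = sum(
                t.cells[pair][0] for t in tables if groups[t.reader_id] == g
            )
            unchanged = sum(
                t.cells[pair][1] for t in tables if groups[t.reader_id] == g
            )
            cells[pair] = SwitchRateCell(changed, unchanged)
        out[g] = cells
    return out


def transition_frame(
    tables: Sequence[TransitionTable],
    groups: Mapping[str, str],
) -> pd.DataFrame:
    """Transition report: one row per reader plus group-total rows.

    Eight count columns ordered (CAD TP: changed, unchanged), (CAD TN: …),
    (CAD FN: …), (CAD FP: …).
    """
    def columns_for(cells: Mapping[tuple[str, str], tuple[int, int]]) -> dict:
        row = {}
        for cad_state, before in CELL_ORDER:
            c, u = cells[(cad_state, before)]
            row[f"cad_{cad_state}_{before}_changed"] = c
            row[f"cad_{cad_state}_{before}_unchanged"] = u
        return row

    rows = []
    for t in sorted(tables, key=lambda t: (groups[t.reader_id], t.reader_id)):
        rows.append(
            {"reader_id": t.reader_id, "group": groups[t.reader_id]}
            | columns_for(t.cells)
        )
    for g, cells in switch_rates(tables, groups).items():
        rows.append(
            {"reader_id": f"all_{g}", "group": g}
            | columns_for({p: (c.changed, c.unchanged) for p, c in cells.items()})
        )
    return pd.DataFrame(rows)
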