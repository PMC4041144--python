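"""Parsimony mapping of coded indel characters onto a fixed species tree.

Each binary gap character is mapped by small parsimony (Fitch score;
Sankoff dynamic programming for placement). The root state is anchored to
the outgroup's observed state, which never increases the minimal change
count because the outgroup subtends the root directly. Among equally
parsimonious reconstructions the derived state is assigned as deep in the
tree as possible, so the first origin of a gap variant lands on the branch
subtending the largest clade in which the variant predominates; any
additional origins or reversals of the same variant are separate events.
Characters needing more than one event are treated as homoplasious and all
their events are flagged.

Polarity: with the root anchored to the outgroup, a 0-to-1 change (gap
gained) is a deletion and a 1-to-0 change (residues gained) an insertion.
When the outgroup itself is unobservable ('?') polarity is reported as
"unresolved", never guessed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import InvariantCharacterError
from .indel_coding import (
    STATE_ABSENT,
    STATE_GAP,
    STATE_INAPPLICABLE,
    GapBlock,
    IndelCharacterMatrix,
)
from .io_formats import Node, Phylogeny

INSERTION = "insertion"
DELETION = "deletion"
UNRESOLVED = "unresolved"

_STATES = (STATE_ABSENT, STATE_GAP)


@dataclass
class IndelEvent:
    """A single inferred insertion/deletion on a branch of the tree."""

    character_id: str
    branch: str  # child-node label of the edge carrying the event
    kind: str  # insertion | deletion | unresolved
    length_nt: int
    homoplasious: bool
    region_label: str

    @property
    def label(self) -> str:
        return f"{self.region_label}-{self.length_nt}"


def _check_observed_variation(states: dict[str, str]) -> None:
    observed = {s for s in states.values() if s != STATE_INAPPLICABLE}
    if len(observed) < 2:
        raise InvariantCharacterError(
            f"character invariant across observed taxa (states {sorted(observed)})"
        )


def fitch_states(
    states: dict[str, str], tree: Phylogeny
) -> tuple[int, dict[str, set[str]]]:
    """Fitch small-parsimony score and per-node state sets.

    ``states`` maps tip label to '0', '1' or '?'; '?' tips contribute the
    full state set. Raises :class:`InvariantCharacterError` when the
    character does not vary among observed taxa.
    """
    _check_observed_variation(states)
    score = 0
    sets: dict[str, set[str]] = {}
    for node in tree.postorder():
        if node.is_tip:
            s = states[node.name]
            sets[node.name] = set(_STATES) if s == STATE_INAPPLICABLE else {s}
        else:
            inter = set(_STATES)
            union: set[str] = set()
            for c in node.children:
                inter &= sets[c.name]
                union |= sets[c.name]
            if inter:
                sets[node.name] = inter
            else:
                sets[node.name] = union
                score += 1
    return score, sets


def _sankoff_costs(
    states: dict[str, str], tree: Phylogeny
) -> dict[str, dict[str, float]]:
    """Minimal change count below each node, per assigned node state."""
    cost: dict[str, dict[str, float]] = {}
    for node in tree.postorder():
        if node.is_tip:
            s = states[node.name]
            if s == STATE_INAPPLICABLE:
                cost[node.name] = {a: 0.0 for a in _STATES}
            else:
                cost[node.name] = {
                    a: (0.0 if a == s else math.inf) for a in _STATES
                }
        else:
            cost[node.name] = {}
            for a in _STATES:
                total = 0.0
                for c in node.children:
                    total += min(
                        cost[c.name][b] + (0.0 if b == a else 1.0)
                        for b in _STATES
                    )
                cost[node.name][a] = total
    return cost


def place_events(
    block: GapBlock,
    tree: Phylogeny,
    *,
    character_id: str | None = None,
) -> list[IndelEvent]:
    """Place the minimal set of indel events for one coded gap character.

    The number of events always equals the Fitch score. The root state is
    the outgroup's state when observed (polarity resolved), otherwise the
    cheaper parsimony state (polarity reported as unresolved).
    """
    states = dict(block.presence)
    score, _ = fitch_states(states, tree)
    cost = _sankoff_costs(states, tree)

    og_state = states.get(tree.outgroup, STATE_INAPPLICABLE)
    polarized = og_state != STATE_INAPPLICABLE
    root_costs = cost[tree.root.name]
    if polarized:
        root_state = og_state
    else:
        # cheaper state; tie resolved toward 'no gap'
        root_state = min(_STATES, key=lambda a: (root_costs[a], a != STATE_ABSENT))
    derived = STATE_GAP if root_state == STATE_ABSENT else STATE_ABSENT

    assignment: dict[str, str] = {tree.root.name: root_state}
    changes: list[tuple[Node, str, str]] = []
    for node in tree.preorder():
        for child in node.children:
            parent_state = assignment[node.name]
            best = min(
                cost[child.name][b] + (0.0 if b == parent_state else 1.0)
                for b in _STATES
            )
            candidates = [
                b
                for b in _STATES
                if cost[child.name][b] + (0.0 if b == parent_state else 1.0)
                == best
            ]
            if len(candidates) > 1:
                # tie: push the derived variant as deep as possible so its
                # first origin subtends the largest clade carrying it
                chosen = derived if derived in candidates else candidates[0]
            else:
                chosen = candidates[0]
            assignment[child.name] = chosen
            if chosen != parent_state:
                changes.append((child, parent_state, chosen))

    assert len(changes) == score, "event count must equal the Fitch score"
    homoplasious = score > 1
    cid = character_id or block.label
    events = []
    for child, from_state, to_state in changes:
        if not polarized:
            kind = UNRESOLVED
        elif from_state == STATE_ABSENT and to_state == STATE_GAP:
            kind = DELETION
        else:
            kind = INSERTION
        events.append(
            IndelEvent(
                character_id=cid,
                branch=child.name,
                kind=kind,
                length_nt=block.length_nt,
                homoplasious=homoplasious,
                region_label=block.region_label,
            )
        )
    return events


def polarize(
    from_state: str, to_state: str, outgroup_state: str
) -> str:
    """Polarity of a single state change given the outgroup's state.

    A gap gained (0 to 1) is a deletion; residues gained (1 to 0) an
    insertion; unresolved when the outgroup is unobservable.
    """
    if outgroup_state == STATE_INAPPLICABLE:
        return UNRESOLVED
    if from_state == STATE_ABSENT and to_state == STATE_GAP:
        return DELETION
    return INSERTION


def map_all_events(
    matrix: IndelCharacterMatrix, tree: Phylogeny
) -> tuple[list[IndelEvent], list[str]]:
    """Map every coded character; invariant characters are skipped and
    returned by label."""
    events: list[IndelEvent] = []
    skipped: list[str] = []
    for block in matrix.blocks:
        try:
            events.extend(place_events(block, tree))
        except InvariantCharacterError:
            skipped.append(block.label)
    return events, skipped


@dataclass
class EventSummary:
    """Aggregate indel-event counts with internal consistency checks."""

    total_events: int
    unique_events: int
    homoplasious_events: int
    terminal_events: int
    internal_events: int
    insertions: int
    deletions: int
    unresolved: int
    per_branch: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.unique_events + self.homoplasious_events == self.total_events
        assert self.terminal_events + self.internal_events == self.total_events
        assert (
            self.insertions + self.deletions + self.unresolved
            == self.total_events
        )
        assert sum(self.per_branch.values()) == self.total_events


def summarize_events(events: list[IndelEvent], tree: Phylogeny) -> EventSummary:
    tips = set(tree.tip_labels())
    per_branch: dict[str, int] = {}
    for e in events:
        per_branch[e.branch] = per_branch.get(e.branch, 0) + 1
    return EventSummary(
        total_events=len(events),
        unique_events=sum(not e.homoplasious for e in events),
        homoplasious_events=sum(e.homoplasious for e in events),
        terminal_events=sum(e.branch in tips for e in events),
        internal_events=sum(e.branch not in tips for e in events),
        insertions=sum(e.kind == INSERTION for e in events),
        deletions=sum(e.kind == DELETION for e in events),
        unresolved=sum(e.kind == UNRESOLVED for e in events),
        per_branch=per_branch,
    )


def events_to_frame(events: list[IndelEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "character": e.character_id,
                "branch": e.branch,
                "kind": e.kind,
                "length_nt": e.length_nt,
                "homoplasious": e.homoplasious,
                "label": e.label,
            }
            for e in events
        ],
        columns=["character", "branch", "kind", "length_nt", "homoplasious", "label"],
    )


def annotated_newick(tree: Phylogeny, events: list[IndelEvent]) -> str:
    """Newick with NHX-style per-branch event annotations for plotting."""
    by_branch: dict[str, list[IndelEvent]] = {}
    for e in events:
        by_branch.setdefault(e.branch, []).append(e)

    def annot(node: Node) -> str:
        evs = by_branch.get(node.name, [])
        if not evs:
            return ""
        tags = "/".join(
            ("+" if e.kind == INSERTION else "-" if e.kind == DELETION else "~")
            + e.label
            + ("*" if e.homoplasious else "")
            for e in evs
        )
        return f"[&&NHX:indels={tags}]"

    def rec(node: Node) -> str:
        if node.is_tip:
            return f"{node.name}:{node.length:.10g}{annot(node)}"
        inner = ",".join(rec(c) for c in node.children)
        if node.parent is None:
            return f"({inner}){node.name}"
        return f"({inner}){node.name}:{node.length:.10g}{annot(node)}"

    return rec(tree.root) + ";"
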