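import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import exhaustive_parsimony_score
from conftest import make_alignment
from phyloindel import (
    Phylogeny,
    code_indels,
    find_gap_blocks,
    fitch_states,
    map_all_events,
    place_events,
    polarize,
    summarize_events,
)
from phyloindel.errors import InvariantCharacterError
from phyloindel.indel_coding import GapBlock
from phyloindel.indel_events import DELETION, INSERTION, UNRESOLVED
from phyloindel.synthetic_data import SimulationConfig, simulate_tree

QUARTET = Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


def block(states: dict[str, str], span=(4, 6), label="R1") -> GapBlock:
    return GapBlock(span[0], span[1], region_label=label, presence=dict(states))


class TestFitch:
    def test_clean_clade_needs_one_change(self):
        score, _ = fitch_states({"A": "1", "B": "1", "C": "0", "D": "0"}, QUARTET)
        assert score == 1

    def test_convergent_pattern_needs_two_changes(self):
        score, _ = fitch_states({"A": "1", "B": "0", "C": "1", "D": "0"}, QUARTET)
        assert score == 2

    def test_invariant_character_rejected(self):
        with pytest.raises(InvariantCharacterError):
            fitch_states({"A": "1", "B": "1", "C": "1", "D": "?"}, QUARTET)

    @settings(deadline=None, max_examples=60)
    @given(data=st.data())
    def test_score_matches_exhaustive_enumeration(self, data):
        n = data.draw(st.integers(4, 8))
        seed = data.draw(st.integers(0, 10_000))
        tree = simulate_tree(SimulationConfig(n_species=n), seed=seed)
        labels = tree.tip_labels()
        states = {
            t: data.draw(st.sampled_from("01?"), label=t) for t in labels
        }
        observed = {s for s in states.values() if s != "?"}
        if len(observed) < 2:
            states[labels[0]], states[labels[1]] = "0", "1"
        score, _ = fitch_states(states, tree)
        assert score == exhaustive_parsimony_score(tree, states)


class TestPlacement:
    TREE = Phylogeny.from_newick(
        "(((A:1,B:1):1,(C:1,D:1):1):1,O:3);", outgroup="O"
    )

    def test_clean_clade_single_event_on_stem(self):
        events = place_events(
            block({"A": "1", "B": "1", "C": "0", "D": "0", "O": "0"}), self.TREE
        )
        assert len(events) == 1
        ev = events[0]
        assert not ev.homoplasious
        assert ev.kind == DELETION
        # the branch subtends exactly the {A,B} clade
        node = self.TREE.node(ev.branch)
        assert sorted(
            t.name for t in self.TREE.prune_to(["A", "B"]).tips()
        ) == ["A", "B"]
        assert {c.name for c in node.children} == {"A", "B"}

    def test_convergent_variant_gives_two_homoplasious_terminal_events(self):
        events = place_events(
            block({"A": "1", "B": "0", "C": "1", "D": "0", "O": "0"}), self.TREE
        )
        assert len(events) == 2
        assert {e.branch for e in events} == {"A", "C"}
        assert all(e.homoplasious for e in events)

    def test_preponderant_clade_takes_the_deep_origin(self):
        # three of four clade members share the gap: one deep origin on the
        # clade stem plus a reversal in D beats two shallow origins
        events = place_events(
            block({"A": "1", "B": "1", "C": "1", "D": "0", "O": "0"}), self.TREE
        )
        assert len(events) == 2
        branches = {e.branch for e in events}
        ingroup_stem = [
            c.name for c in self.TREE.root.children if c.name != "O"
        ][0]
        assert ingroup_stem in branches
        assert "D" in branches

    def test_event_count_equals_fitch_score_on_simulated_characters(
        self, default_species_alignment, default_study
    ):
        aln, _ = default_species_alignment
        tree = default_study["tree"]
        matrix = code_indels(find_gap_blocks(aln), aln)
        for blk in matrix.blocks:
            try:
                score, _ = fitch_states(blk.presence, tree)
            except InvariantCharacterError:
                continue
            events = place_events(blk, tree)
            assert len(events) == score


class TestPolarity:
    TREE = TestPlacement.TREE

    def test_outgroup_without_gap_polarizes_deletion(self):
        assert polarize("0", "1", "0") == DELETION

    def test_outgroup_with_gap_polarizes_insertion(self):
        events = place_events(
            block({"A": "0", "B": "0", "C": "0", "D": "0", "O": "1"}), self.TREE
        )
        assert len(events) == 1
        assert events[0].kind == INSERTION

    def test_unobservable_outgroup_reports_unresolved(self):
        events = place_events(
            block({"A": "1", "B": "1", "C": "0", "D": "0", "O": "?"}), self.TREE
        )
        assert all(e.kind == UNRESOLVED for e in events)


class TestSummary:
    def test_empty_event_list_gives_zero_summary(self, five_taxon_tree):
        s = summarize_events([], five_taxon_tree)
        assert s.total_events == 0
        assert s.insertions == s.deletions == s.unresolved == 0

    def test_identities_hold_on_simulated_data(
        self, default_species_alignment, default_study
    ):
        aln, _ = default_species_alignment
        tree = default_study["tree"]
        matrix = code_indels(find_gap_blocks(aln), aln)
        events, skipped = map_all_events(matrix, tree)
        s = summarize_events(events, tree)  # __post_init__ asserts identities
        assert s.total_events == len(events)
        truth = default_study["truth"]
        assert s.total_events + len(skipped) >= len(truth.events) * 0.9

    def test_events_invariant_to_taxon_input_order(
        self, default_species_alignment, default_study
    ):
        aln, _ = default_species_alignment
        tree = default_study["tree"]

        def run(a):
            m = code_indels(find_gap_blocks(a), a)
            events, _ = map_all_events(m, tree)
            return sorted(
                (e.character_id, e.branch, e.kind, e.length_nt) for e in events
            )

        shuffled = make_alignment(
            {
                r.id: r.seq
                for r in random.Random(3).sample(aln.records, len(aln.records))
            }
        )
        assert run(aln) == run(shuffled)


def test_end_to_end_event_totals_match_ground_truth():
    """At default settings the parsimony map recovers the simulator's
    realized event count in nearly every run (span collisions can merge)."""
    hits = 0
    n_seeds = 8
    from phyloindel import simulate_study, species_consensus_alignment

    for seed in range(n_seeds):
        study = simulate_study(seed=100 + seed)
        aln, _ = species_consensus_alignment(study["alignment"])
        matrix = code_indels(find_gap_blocks(aln), aln)
        events, skipped = map_all_events(matrix, study["tree"])
        if len(events) == len(study["truth"].events):
            hits += 1
    assert hits >= int(0.9 * n_seeds)
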