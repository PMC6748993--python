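"""Synteny chaining and karyotype-event detection, with a brute-force oracle."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import zwscout as zw
from zwscout.simulate import ANCHOR_COLUMNS
from zwscout.synteny import KaryotypeEvent, SyntenyBlock


def anchors_df(rows):
    """rows: (query_id, query_pos, ref_chrom, ref_pos[, strand])."""
    recs = [
        dict(zip(ANCHOR_COLUMNS, list(r) + (["+"] if len(r) == 4 else [])))
        for r in rows
    ]
    return pd.DataFrame(recs, columns=ANCHOR_COLUMNS)


# ---------------------------------------------------------------------------
# Brute-force oracle: longest valid prefix by definition-checking slices
# ---------------------------------------------------------------------------


def _slice_is_valid_run(rows, max_gap) -> bool:
    refs = {r[1] for r in rows}
    if len(refs) != 1:
        return False
    for a, b in zip(rows, rows[1:]):
        if b[0] - a[0] > max_gap:
            return False
    steps = [np.sign(b[2] - a[2]) for a, b in zip(rows, rows[1:])]
    nonzero = [s for s in steps if s != 0]
    return len(set(nonzero)) <= 1


def brute_blocks(anchors: pd.DataFrame, min_block_anchors: int, max_gap: int):
    """Partition each query's sorted anchors into greedy-longest valid runs,
    validity checked from scratch on every candidate slice."""
    df = anchors.sort_values(ANCHOR_COLUMNS, kind="stable")
    out = []
    for query_id, grp in df.groupby("query_id", sort=True):
        rows = list(zip(grp["query_pos"].astype(int), grp["ref_chrom"],
                        grp["ref_pos"].astype(int)))
        i = 0
        while i < len(rows):
            # longest valid prefix starting at i, checked from scratch
            j = i
            while j + 1 < len(rows) and _slice_is_valid_run(rows[i : j + 2], max_gap):
                j += 1
            run = rows[i : j + 1]
            if len(run) >= min_block_anchors:
                qpos = [r[0] for r in run]
                rpos = [r[2] for r in run]
                nonzero = [np.sign(b[2] - a[2]) for a, b in zip(run, run[1:])
                           if b[2] != a[2]]
                out.append(
                    (query_id, qpos[0], qpos[-1] + 1, run[0][1], min(rpos),
                     max(rpos) + 1, "-" if (nonzero and nonzero[0] < 0) else "+",
                     len(run))
                )
            i = j + 1
    return sorted(out)


def brute_events(blocks, min_support):
    """Event calls re-derived with plain dictionaries."""
    per_query: dict[str, dict[str, int]] = {}
    per_ref: dict[str, dict[str, int]] = {}
    for b in blocks:
        per_query.setdefault(b.query_id, {}).setdefault(b.ref_chrom, 0)
        per_query[b.query_id][b.ref_chrom] += b.n_anchors
        per_ref.setdefault(b.ref_chrom, {}).setdefault(b.query_id, 0)
        per_ref[b.ref_chrom][b.query_id] += b.n_anchors
    fusions = set()
    for q, refs in per_query.items():
        good = tuple(sorted(r for r, n in refs.items() if n >= min_support))
        if len(good) >= 2:
            fusions.add((q, good))
    fissions = set()
    for r, queries in per_ref.items():
        good = tuple(sorted(q for q, n in queries.items() if n >= min_support))
        if len(good) >= 2:
            fissions.add((r, good))
    return fusions, fissions


def as_tuples(blocks):
    return sorted(
        (b.query_id, b.query_start, b.query_end, b.ref_chrom, b.ref_start,
         b.ref_end, b.orientation, b.n_anchors)
        for b in blocks
    )


# ---------------------------------------------------------------------------
# Hand-derived cases
# ---------------------------------------------------------------------------


class TestChaining:
    def test_two_ref_runs_give_two_blocks(self):
        rows = [("q", i * 10, "refA", i * 5) for i in range(10)]
        rows += [("q", 100 + i * 10, "refB", i * 5) for i in range(10)]
        blocks = zw.chain_anchors(anchors_df(rows), min_block_anchors=3, max_gap=1000)
        assert [(b.ref_chrom, b.n_anchors) for b in blocks] == [("refA", 10), ("refB", 10)]

    def test_collinear_anchors_one_block(self):
        rows = [("q", i * 7, "refA", 1000 - i * 3) for i in range(12)]
        blocks = zw.chain_anchors(anchors_df(rows))
        assert len(blocks) == 1
        assert blocks[0].n_anchors == 12
        assert blocks[0].orientation == "-"

    def test_stray_anchor_below_support_dropped(self):
        rows = [("q", i * 10, "refA", i * 5) for i in range(5)]
        rows.insert(3, ("q", 25, "refC", 999))
        blocks = zw.chain_anchors(anchors_df(rows), min_block_anchors=3)
        assert {b.ref_chrom for b in blocks} == {"refA"}

    def test_empty_input_empty_output(self):
        assert zw.chain_anchors(anchors_df([])) == []

    def test_gap_splits_runs(self):
        rows = [("q", i * 10, "refA", i * 5) for i in range(4)]
        rows += [("q", 5000 + i * 10, "refA", 200 + i * 5) for i in range(4)]
        blocks = zw.chain_anchors(anchors_df(rows), min_block_anchors=3, max_gap=100)
        assert len(blocks) == 2

    def test_negative_positions_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            zw.chain_anchors(anchors_df([("q", -1, "refA", 5)]))


class TestEvents:
    def test_one_to_one_blocks_no_events(self):
        rows = [("q1", i * 10, "refA", i * 5) for i in range(5)]
        rows += [("q2", i * 10, "refB", i * 5) for i in range(5)]
        blocks = zw.chain_anchors(anchors_df(rows))
        assert zw.detect_events(blocks) == []

    def test_fission_split_across_two_queries(self):
        """refX hosted on two query scaffolds (plus 1:1 controls) yields
        exactly one fission naming both scaffolds."""
        rows = [("q1", i * 10, "refX", i * 5) for i in range(4)]
        rows += [("q2", i * 10, "refX", 500 + i * 5) for i in range(4)]
        rows += [("q3", i * 10, "refA", i * 5) for i in range(4)]
        rows += [("q4", i * 10, "refB", i * 5) for i in range(4)]
        events = zw.detect_events(zw.chain_anchors(anchors_df(rows)))
        assert len(events) == 1
        assert events[0].type == "fission"
        assert events[0].host == "refX"
        assert events[0].members == ("q1", "q2")

    def test_fusion_breakpoint_is_block_gap(self):
        rows = [("q", i * 10, "refA", i * 5) for i in range(5)]        # ends 41
        rows += [("q", 100 + i * 10, "refB", i * 5) for i in range(5)]  # starts 100
        events = zw.detect_events(zw.chain_anchors(anchors_df(rows)))
        assert len(events) == 1
        assert events[0].type == "fusion"
        assert events[0].breakpoints == ((41, 100),)
        assert events[0].support == 5

    def test_default_simulation_three_fusions(self, default_anchors, default_depth):
        _, truth = default_depth
        blocks = zw.chain_anchors(default_anchors)
        events = zw.detect_events(blocks)
        fusions = [e for e in events if e.type == "fusion"]
        fissions = [e for e in events if e.type == "fission"]
        assert len(fusions) == 3
        assert len(fissions) == 0
        found = {frozenset(e.members) for e in fusions}
        assert found == set(truth.fusion_events_true)

    def test_conservation_against_model(self, default_anchors, default_model):
        """Chromosome count from events equals the model's non-W scaffold
        count for the simulated anchor map."""
        events = zw.detect_events(zw.chain_anchors(default_anchors))
        n_query, _ = zw.karyotype_count(default_model.config.ancestral_n, events)
        assert n_query == sum(1 for s in default_model.scaffolds if s.cls != "W")


class TestKaryotypeCount:
    def ev(self, type_, members, host="h"):
        return KaryotypeEvent(type_, tuple(sorted(members)), host, (), 3)

    def test_three_fusions_from_31_gives_28(self):
        events = [self.ev("fusion", ["a", "b"]), self.ev("fusion", ["c", "d"]),
                  self.ev("fusion", ["e", "f"])]
        n, tally = zw.karyotype_count(31, events)
        assert n == 28
        assert tally["n_fusions"] == 3

    def test_identity_without_events(self):
        assert zw.karyotype_count(31, [])[0] == 31

    def test_mixed_events_arithmetic(self):
        events = [self.ev("fusion", ["a", "b"]), self.ev("fission", ["q1", "q2"]),
                  self.ev("fission", ["q3", "q4"])]
        assert zw.karyotype_count(5, events)[0] == 6

    def test_inconsistent_event_set_rejected(self):
        events = [self.ev("fusion", ["a", "b", "c"])]
        with pytest.raises(ValueError, match="inconsistent"):
            zw.karyotype_count(2, events)
        with pytest.raises(ValueError, match="n_ref"):
            zw.karyotype_count(0, [])


class TestOxfordGrid:
    def test_midpoints(self):
        blocks = [
            SyntenyBlock("q", 0, 100, "refA", 0, 50, "+", 5),
            SyntenyBlock("q", 200, 300, "refB", 10, 110, "-", 4),
        ]
        grid = zw.oxford_grid(blocks)
        assert grid["query_mid"].tolist() == [50.0, 250.0]
        assert grid["ref_mid"].tolist() == [25.0, 60.0]

    def test_empty_blocks_empty_table_with_header(self):
        grid = zw.oxford_grid([])
        assert len(grid) == 0
        assert list(grid.columns) == [
            "query_id", "query_mid", "ref_chrom", "ref_mid", "orientation", "n_anchors"
        ]

    def test_default_simulation_covers_all_ancestral_chromosomes(
        self, default_anchors, default_config
    ):
        grid = zw.oxford_grid(zw.chain_anchors(default_anchors))
        assert set(grid["ref_chrom"]) == set(default_config.ancestral_ids())


# ---------------------------------------------------------------------------
# Property-based checks
# ---------------------------------------------------------------------------

anchor_rows = st.lists(
    st.tuples(
        st.sampled_from(["q1", "q2"]),
        st.integers(min_value=0, max_value=1000),
        st.sampled_from(["r1", "r2", "r3", "r4"]),
        st.integers(min_value=0, max_value=500),
    ),
    min_size=0,
    max_size=30,
)


class TestOracleEquivalence:
    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(rows=anchor_rows, min_n=st.sampled_from([2, 3]),
           max_gap=st.sampled_from([50, 200, 2000]))
    def test_chain_and_detect_match_brute_force(self, rows, min_n, max_gap):
        df = anchors_df(rows)
        blocks = zw.chain_anchors(df, min_block_anchors=min_n, max_gap=max_gap)
        assert as_tuples(blocks) == brute_blocks(df, min_n, max_gap)
        events = zw.detect_events(blocks, min_support=3)
        fusions = {(e.host, e.members) for e in events if e.type == "fusion"}
        fissions = {(e.host, e.members) for e in events if e.type == "fission"}
        bf_fusions, bf_fissions = brute_events(blocks, 3)
        assert fusions == bf_fusions
        assert fissions == bf_fissions

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(rows=anchor_rows, seed=st.integers(min_value=0, max_value=2**16))
    def test_permutation_invariance(self, rows, seed):
        """Shuffling anchor row order never changes the event list."""
        df = anchors_df(rows)
        shuffled = df.sample(frac=1.0, random_state=seed).reset_index(drop=True)
        assert zw.detect_events(zw.chain_anchors(df)) == zw.detect_events(
            zw.chain_anchors(shuffled)
        )


class TestRobustness:
    def test_fusion_recovery_under_spurious_anchors(self):
        """With 5% spurious anchors the three planted fusions are recovered
        exactly in >= 95% of 100 seeded replicates."""
        model = zw.build_genome_model(zw.SimConfig(seed=0))
        true_sets = set(model.truth().fusion_events_true)
        hits = 0
        for seed in range(100):
            anchors = zw.emit_anchor_map(model, spurious_fraction=0.05, seed=seed)
            events = zw.detect_events(zw.chain_anchors(anchors))
            fusions = {frozenset(e.members) for e in events if e.type == "fusion"}
            hits += fusions == true_sets
        assert hits >= 95
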