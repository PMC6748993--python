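"""Synteny-anchor chaining and karyotype-event detection.

Ortholog anchors (query position -> reference chromosome + position) are
chained into collinear blocks; the block composition of each query scaffold
then reveals chromosome fusions (one query scaffold hosting blocks from two
or more ancestral chromosomes) and fissions (one ancestral chromosome split
across several query scaffolds).  The haploid chromosome number follows by
simple arithmetic: n_query = n_ref - fusion merges + fission splits.

The anchor table is the input contract: any whole-genome aligner's output
can be reduced to (query_id, query_pos, ref_chrom, ref_pos, strand) rows.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .simulate import ANCHOR_COLUMNS


@dataclass(frozen=True)
class SyntenyBlock:
    """A maximal collinear run of anchors on one query scaffold mapping to
    one reference chromosome (intervals half-open, orientation from the
    monotone direction of reference positions)."""

    query_id: str
    query_start: int
    query_end: int
    ref_chrom: str
    ref_start: int
    ref_end: int
    orientation: str
    n_anchors: int


@dataclass(frozen=True)
class KaryotypeEvent:
    """A fusion (several reference chromosomes on one query scaffold) or
    fission (one reference chromosome across several query scaffolds).

    ``breakpoints`` are intervals (gaps between flanking blocks), never
    point estimates; ``support`` is the smallest anchor count among the
    participating members.
    """

    type: str  # 'fusion' | 'fission'
    members: tuple[str, ...]
    host: str
    breakpoints: tuple[tuple[int, int], ...]
    support: int

    @property
    def merges(self) -> int:
        """Chromosome-count change contributed by this event."""
        return len(self.members) - 1


def _sorted_anchors(anchors: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ANCHOR_COLUMNS if c not in anchors.columns]
    if missing:
        raise ValueError(f"anchor table missing columns {missing}")
    if len(anchors) and (
        (anchors["query_pos"] < 0).any() or (anchors["ref_pos"] < 0).any()
    ):
        raise ValueError("anchor positions must be >= 0")
    # full-row lexicographic sort makes chaining invariant to input order
    return anchors.sort_values(ANCHOR_COLUMNS, kind="stable").reset_index(drop=True)


def chain_anchors(
    anchors: pd.DataFrame, min_block_anchors: int = 3, max_gap: int = 1_000_000
) -> list[SyntenyBlock]:
    """Chain anchors into collinear synteny blocks.

    Within each query scaffold (anchors sorted by query position) a block is
    a maximal run that keeps the same reference chromosome, has successive
    query gaps <= ``max_gap``, and reference positions monotone in either
    direction.  Runs shorter than ``min_block_anchors`` are discarded as
    noise; every retained anchor belongs to exactly one block.
    """
    if min_block_anchors < 2:
        raise ValueError("min_block_anchors must be >= 2")
    if max_gap <= 0:
        raise ValueError("max_gap must be > 0")
    if len(anchors) == 0:
        return []
    df = _sorted_anchors(anchors)

    blocks: list[SyntenyBlock] = []

    def flush(run: list[tuple[int, str, int]], query_id: str, direction: int) -> None:
        if len(run) < min_block_anchors:
            return
        qpos = [r[0] for r in run]
        rpos = [r[2] for r in run]
        blocks.append(
            SyntenyBlock(
                query_id=query_id,
                query_start=qpos[0],
                query_end=qpos[-1] + 1,
                ref_chrom=run[0][1],
                ref_start=min(rpos),
                ref_end=max(rpos) + 1,
                orientation="-" if direction < 0 else "+",
                n_anchors=len(run),
            )
        )

    for query_id, grp in df.groupby("query_id", sort=True):
        rows = list(
            zip(
                grp["query_pos"].astype(int),
                grp["ref_chrom"],
                grp["ref_pos"].astype(int),
            )
        )
        run = [rows[0]]
        direction = 0
        for row in rows[1:]:
            prev = run[-1]
            ok = row[1] == prev[1] and row[0] - prev[0] <= max_gap
            step = int(np.sign(row[2] - prev[2]))
            if ok and step != 0 and direction != 0 and step != direction:
                ok = False
            if ok:
                run.append(row)
                if direction == 0 and step != 0:
                    direction = step
            else:
                flush(run, query_id, direction)
                run = [row]
                direction = 0
        flush(run, query_id, direction)
    return blocks


def detect_events(
    blocks: Sequence[SyntenyBlock], min_support: int = 3
) -> list[KaryotypeEvent]:
    """Call fusion and fission events from the block composition.

    A fusion is emitted for each query scaffold whose blocks cover >= 2
    distinct reference chromosomes, each backed by >= ``min_support``
    anchors in total; its breakpoints are the gaps between adjacent blocks
    of different reference chromosomes.  A fission is emitted for each
    reference chromosome hosted (with the same per-query anchor support) on
    >= 2 query scaffolds.  Output is deduplicated and sorted
    lexicographically, hence deterministic for any input order.
    """
    per_query: dict[str, list[SyntenyBlock]] = defaultdict(list)
    for b in blocks:
        per_query[b.query_id].append(b)

    events: list[KaryotypeEvent] = []

    ref_hosts: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for query_id in sorted(per_query):
        qblocks = sorted(per_query[query_id], key=lambda b: (b.query_start, b.ref_chrom))
        support: dict[str, int] = defaultdict(int)
        for b in qblocks:
            support[b.ref_chrom] += b.n_anchors
            ref_hosts[b.ref_chrom][query_id] += b.n_anchors
        qualified = sorted(r for r, n in support.items() if n >= min_support)
        if len(qualified) >= 2:
            kept = [b for b in qblocks if b.ref_chrom in qualified]
            breakpoints = []
            for prev, nxt in zip(kept, kept[1:]):
                if prev.ref_chrom != nxt.ref_chrom:
                    breakpoints.append((prev.query_end, nxt.query_start))
            events.append(
                KaryotypeEvent(
                    type="fusion",
                    members=tuple(qualified),
                    host=query_id,
                    breakpoints=tuple(breakpoints),
                    support=min(support[r] for r in qualified),
                )
            )

    for ref_chrom in sorted(ref_hosts):
        hosts = {q: n for q, n in ref_hosts[ref_chrom].items() if n >= min_support}
        if len(hosts) >= 2:
            members = tuple(sorted(hosts))
            events.append(
                KaryotypeEvent(
                    type="fission",
                    members=members,
                    host=ref_chrom,
                    breakpoints=(),
                    support=min(hosts.values()),
                )
            )
    # dedupe (defensive; construction above cannot duplicate) and order
    uniq = sorted(set(events), key=lambda e: (e.type, e.host, e.members))
    return uniq


def karyotype_count(
    n_ref: int, events: Iterable[KaryotypeEvent]
) -> tuple[int, dict[str, int]]:
    """Haploid chromosome number implied by the detected events.

    Each fusion of m chromosomes removes m-1; each fission into m pieces
    adds m-1 (identical to counting events when all events are pairwise).
    Returns (n_query, tally) where the tally records event and merge counts.
    """
    if n_ref < 1:
        raise ValueError("n_ref must be >= 1")
    fusions = [e for e in events if e.type == "fusion"]
    fissions = [e for e in events if e.type == "fission"]
    merges = sum(e.merges for e in fusions)
    splits = sum(e.merges for e in fissions)
    n_query = n_ref - merges + splits
    if n_query < 1:
        raise ValueError(
            f"inconsistent event set: n_ref={n_ref} with {merges} fusion merges "
            f"and {splits} fission splits yields {n_query} chromosomes"
        )
    tally = {
        "n_ref": n_ref,
        "n_query": n_query,
        "n_fusions": len(fusions),
        "n_fissions": len(fissions),
        "fusion_merges": merges,
        "fission_splits": splits,
    }
    return n_query, tally


GRID_COLUMNS = ["query_id", "query_mid", "ref_chrom", "ref_mid", "orientation", "n_anchors"]


def oxford_grid(blocks: Sequence[SyntenyBlock]) -> pd.DataFrame:
    """Long-format dot-plot table (one row per block, interval midpoints)."""
    rows = [
        {
            "query_id": b.query_id,
            "query_mid": (b.query_start + b.query_end) / 2,
            "ref_chrom": b.ref_chrom,
            "ref_mid": (b.ref_start + b.ref_end) / 2,
            "orientation": b.orientation,
            "n_anchors": b.n_anchors,
        }
        for b in blocks
    ]
    return pd.DataFrame(rows, columns=GRID_COLUMNS)


# ---------------------------------------------------------------------------
# Plain-text IO
# ---------------------------------------------------------------------------


def read_anchor_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ANCHOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: anchor table missing columns {missing}")
    return df


def write_blocks_tsv(blocks: Sequence[SyntenyBlock], path: str | Path) -> None:
    pd.DataFrame([vars(b) for b in blocks], columns=[
        "query_id", "query_start", "query_end", "ref_chrom", "ref_start",
        "ref_end", "orientation", "n_anchors",
    ]).to_csv(path, sep="\t", index=False)


def write_events_tsv(events: Sequence[KaryotypeEvent], path: str | Path) -> None:
    rows = [
        {
            "type": e.type,
            "host": e.host,
            "members": ",".join(e.members),
            "breakpoints": ";".join(f"{a}-{b}" for a, b in e.breakpoints),
            "support": e.support,
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=["type", "host", "members", "breakpoints", "support"]).to_csv(
        path, sep="\t", index=False
    )


def write_grid_tsv(grid: pd.DataFrame, path: str | Path) -> None:
    grid.to_csv(path, sep="\t", index=False)
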