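"""Synthetic ZW genome simulator with known ground truth.

Generates desk-scale genomes that emulate the statistical structure of a
lepidopteran ZW system: a set of autosomes plus a Z chromosome carrying an
ancestral and a neo segment (from a Z-autosome fusion) and a partially
assembled, degenerate, female-limited W.  The simulator emits

* the genome model itself (scaffold structure + sequences + planted
  female-specific repeat families),
* per-window sequencing-depth tables for ZZ males and ZW females
  (Poisson counts; expectation = mean depth x copy number, with optional
  repeat cross-mapping noise on the W),
* per-sex canonical k-mer pools,
* ortholog anchor maps against an ancestral karyotype with planted fusion
  events and optional spurious anchors,

together with a SimTruth record so every downstream stage can be scored
against ground truth without any external data.

All outputs are deterministic functions of the SimConfig (including its
seed); each stage draws from an independently seeded generator so that e.g.
requesting k-mer pools never perturbs the depth tables.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from .kmers import (
    KmerCountTable,
    canonical_codes,
    decode_bases,
    kmer_codes,
    _check_k,
)

# stage tags keeping the per-stage RNG streams independent
_STAGE_STRUCTURE = 1
_STAGE_DEPTH = 2
_STAGE_KMER = 3
_STAGE_ANCHORS = 4

ANCESTRAL_Z = "ancZ"

DEFAULT_FUSION_PLAN: tuple[frozenset[str], ...] = (
    frozenset({ANCESTRAL_Z, "anc15"}),  # Z-autosome fusion -> neo-Z
    frozenset({"anc5", "anc22"}),
    frozenset({"anc7", "anc8"}),
)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic ZW genome.

    Lengths are in bp.  ``mean_depth`` is the expected read count per window
    per haploid copy, so autosomes run at 2 x mean_depth in both sexes, the
    Z at 2x in males / 1x in females, and the assembled W at 1x in females
    only.  ``w_crossmap_rate`` is the fraction of W windows acting as
    repeat cross-mapping hotspots that collect male reads.
    ``w_fraction_assembled`` is the assembled fraction of the W; 0 disables
    the W scaffold entirely (used for null simulations).
    ``n_autosomes`` may be left None (derived from ancestral_n and
    fusion_plan); an explicit value is validated against the derived count.
    """

    n_autosomes: int | None = None
    z_ancestral_len: int = 150_000
    z_neo_len: int = 100_000
    autosome_len_range: tuple[int, int] = (40_000, 80_000)
    w_len: int = 250_000
    w_fraction_assembled: float = 0.1
    ancestral_n: int = 31
    fusion_plan: tuple[frozenset[str], ...] = DEFAULT_FUSION_PLAN
    n_males: int = 3
    n_females: int = 3
    mean_depth: float = 30.0
    w_crossmap_rate: float = 0.1
    n_w_repeat_families: int = 2
    w_repeat_length: int = 500
    w_repeat_copies: int = 10
    kmer_error_rate: float = 0.001
    seed: int = 0

    @property
    def has_w(self) -> bool:
        return self.w_fraction_assembled > 0

    @property
    def n_fusion_merges(self) -> int:
        return sum(len(s) - 1 for s in self.fusion_plan)

    @property
    def derived_n_autosomes(self) -> int:
        return self.ancestral_n - 1 - self.n_fusion_merges

    def ancestral_ids(self) -> list[str]:
        return [ANCESTRAL_Z] + [f"anc{i}" for i in range(1, self.ancestral_n)]

    def validate(self) -> None:
        if self.ancestral_n < 1:
            raise ValueError("ancestral_n must be >= 1")
        for name in ("z_ancestral_len", "z_neo_len", "w_len", "w_repeat_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        lo, hi = self.autosome_len_range
        if not (0 < lo <= hi):
            raise ValueError("autosome_len_range must satisfy 0 < lo <= hi")
        if not (0 <= self.w_fraction_assembled <= 1):
            raise ValueError("w_fraction_assembled must be in [0, 1]")
        if not (0 <= self.w_crossmap_rate < 1):
            raise ValueError("w_crossmap_rate must be in [0, 1)")
        if self.n_males < 1 or self.n_females < 1:
            raise ValueError("n_males and n_females must be >= 1")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")
        if not (0 <= self.kmer_error_rate < 1):
            raise ValueError("kmer_error_rate must be in [0, 1)")
        if self.n_w_repeat_families < 0 or self.w_repeat_copies < 0:
            raise ValueError("repeat family counts must be >= 0")
        if self.n_w_repeat_families > 0 and not self.has_w:
            raise ValueError("planted W repeat families require an assembled W "
                             "(set n_w_repeat_families=0 for a no-W genome)")
        known = set(self.ancestral_ids())
        seen: set[str] = set()
        for s in self.fusion_plan:
            if len(s) < 2:
                raise ValueError(f"fusion set {sorted(s)} must name >= 2 chromosomes")
            unknown = s - known
            if unknown:
                raise ValueError(
                    f"fusion set {sorted(s)} names unknown ancestral "
                    f"chromosomes {sorted(unknown)}"
                )
            overlap = s & seen
            if overlap:
                raise ValueError(
                    f"fusion set {sorted(s)} overlaps another set on {sorted(overlap)}"
                )
            seen |= s
        if self.ancestral_n - self.n_fusion_merges < 1:
            raise ValueError("fusion_plan collapses the karyotype below one chromosome")
        if (
            self.n_autosomes is not None
            and self.n_autosomes != self.derived_n_autosomes
        ):
            raise ValueError(
                f"n_autosomes={self.n_autosomes} inconsistent with ancestral_n="
                f"{self.ancestral_n} and fusion_plan ({self.n_fusion_merges} merges"
                f" -> {self.derived_n_autosomes} autosomes)"
            )


@dataclass(frozen=True)
class Segment:
    """A stretch of a query scaffold descending from one ancestral chromosome
    (coordinates on the query scaffold, BED-style half-open)."""

    anc_id: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Scaffold:
    id: str
    length: int
    cls: str  # 'autosome' | 'Z' | 'W'
    composition: list[Segment] = field(default_factory=list)
    z_segments: list[Segment] | None = None  # ancestral / neo annotation on Z


@dataclass
class RepeatFamily:
    family_id: str
    consensus: str
    copies: int
    home_class: str = "W"


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth labels emitted alongside every simulated dataset."""

    scaffold_classes: dict[str, str]
    fusion_events_true: list[frozenset[str]]
    w_repeat_ids: list[str]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "scaffold_classes": dict(sorted(self.scaffold_classes.items())),
            "fusion_events_true": sorted(sorted(s) for s in self.fusion_events_true),
            "w_repeat_ids": sorted(self.w_repeat_ids),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


@dataclass
class GenomeModel:
    scaffolds: list[Scaffold]
    planted_repeats: list[RepeatFamily]
    ancestral_lengths: dict[str, int]
    sequences: dict[str, np.ndarray]  # scaffold id -> 2-bit codes
    config: SimConfig

    def scaffold(self, scaffold_id: str) -> Scaffold:
        for s in self.scaffolds:
            if s.id == scaffold_id:
                return s
        raise KeyError(f"unknown scaffold {scaffold_id!r}")

    @property
    def z_scaffold(self) -> Scaffold | None:
        return next((s for s in self.scaffolds if s.cls == "Z"), None)

    @property
    def w_scaffold(self) -> Scaffold | None:
        return next((s for s in self.scaffolds if s.cls == "W"), None)

    def truth(self) -> SimTruth:
        return SimTruth(
            scaffold_classes={s.id: s.cls for s in self.scaffolds},
            fusion_events_true=[
                frozenset(seg.anc_id for seg in s.composition)
                for s in self.scaffolds
                if len(s.composition) > 1
            ],
            w_repeat_ids=[f.family_id for f in self.planted_repeats],
        )

    def sequence_str(self, scaffold_id: str) -> str:
        return decode_bases(self.sequences[scaffold_id])

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for s in self.scaffolds:
                fh.write(f">{s.id} class={s.cls} length={s.length}\n")
                seq = self.sequence_str(s.id)
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")


def _anc_sort_key(anc_id: str):
    # ancestral Z first, then autosomes in numeric order
    if anc_id == ANCESTRAL_Z:
        return (0, 0)
    return (1, int(anc_id[3:]))


def _round_kb(x: float) -> int:
    return max(1000, int(round(x / 1000.0)) * 1000)


def build_genome_model(config: SimConfig) -> GenomeModel:
    """Construct the scaffold structure, sequences, and planted repeats.

    Query chromosomes are the ancestral chromosomes merged according to the
    fusion plan; the Z (if fused) carries an ancestral segment followed by a
    neo segment.  Scaffolds are named chr1..chrN with the Z first (it is the
    largest chromosome by construction), autosomes in decreasing length, and
    the assembled W fragment last — mirroring a chromosome-level assembly in
    which the W is only fractionally represented.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, _STAGE_STRUCTURE])

    anc_ids = config.ancestral_ids()
    neo_partners: set[str] = set()
    z_set = next((s for s in config.fusion_plan if ANCESTRAL_Z in s), None)
    if z_set is not None:
        neo_partners = set(z_set) - {ANCESTRAL_Z}

    lo, hi = config.autosome_len_range
    anc_len: dict[str, int] = {}
    for aid in anc_ids:
        if aid == ANCESTRAL_Z:
            anc_len[aid] = config.z_ancestral_len
        elif aid in neo_partners:
            anc_len[aid] = config.z_neo_len
        else:
            anc_len[aid] = _round_kb(rng.integers(lo, hi + 1))

    # group ancestral chromosomes into query chromosomes
    group_of: dict[str, int] = {}
    groups: list[list[str]] = []
    for s in config.fusion_plan:
        groups.append(sorted(s, key=_anc_sort_key))
        for aid in s:
            group_of[aid] = len(groups) - 1
    for aid in anc_ids:
        if aid not in group_of:
            groups.append([aid])

    drafts = []
    for members in groups:
        length = sum(anc_len[a] for a in members)
        cls = "Z" if ANCESTRAL_Z in members else "autosome"
        segs = []
        pos = 0
        for a in members:
            segs.append(Segment(a, pos, pos + anc_len[a]))
            pos += anc_len[a]
        drafts.append((cls, length, tuple(members), segs))

    # naming: Z first, then autosomes by decreasing length (ties by members)
    drafts.sort(key=lambda d: (d[0] != "Z", -d[1], d[2]))
    scaffolds: list[Scaffold] = []
    for i, (cls, length, _members, segs) in enumerate(drafts, start=1):
        z_segments = None
        if cls == "Z":
            z_anc_end = next(s.end for s in segs if s.anc_id == ANCESTRAL_Z)
            z_segments = [Segment("ancestral", 0, z_anc_end)]
            if z_anc_end < length:
                z_segments.append(Segment("neo", z_anc_end, length))
        scaffolds.append(Scaffold(f"chr{i}", length, cls, list(segs), z_segments))

    planted: list[RepeatFamily] = []
    if config.has_w:
        w_assembled = _round_kb(config.w_len * config.w_fraction_assembled)
        scaffolds.append(Scaffold(f"chr{len(scaffolds) + 1}", w_assembled, "W"))

    # sequences: i.i.d. uniform nucleotides, repeats planted on the W
    sequences: dict[str, np.ndarray] = {}
    for s in scaffolds:
        sequences[s.id] = rng.integers(0, 4, s.length, dtype=np.uint8)

    if config.has_w and config.n_w_repeat_families > 0:
        w = next(s for s in scaffolds if s.cls == "W")
        copies_total = config.n_w_repeat_families * config.w_repeat_copies
        occupied = copies_total * config.w_repeat_length
        free = w.length - occupied
        if free < 0:
            raise ValueError(
                f"planted repeats ({occupied} bp) exceed the assembled W "
                f"({w.length} bp); reduce families/copies/length"
            )
        for i in range(config.n_w_repeat_families):
            consensus_codes = rng.integers(0, 4, config.w_repeat_length, dtype=np.uint8)
            planted.append(
                RepeatFamily(
                    family_id=f"Wrep{i + 1}",
                    consensus=decode_bases(consensus_codes),
                    copies=config.w_repeat_copies,
                )
            )
        # interleave copies of all families at random non-overlapping offsets
        order = np.repeat(np.arange(config.n_w_repeat_families), config.w_repeat_copies)
        rng.shuffle(order)
        cuts = np.sort(rng.integers(0, free + 1, size=copies_total))
        seq = sequences[w.id]
        offset = 0
        for slot, fam_idx in enumerate(order):
            start = int(cuts[slot]) + offset
            fam = planted[fam_idx]
            seq[start : start + config.w_repeat_length] = _consensus_codes(fam)
            offset += config.w_repeat_length

    return GenomeModel(
        scaffolds=scaffolds,
        planted_repeats=planted,
        ancestral_lengths=anc_len,
        sequences=sequences,
        config=config,
    )


def _consensus_codes(fam: RepeatFamily) -> np.ndarray:
    from .kmers import encode_bases

    return encode_bases(fam.consensus)


# ---------------------------------------------------------------------------
# Depth simulation
# ---------------------------------------------------------------------------

# (male, female) copy number by scaffold class
COPY_NUMBER = {"autosome": (2, 2), "Z": (2, 1), "W": (0, 1)}


def sample_ids(config: SimConfig) -> tuple[list[str], list[str]]:
    males = [f"M{i + 1}" for i in range(config.n_males)]
    females = [f"F{i + 1}" for i in range(config.n_females)]
    return males, females


def simulate_depth(
    model: GenomeModel, config: SimConfig | None = None, window_size: int = 500
) -> tuple[pd.DataFrame, SimTruth]:
    """Per-window read counts for every sample.

    Window counts are Poisson with expectation
    mean_depth x copy_number x (window_length / window_size); W windows are
    additionally cross-mapping hotspots with probability ``w_crossmap_rate``,
    in which case male samples collect a full mean_depth of stray reads
    (hotspots are a property of the window, shared across male samples).
    """
    config = config or model.config
    if window_size <= 0:
        raise ValueError("window_size must be > 0")
    shortest = min(model.scaffolds, key=lambda s: s.length)
    if window_size > shortest.length:
        raise ValueError(
            f"window_size {window_size} exceeds the shortest scaffold "
            f"{shortest.id} ({shortest.length} bp)"
        )
    rng = np.random.default_rng([config.seed, _STAGE_DEPTH])
    males, females = sample_ids(config)

    frames = []
    for s in model.scaffolds:
        starts = np.arange(0, s.length, window_size)
        ends = np.minimum(starts + window_size, s.length)
        frac = (ends - starts) / window_size
        m_copy, f_copy = COPY_NUMBER[s.cls]
        mu_m = config.mean_depth * m_copy * frac
        mu_f = config.mean_depth * f_copy * frac
        if s.cls == "W" and config.w_crossmap_rate > 0:
            hot = rng.random(starts.size) < config.w_crossmap_rate
            mu_m = mu_m + config.mean_depth * hot * frac
        for sample, sex, mu in [(x, "M", mu_m) for x in males] + [
            (x, "F", mu_f) for x in females
        ]:
            frames.append(
                pd.DataFrame(
                    {
                        "scaffold": s.id,
                        "start": starts,
                        "end": ends,
                        "sample": sample,
                        "sex": sex,
                        "raw": rng.poisson(mu),
                        "partial": (ends - starts) < window_size,
                    }
                )
            )
    table = pd.concat(frames, ignore_index=True)
    return table, model.truth()


# ---------------------------------------------------------------------------
# K-mer pool simulation
# ---------------------------------------------------------------------------


def simulate_kmer_pools(
    model: GenomeModel, config: SimConfig | None = None, k: int = 21
) -> tuple[KmerCountTable, KmerCountTable, SimTruth]:
    """Per-sex canonical k-mer pools over the model sequences.

    Each distinct canonical k-mer receives a Poisson count with expectation
    mean_depth x (its summed genomic multiplicity weighted by the sex's copy
    number).  Sequencing errors inject singleton k-mers at a rate of
    k x kmer_error_rate per counted k-mer instance (a read k-mer containing
    at least one miscalled base becomes a random novel k-mer).
    """
    config = config or model.config
    _check_k(k)
    if model.planted_repeats:
        shortest = min(len(f.consensus) for f in model.planted_repeats)
        if k > shortest:
            raise ValueError(
                f"k={k} exceeds the shortest planted repeat ({shortest} bp)"
            )
    rng = np.random.default_rng([config.seed, _STAGE_KMER])

    chunks = []
    weights_m = []
    weights_f = []
    for s in model.scaffolds:
        vals = canonical_codes(kmer_codes(model.sequences[s.id], k), k)
        m_copy, f_copy = COPY_NUMBER[s.cls]
        chunks.append(vals)
        weights_m.append(np.full(vals.size, m_copy, dtype=np.int64))
        weights_f.append(np.full(vals.size, f_copy, dtype=np.int64))
    from .kmers import unique_counts

    all_codes = np.concatenate(chunks)
    uniq, _ = unique_counts(all_codes)
    mult_m = np.zeros(uniq.size, dtype=np.int64)
    mult_f = np.zeros(uniq.size, dtype=np.int64)
    inv = np.searchsorted(uniq, all_codes)
    np.add.at(mult_m, inv, np.concatenate(weights_m))
    np.add.at(mult_f, inv, np.concatenate(weights_f))

    from .kmers import _sorted_union

    tables = []
    for mult in (mult_m, mult_f):
        counts = rng.poisson(config.mean_depth * mult)
        keep = counts > 0
        codes, cnts = uniq[keep], counts[keep].astype(np.int64)
        if config.kmer_error_rate > 0:
            total = int(cnts.sum())
            n_err = rng.poisson(total * k * config.kmer_error_rate)
            if n_err > 0:
                err = canonical_codes(
                    rng.integers(0, 4**k, size=n_err, dtype=np.uint64), k
                )
                err_codes, err_cnts = unique_counts(err)
                # merge two sorted count vectors without re-sorting everything
                merged = _sorted_union(codes, err_codes)
                tot = np.zeros(merged.size, dtype=np.int64)
                tot[np.searchsorted(merged, codes)] += cnts
                tot[np.searchsorted(merged, err_codes)] += err_cnts
                codes, cnts = merged, tot
        tables.append(KmerCountTable(k, codes, cnts))
    male, female = tables
    return male, female, model.truth()


# ---------------------------------------------------------------------------
# Anchor map emission
# ---------------------------------------------------------------------------

ANCHOR_COLUMNS = ["query_id", "query_pos", "ref_chrom", "ref_pos", "strand"]


def emit_anchor_map(
    model: GenomeModel,
    anchors_per_mb: float = 300.0,
    spurious_fraction: float = 0.02,
    seed: int | None = None,
) -> pd.DataFrame:
    """Ortholog anchors linking query scaffolds to ancestral chromosomes.

    Anchor counts per scaffold are Poisson(length_Mb x anchors_per_mb) with
    uniform positions; each anchor carries the true ancestral chromosome of
    its segment and a collinear reference position (one random orientation
    per segment).  A ``spurious_fraction`` of anchors is relabeled to a
    random wrong chromosome at a random position, emulating alignment noise.
    The W scaffold has no ancestral composition and contributes no anchors.
    """
    if anchors_per_mb <= 0:
        raise ValueError("anchors_per_mb must be > 0")
    if not (0 <= spurious_fraction < 0.5):
        raise ValueError("spurious_fraction must be in [0, 0.5)")
    seed = model.config.seed if seed is None else seed
    rng = np.random.default_rng([seed, _STAGE_ANCHORS])
    anc_ids = sorted(model.ancestral_lengths, key=_anc_sort_key)

    rows: list[dict] = []
    for s in model.scaffolds:
        if not s.composition:
            continue
        n = rng.poisson(s.length / 1e6 * anchors_per_mb)
        if n == 0:
            continue
        positions = np.sort(rng.integers(0, s.length, size=n))
        seg_strand = {seg.anc_id: rng.choice(["+", "-"]) for seg in s.composition}
        seg_starts = np.array([seg.start for seg in s.composition])
        seg_idx = np.searchsorted(seg_starts, positions, side="right") - 1
        for pos, si in zip(positions, seg_idx):
            seg = s.composition[si]
            strand = seg_strand[seg.anc_id]
            offset = int(pos) - seg.start
            ref_pos = offset if strand == "+" else seg.length - 1 - offset
            ref_chrom = seg.anc_id
            if rng.random() < spurious_fraction:
                others = [a for a in anc_ids if a != seg.anc_id]
                ref_chrom = others[rng.integers(len(others))]
                ref_pos = int(rng.integers(0, model.ancestral_lengths[ref_chrom]))
                strand = rng.choice(["+", "-"])
            rows.append(
                {
                    "query_id": s.id,
                    "query_pos": int(pos),
                    "ref_chrom": ref_chrom,
                    "ref_pos": int(ref_pos),
                    "strand": strand,
                }
            )
    return pd.DataFrame(rows, columns=ANCHOR_COLUMNS)


# ---------------------------------------------------------------------------
# Plain-text writers
# ---------------------------------------------------------------------------


def write_depth_tsv(table: pd.DataFrame, path: str | Path) -> None:
    cols = ["scaffold", "start", "end", "sample", "raw"]
    table[cols].rename(columns={"raw": "count"}).to_csv(path, sep="\t", index=False)


def write_windows_bed(table: pd.DataFrame, path: str | Path) -> None:
    windows = (
        table[["scaffold", "start", "end"]]
        .drop_duplicates()
        .sort_values(["scaffold", "start"], kind="stable")
    )
    windows.to_csv(path, sep="\t", index=False, header=False)


def write_sample_sheet(table: pd.DataFrame, path: str | Path) -> None:
    sheet = (
        table[["sample", "sex"]]
        .drop_duplicates()
        .sort_values("sample", kind="stable")
        .rename(columns={"sample": "sample_id"})
    )
    sheet.to_csv(path, sep="\t", index=False)


def write_anchor_tsv(anchors: pd.DataFrame, path: str | Path) -> None:
    anchors[ANCHOR_COLUMNS].to_csv(path, sep="\t", index=False)
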