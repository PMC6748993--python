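"""End-to-end pipeline: simulate -> coverage -> classify -> synteny -> k-mer.

Wires the stage modules into a single reproducible run with plain-text
TSV/JSON outputs and a deterministic markdown report.  Rerunning with the
same configuration yields byte-identical outputs.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import coverage as cov
from . import kmers as km
from . import simulate as sim
from . import synteny as syn

logger = logging.getLogger("zwscout")

ALL_STAGES = ("simulate", "coverage", "classify", "synteny", "kmer")

FAIL_MARKER = "PIPELINE_FAILED"


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Full pipeline configuration (round-trips through JSON/YAML)."""

    outdir: str = "zwscout_out"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    log_level: str = "INFO"
    # simulation
    sim: sim.SimConfig = field(default_factory=sim.SimConfig)
    # coverage / classification
    window_size: int = 500
    pseudocount: float = 0.01
    thresholds: cov.ClassifierThresholds = field(default_factory=cov.ClassifierThresholds)
    # synteny
    anchors_per_mb: float = 300.0
    spurious_fraction: float = 0.02
    min_block_anchors: int = 3
    max_gap: int = 1_000_000
    min_support: int = 3
    # k-mer analysis
    k: int = 21
    min_total: int = 10
    fdr: float = 0.05
    min_enrichment: float = 4.0
    # external inputs (used when the simulate stage is disabled)
    depth_tsv: str | None = None
    window_counts_tsv: str | None = None
    sample_sheet: str | None = None
    anchor_tsv: str | None = None
    male_kmers_tsv: str | None = None
    female_kmers_tsv: str | None = None
    male_reads: str | None = None
    female_reads: str | None = None

    def __post_init__(self) -> None:
        self.stages = tuple(self.stages)
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise ValueError(f"unknown stages {unknown}; valid: {list(ALL_STAGES)}")
        # seed flows into the simulator unless the user pinned one explicitly
        if self.sim.seed != self.seed and self.sim.seed == 0:
            self.sim = dataclasses.replace(self.sim, seed=self.seed)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["sim"]["fusion_plan"] = sorted(
            sorted(s) for s in self.sim.fusion_plan
        )
        d["sim"]["autosome_len_range"] = list(self.sim.autosome_len_range)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        if "sim" in d and isinstance(d["sim"], dict):
            s = dict(d["sim"])
            if "fusion_plan" in s:
                s["fusion_plan"] = tuple(frozenset(x) for x in s["fusion_plan"])
            if "autosome_len_range" in s:
                s["autosome_len_range"] = tuple(s["autosome_len_range"])
            d["sim"] = sim.SimConfig(**s)
        if "thresholds" in d and isinstance(d["thresholds"], dict):
            d["thresholds"] = cov.ClassifierThresholds(**d["thresholds"])
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in {".yaml", ".yml"}:
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        data = self.to_dict()
        if path.suffix.lower() in {".yaml", ".yml"}:
            import yaml

            path.write_text(yaml.safe_dump(data, sort_keys=True))
        else:
            path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")


def _require_path(path: str | None, what: str) -> Path:
    if path is None:
        raise PipelineError(f"{what} required but no path configured")
    p = Path(path)
    if not p.exists():
        raise PipelineError(f"{what} not found: {p}")
    return p


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run the enabled stages, writing TSV/JSON outputs plus report.md.

    Returns the report data dictionary.  A failing stage aborts the run
    with the stage named; outputs written so far are retained next to a
    ``PIPELINE_FAILED`` marker file.
    """
    from . import __version__

    out = Path(outdir) if outdir is not None else Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    logger.info("zwscout %s | seed=%d | stages=%s", __version__, config.seed, config.stages)
    params = config.to_dict()
    params["version"] = __version__
    (out / "params.json").write_text(json.dumps(params, indent=2, sort_keys=True) + "\n")

    report: dict[str, Any] = {"seed": config.seed, "stages": list(config.stages)}
    state: dict[str, Any] = {}
    stage = None
    try:
        for stage in config.stages:
            logger.info("stage: %s", stage)
            _STAGE_FUNCS[stage](config, out, state, report)
        stage = "report"
        text = render_report(report)
        (out / "report.md").write_text(text)
    except Exception as exc:
        (out / FAIL_MARKER).write_text(f"stage: {stage}\nerror: {exc}\n")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    marker = out / FAIL_MARKER
    if marker.exists():
        marker.unlink()
    return report


# -- stages ----------------------------------------------------------------


def _stage_simulate(config: PipelineConfig, out: Path, state: dict, report: dict) -> None:
    model = sim.build_genome_model(config.sim)
    state["model"] = model
    model.to_fasta(out / "genome.fasta")
    table, truth = sim.simulate_depth(model, window_size=config.window_size)
    state["depth_table"] = table
    state["truth"] = truth
    truth.to_json(out / "truth.json")
    sim.write_depth_tsv(table, out / "window_counts.tsv")
    sim.write_windows_bed(table, out / "windows.bed")
    sim.write_sample_sheet(table, out / "samples.tsv")
    anchors = sim.emit_anchor_map(
        model, config.anchors_per_mb, config.spurious_fraction
    )
    state["anchors"] = anchors
    sim.write_anchor_tsv(anchors, out / "anchors.tsv")
    male, female, _ = sim.simulate_kmer_pools(model, k=config.k)
    state["kmer_pools"] = (male, female)
    report["simulate"] = {
        "n_scaffolds": len(model.scaffolds),
        "classes": {c: sum(1 for s in model.scaffolds if s.cls == c) for c in ("autosome", "Z", "W")},
        "genome_bp": int(sum(s.length for s in model.scaffolds)),
        "n_anchors": int(len(anchors)),
        "planted_w_families": [f.family_id for f in model.planted_repeats],
    }


def _load_window_table(config: PipelineConfig, state: dict) -> pd.DataFrame:
    if "depth_table" in state:
        return state["depth_table"]
    sheet = cov.read_sample_sheet(_require_path(config.sample_sheet, "sample sheet"))
    if config.window_counts_tsv is not None:
        counts = cov.read_window_counts_tsv(
            _require_path(config.window_counts_tsv, "window counts TSV")
        )
        return cov.attach_sex(counts, sheet)
    depth = cov.read_depth_tsv(_require_path(config.depth_tsv, "depth TSV"))
    return cov.tally_windows(depth, sheet, window_size=config.window_size)


def _stage_coverage(config: PipelineConfig, out: Path, state: dict, report: dict) -> None:
    table = _load_window_table(config, state)
    norm = cov.normalize_by_sample_median(table)
    state["norm_table"] = norm
    summary = cov.summarize_by_sex(norm, pseudocount=config.pseudocount)
    state["summary"] = summary
    cov.write_summary_tsv(summary, out / "coverage_summary.tsv")
    report["coverage"] = {
        "n_scaffolds": int(len(summary)),
        "n_samples": int(table["sample"].nunique()),
        "n_windows": int(summary["n_windows"].sum()),
    }


def _stage_classify(config: PipelineConfig, out: Path, state: dict, report: dict) -> None:
    if "summary" not in state:
        raise PipelineError("classify requires the coverage stage")
    labeled = cov.classify(state["summary"], config.thresholds)
    state["labeled"] = labeled
    cov.write_summary_tsv(labeled, out / "scaffold_labels.tsv")
    counts = labeled["label"].value_counts().to_dict()
    z = labeled[labeled["label"] == "Z"]
    report["classify"] = {
        "label_counts": {k: int(v) for k, v in sorted(counts.items())},
        "z_scaffolds": sorted(z.index.tolist()),
        "w_scaffolds": sorted(labeled[labeled["label"] == "W"].index.tolist()),
        "z_mf_ratio": round(float(z["mf_ratio"].iloc[0]), 4) if len(z) else None,
    }


def _stage_synteny(config: PipelineConfig, out: Path, state: dict, report: dict) -> None:
    if "anchors" in state:
        anchors = state["anchors"]
    else:
        anchors = syn.read_anchor_tsv(_require_path(config.anchor_tsv, "anchor TSV"))
    blocks = syn.chain_anchors(anchors, config.min_block_anchors, config.max_gap)
    events = syn.detect_events(blocks, config.min_support)
    n_query, tally = syn.karyotype_count(config.sim.ancestral_n, events)
    syn.write_blocks_tsv(blocks, out / "synteny_blocks.tsv")
    syn.write_events_tsv(events, out / "karyotype_events.tsv")
    syn.write_grid_tsv(syn.oxford_grid(blocks), out / "oxford_grid.tsv")
    report["synteny"] = {
        "n_blocks": len(blocks),
        "events": [
            {"type": e.type, "host": e.host, "members": list(e.members), "support": e.support}
            for e in events
        ],
        "karyotype": tally,
    }


def _load_kmer_pools(config: PipelineConfig, state: dict) -> tuple[km.KmerCountTable, km.KmerCountTable]:
    if "kmer_pools" in state:
        return state["kmer_pools"]
    if config.male_kmers_tsv and config.female_kmers_tsv:
        return (
            km.KmerCountTable.from_tsv(_require_path(config.male_kmers_tsv, "male k-mer TSV")),
            km.KmerCountTable.from_tsv(_require_path(config.female_kmers_tsv, "female k-mer TSV")),
        )
    male = km.count_canonical_kmers(_require_path(config.male_reads, "male reads"), config.k)
    female = km.count_canonical_kmers(_require_path(config.female_reads, "female reads"), config.k)
    return male, female


def _stage_kmer(config: PipelineConfig, out: Path, state: dict, report: dict) -> None:
    male, female = _load_kmer_pools(config, state)
    hist = male.histogram()
    pd.DataFrame({"depth": np.arange(hist.size), "n_kmers": hist}).query("n_kmers > 0").to_csv(
        out / "kmer_histogram.tsv", sep="\t", index=False
    )
    size = km.estimate_genome_size(hist)
    (out / "genome_size.json").write_text(
        json.dumps(dataclasses.asdict(size), indent=2, sort_keys=True) + "\n"
    )
    records = km.test_sex_enrichment(
        male, female, config.min_total, config.fdr, config.min_enrichment
    )
    km.write_enrichment_tsv(records, out / "female_enriched_kmers.tsv")
    # repeat candidates: abundance above ~2x the single-copy coverage peak
    min_female = int(np.ceil(2 * size.peak_depth))
    families = km.cluster_enriched(records, min_female_count=min_female)
    km.write_families(families, out / "w_repeat_families.tsv", out / "w_repeat_families.fasta")
    report["kmer"] = {
        "k": config.k,
        "genome_size_bp": round(size.size_bp, 1),
        "peak_depth": round(size.peak_depth, 3),
        "n_significant_kmers": int(records["significant"].sum()),
        "repeat_count_floor": min_female,
        "n_families": len(families),
        "families": [
            {"family_id": f.family_id, "n_kmers": len(f.kmers), "score": round(f.score, 2)}
            for f in families
        ],
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "coverage": _stage_coverage,
    "classify": _stage_classify,
    "synteny": _stage_synteny,
    "kmer": _stage_kmer,
}


# -- reporting -------------------------------------------------------------


def render_report(data: dict) -> str:
    """Human-readable markdown summary echoing stage outputs verbatim."""
    lines = ["# zwscout pipeline report", "", f"seed: {data.get('seed')}", ""]
    if "simulate" in data:
        s = data["simulate"]
        lines += [
            "## Simulation",
            "",
            f"- scaffolds: {s['n_scaffolds']} "
            f"({s['classes']['autosome']} autosomes, {s['classes']['Z']} Z, {s['classes']['W']} W)",
            f"- genome size: {s['genome_bp']} bp",
            f"- anchors emitted: {s['n_anchors']}",
            f"- planted W repeat families: {', '.join(s['planted_w_families']) or 'none'}",
            "",
        ]
    if "coverage" in data:
        c = data["coverage"]
        lines += [
            "## Coverage",
            "",
            f"- scaffolds summarized: {c['n_scaffolds']} "
            f"({c['n_windows']} windows, {c['n_samples']} samples)",
            "",
        ]
    if "classify" in data:
        c = data["classify"]
        counts = ", ".join(f"{k}: {v}" for k, v in c["label_counts"].items())
        lines += [
            "## Classification",
            "",
            f"- labels: {counts}",
            f"- Z scaffold(s): {', '.join(c['z_scaffolds']) or 'none'}"
            + (f" (M:F ratio {c['z_mf_ratio']})" if c.get("z_mf_ratio") else ""),
            f"- W scaffold(s): {', '.join(c['w_scaffolds']) or 'none'}",
            "",
        ]
    if "synteny" in data:
        s = data["synteny"]
        t = s["karyotype"]
        lines += ["## Karyotype events", ""]
        if s["events"]:
            for e in s["events"]:
                lines.append(
                    f"- {e['type']}: {e['host']} <- {{{', '.join(e['members'])}}} "
                    f"(support {e['support']})"
                )
        else:
            lines.append("- no events detected")
        lines += [
            f"- chromosome number: n_ref {t['n_ref']} - {t['fusion_merges']} fusion merges "
            f"+ {t['fission_splits']} fission splits = n_query {t['n_query']}",
            "",
        ]
    if "kmer" in data:
        kk = data["kmer"]
        lines += [
            "## Sex-differential k-mers",
            "",
            f"- k = {kk['k']}; male-pool genome size estimate: {kk['genome_size_bp']} bp "
            f"(coverage peak {kk['peak_depth']})",
            f"- significantly female-enriched k-mers: {kk['n_significant_kmers']}",
            f"- candidate W repeat families (female count >= {kk['repeat_count_floor']}): "
            f"{kk['n_families']}",
        ]
        for f in kk["families"]:
            lines.append(f"  - {f['family_id']}: {f['n_kmers']} k-mers, score {f['score']}")
        lines.append("")
    return "\n".join(lines) + "\n"
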