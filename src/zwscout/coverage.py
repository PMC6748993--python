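"""Coverage-based sex-linkage inference for ZW genomes.

Implements the classical read-depth test for sex chromosomes in a
female-heterogametic system: window read counts per sample are normalized by
each sample's median coverage, averaged by sex per scaffold, and the
male:female ratio classifies each scaffold —

* ~1 (log2 ~ 0):  autosome (two copies in both sexes),
* ~2 (log2 ~ 1):  Z-linked (ZZ males vs ZW females),
* << 1:           W-linked (female-limited, male coverage near zero).

All window coordinates follow the BED convention (0-based, half-open).
Sexes are encoded {M, F} under ZW heterogamety; for an XY system the same
machinery applies with the ratio interpretation inverted (X at ~0.5, Y-like
at >> 1 on the male side).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

SEXES = ("M", "F")

TABLE_COLUMNS = ["scaffold", "start", "end", "sample", "sex", "raw", "partial"]


@dataclass(frozen=True)
class ClassifierThresholds:
    """Decision rule on the log2 male:female ratio.

    Autosome: |log2| <= t_auto; Z: |log2 - z_center| <= t_z;
    W: log2 <= t_w; anything else is ambiguous.  The autosome and Z
    intervals must be disjoint and the W cutoff must sit below the autosome
    band.  Scaffolds with fewer than ``min_windows`` windows, or with
    normalized mean coverage below ``min_total_cov`` in the informative sex,
    are labeled ambiguous with the reason recorded (the W is exempt from the
    male-side coverage floor, since zero male coverage is its signature).
    """

    t_auto: float = 0.35
    z_center: float = 1.0
    t_z: float = 0.35
    t_w: float = -1.0
    min_windows: int = 10
    min_total_cov: float = 0.1

    def validate(self) -> None:
        if self.t_auto <= 0 or self.t_z <= 0:
            raise ValueError("threshold half-widths must be > 0")
        if self.z_center - self.t_z <= self.t_auto:
            raise ValueError(
                "autosome and Z intervals overlap: "
                f"[-{self.t_auto}, {self.t_auto}] vs "
                f"[{self.z_center - self.t_z}, {self.z_center + self.t_z}]"
            )
        if self.t_w >= -self.t_auto:
            raise ValueError("t_w must lie below the autosome interval")
        if self.min_windows < 1:
            raise ValueError("min_windows must be >= 1")


# ---------------------------------------------------------------------------
# Tallying
# ---------------------------------------------------------------------------


def _check_sex_labels(samples: Sequence[str], sample_sex: Mapping[str, str]) -> None:
    missing = sorted(s for s in samples if s not in sample_sex)
    if missing:
        raise ValueError(f"samples without a sex label: {missing}")
    bad = sorted(s for s in samples if sample_sex[s] not in SEXES)
    if bad:
        raise ValueError(f"sex labels must be one of {SEXES}; offending samples: {bad}")


def tally_windows(
    depth: pd.DataFrame,
    sample_sex: Mapping[str, str],
    window_size: int = 500,
    windows: pd.DataFrame | None = None,
    scaffold_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Aggregate per-position depth into per-window per-base mean coverage.

    ``depth`` uses the multi-sample depth text layout: columns
    (scaffold, pos, <sample>, <sample>, ...) with 1-based positions, one row
    per covered position (absent positions count as depth 0).  Windows are
    either nonoverlapping fixed-size tiles (``window_size``, default 500 bp)
    or explicit BED intervals.  The value stored in ``raw`` is the window's
    summed depth divided by the window length, so a partial terminal window
    (flagged ``partial``) remains comparable to full windows.
    """
    if list(depth.columns[:2]) != ["scaffold", "pos"]:
        raise ValueError("depth table must start with columns (scaffold, pos)")
    samples = list(depth.columns[2:])
    if not samples:
        raise ValueError("depth table has no sample columns")
    _check_sex_labels(samples, sample_sex)

    if windows is not None:
        win = windows[["scaffold", "start", "end"]].sort_values(
            ["scaffold", "start"], kind="stable"
        )
    else:
        if window_size <= 0:
            raise ValueError("window_size must be > 0")
        lengths: dict[str, int] = dict(scaffold_lengths or {})
        for sc, grp in depth.groupby("scaffold", sort=False):
            lengths.setdefault(sc, int(grp["pos"].max()))
        parts = []
        for sc in sorted(lengths):
            starts = np.arange(0, lengths[sc], window_size)
            parts.append(
                pd.DataFrame(
                    {
                        "scaffold": sc,
                        "start": starts,
                        "end": np.minimum(starts + window_size, lengths[sc]),
                    }
                )
            )
        win = pd.concat(parts, ignore_index=True)

    frames = []
    for sc, wgrp in win.groupby("scaffold", sort=False):
        wgrp = wgrp.reset_index(drop=True)
        sums = np.zeros((len(wgrp), len(samples)))
        d = depth[depth["scaffold"] == sc]
        if len(d):
            pos0 = d["pos"].to_numpy() - 1  # to 0-based
            idx = np.searchsorted(wgrp["start"].to_numpy(), pos0, side="right") - 1
            inside = (idx >= 0) & (pos0 < wgrp["end"].to_numpy()[np.clip(idx, 0, None)])
            vals = d[samples].to_numpy(dtype=float)
            np.add.at(sums, (idx[inside],), vals[inside])
        wlen = (wgrp["end"] - wgrp["start"]).to_numpy(dtype=float)
        longest = wlen.max() if len(wlen) else 0
        for j, sample in enumerate(samples):
            frames.append(
                pd.DataFrame(
                    {
                        "scaffold": sc,
                        "start": wgrp["start"],
                        "end": wgrp["end"],
                        "sample": sample,
                        "sex": sample_sex[sample],
                        "raw": sums[:, j] / wlen,
                        "partial": wlen < longest,
                    }
                )
            )
    table = pd.concat(frames, ignore_index=True)
    return table[TABLE_COLUMNS]


def attach_sex(table: pd.DataFrame, sample_sex: Mapping[str, str]) -> pd.DataFrame:
    """Attach sex labels to a precomputed window-count table."""
    samples = sorted(table["sample"].unique())
    _check_sex_labels(samples, sample_sex)
    out = table.copy()
    out["sex"] = out["sample"].map(sample_sex)
    if "partial" not in out:
        out["partial"] = False
    return out


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def normalize_by_sample_median(table: pd.DataFrame) -> pd.DataFrame:
    """Divide each sample's window counts by that sample's median count.

    After normalization every sample's median window coverage is exactly 1;
    because autosomes dominate the genome this approximates normalizing to
    the diploid autosomal level.  A sample whose median is 0 (degenerate
    library) is an error.
    """
    out = table.copy()
    medians = out.groupby("sample")["raw"].median()
    zero = sorted(medians[medians == 0].index)
    if zero:
        raise ValueError(f"sample median coverage is 0 for samples: {zero}")
    out["norm"] = out["raw"] / out["sample"].map(medians)
    return out


# ---------------------------------------------------------------------------
# Sex-averaged summaries and classification
# ---------------------------------------------------------------------------


def _per_window_sex_means(table: pd.DataFrame) -> pd.DataFrame:
    g = (
        table.groupby(["scaffold", "start", "end", "partial", "sex"], sort=True)["norm"]
        .mean()
        .unstack("sex")
        .reset_index()
    )
    return g


def summarize_by_sex(
    table: pd.DataFrame, pseudocount: float = 0.01, weights: str = "window"
) -> pd.DataFrame:
    """Per-scaffold sex-averaged coverage and male:female ratio.

    ``mf_ratio`` applies the pseudocount to both sex means so W scaffolds
    with near-zero male coverage stay finite; ``mf_ratio_raw`` is the plain
    ratio of the sex means (inf when female coverage is exactly 0).
    ``ratio_dispersion`` is the variance of per-window log2 ratios over
    full (non-partial) windows — W scaffolds show a much larger dispersion
    than autosomes because repeat cross-mapping hits scattered windows.

    ``weights``: "window" averages per-window values with equal weight;
    "length" weights windows by their span, equivalent to one whole-scaffold
    tally divided by scaffold length.  Identical except for partial terminal
    windows.
    """
    if "norm" not in table.columns:
        raise ValueError("table is not normalized; run normalize_by_sample_median first")
    if weights not in ("window", "length"):
        raise ValueError("weights must be 'window' or 'length'")
    present = set(table["sex"].unique())
    missing = [s for s in SEXES if s not in present]
    if missing:
        raise ValueError(f"no samples for sex(es): {missing}")
    eps = pseudocount

    if weights == "length":
        tmp = table.assign(
            _w=(table["end"] - table["start"]).astype(float),
            _wn=lambda d: d["norm"] * d["_w"],
        )
        g = tmp.groupby(["scaffold", "sex"])
        sex_means = (g["_wn"].sum() / g["_w"].sum()).unstack("sex")
    else:
        sex_means = table.groupby(["scaffold", "sex"])["norm"].mean().unstack("sex")
    win = _per_window_sex_means(table)
    win["log2_ratio"] = np.log2((win["M"] + eps) / (win["F"] + eps))
    full = win[~win["partial"]]
    dispersion = full.groupby("scaffold")["log2_ratio"].var(ddof=1)
    n_windows = win.groupby("scaffold")["start"].count()
    length = win.groupby("scaffold")["end"].max()

    m = sex_means["M"]
    f = sex_means["F"]
    with np.errstate(divide="ignore", invalid="ignore"):
        raw_ratio = np.where(f > 0, m / f, np.inf)
    summary = pd.DataFrame(
        {
            "length": length,
            "n_windows": n_windows,
            "mean_male_cov": m,
            "mean_female_cov": f,
            "mf_ratio": (m + eps) / (f + eps),
            "mf_ratio_raw": raw_ratio,
            "ratio_dispersion": dispersion,
        }
    )
    summary["log2_mf"] = np.log2(summary["mf_ratio"])
    summary.index.name = "scaffold"
    summary.attrs["pseudocount"] = eps
    return summary.sort_index()


def classify(
    summary: pd.DataFrame, thresholds: ClassifierThresholds | None = None
) -> pd.DataFrame:
    """Label each scaffold autosome / Z / W / ambiguous from its log2 ratio."""
    th = thresholds or ClassifierThresholds()
    th.validate()
    out = summary.copy()
    labels = []
    reasons = []
    for _, row in out.iterrows():
        label, reason = _classify_one(row, th)
        labels.append(label)
        reasons.append(reason)
    out["label"] = labels
    out["filter_reason"] = reasons
    return out


def _classify_one(row: pd.Series, th: ClassifierThresholds) -> tuple[str, str]:
    if row["n_windows"] < th.min_windows:
        return "ambiguous", "too_few_windows"
    l2 = row["log2_mf"]
    if l2 <= th.t_w:
        if row["mean_female_cov"] < th.min_total_cov:
            return "ambiguous", "low_female_coverage"
        return "W", ""
    if row["mean_male_cov"] < th.min_total_cov or row["mean_female_cov"] < th.min_total_cov:
        return "ambiguous", "low_coverage"
    if abs(l2) <= th.t_auto:
        return "autosome", ""
    if abs(l2 - th.z_center) <= th.t_z:
        return "Z", ""
    return "ambiguous", "outside_intervals"


# ---------------------------------------------------------------------------
# Window-level ratio profiles
# ---------------------------------------------------------------------------


def window_ratio_profile(
    table: pd.DataFrame,
    scaffold_id: str,
    segments: Sequence[tuple[str, int, int]] | None = None,
    pseudocount: float = 0.01,
) -> tuple[pd.DataFrame, dict]:
    """Ordered per-window log2 male:female ratios for one scaffold.

    When ``segments`` (name, start, end) are supplied — e.g. the ancestral
    and neo parts of the Z — per-segment mean ratios and the largest
    absolute pairwise difference are returned as a consistency statistic.
    """
    sub = table[table["scaffold"] == scaffold_id]
    if len(sub) == 0:
        raise KeyError(f"unknown scaffold {scaffold_id!r}")
    if "norm" not in sub.columns:
        raise ValueError("table is not normalized; run normalize_by_sample_median first")
    win = _per_window_sex_means(sub).sort_values("start", kind="stable")
    win["log2_ratio"] = np.log2((win["M"] + pseudocount) / (win["F"] + pseudocount))
    profile = win[["start", "end", "M", "F", "log2_ratio", "partial"]].reset_index(
        drop=True
    )
    full = profile[~profile["partial"]]
    stats: dict = {
        "ratio_dispersion": float(full["log2_ratio"].var(ddof=1))
        if len(full) > 1
        else float("nan")
    }
    if segments is not None:
        seg_means = {}
        for name, start, end in segments:
            inside = full[(full["start"] >= start) & (full["end"] <= end)]
            seg_means[name] = float(inside["log2_ratio"].mean())
        stats["segment_means"] = seg_means
        vals = list(seg_means.values())
        stats["segment_abs_diff"] = float(
            max(abs(a - b) for a in vals for b in vals) if len(vals) > 1 else 0.0
        )
    return profile, stats


# ---------------------------------------------------------------------------
# Plain-text IO
# ---------------------------------------------------------------------------


def read_depth_tsv(path: str | Path) -> pd.DataFrame:
    """Multi-sample per-position depth text: scaffold, pos, then one column
    per sample (samtools-depth style, 1-based positions)."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["scaffold", "pos"]:
        raise ValueError(f"{path}: expected leading columns (scaffold, pos)")
    return df


def read_window_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Precomputed per-window counts: scaffold, start, end, sample, count."""
    df = pd.read_csv(path, sep="\t")
    required = {"scaffold", "start", "end", "sample", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df.rename(columns={"count": "raw"})


def read_sample_sheet(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    if not {"sample_id", "sex"} <= set(df.columns):
        raise ValueError(f"{path}: sample sheet needs columns (sample_id, sex)")
    return dict(zip(df["sample_id"].astype(str), df["sex"].astype(str)))


def write_summary_tsv(summary: pd.DataFrame, path: str | Path) -> None:
    summary.reset_index().to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_profile_tsv(profile: pd.DataFrame, path: str | Path) -> None:
    profile.to_csv(path, sep="\t", index=False, float_format="%.6g")
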