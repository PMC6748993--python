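"""Canonical k-mer counting and sex-differential k-mer analysis.

This module covers the read-pool side of sex-chromosome characterization in a
female-heterogametic (ZW) system:

* canonical k-mer counting over FASTA/FASTQ read pools (a k-mer and its
  reverse complement are merged under the lexicographically smaller form, so
  counts are strand-independent);
* genome-size estimation from the k-mer depth histogram (haploid size ~
  total non-error k-mer observations divided by the homozygous peak depth);
* per-k-mer exact binomial tests of female enrichment between a male and a
  female pool, BH-corrected, to nominate W-linked sequence;
* greedy single-linkage clustering of significant k-mers by (k-1)-overlap
  into unitig-like candidate repeat families.

K-mers are represented internally as 2-bit packed ``uint64`` codes
(A=0, C=1, G=2, T=3), which makes the lexicographic minimum of a k-mer and
its reverse complement equal to the numeric minimum of their codes.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_K = 21

_BASES = "ACGT"
_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _CODE_LUT[ord(_b)] = _i
    _CODE_LUT[ord(_b.lower())] = _i
_BYTE_LUT = np.frombuffer(_BASES.encode(), dtype=np.uint8)

_RC_TABLE = str.maketrans("ACGTacgt", "TGCAtgca")


def _check_k(k: int) -> None:
    if not isinstance(k, (int, np.integer)) or k < 1 or k > 31:
        raise ValueError(f"k must be an integer in [1, 31], got {k}")
    if k % 2 == 0:
        raise ValueError(f"k must be odd so canonical form is unambiguous, got {k}")


def encode_bases(seq: str | bytes) -> np.ndarray:
    """Map a nucleotide string to 2-bit codes (255 marks non-ACGT symbols)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _CODE_LUT[np.frombuffer(seq, dtype=np.uint8)]


def decode_bases(codes: np.ndarray) -> str:
    return _BYTE_LUT[codes].tobytes().decode("ascii")


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """All k-mer codes of a 2-bit coded sequence; windows with non-ACGT skipped."""
    _check_k(k)
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    bad = codes == 255
    clean = np.where(bad, 0, codes).astype(np.uint64)
    vals = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        vals = (vals << np.uint64(2)) | clean[j : j + n]
    if bad.any():
        cs = np.concatenate(([0], np.cumsum(bad)))
        vals = vals[cs[k:] - cs[:-k] == 0]
    return vals


def _build_rc16() -> np.ndarray:
    # reverse complement of every 8-base (16-bit) chunk
    v = np.arange(65536, dtype=np.uint64)
    rc = np.zeros_like(v)
    for _ in range(8):
        rc = (rc << np.uint64(2)) | (np.uint64(3) - (v & np.uint64(3)))
        v >>= np.uint64(2)
    return rc


_RC16 = _build_rc16()


def revcomp_codes(vals: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement of packed k-mer codes (8-base chunk lookup)."""
    v = np.asarray(vals, dtype=np.uint64)
    n_chunks = (k + 7) // 8
    # pad the sequence end with A's up to a whole number of chunks; their
    # complements land above bit 2k and are masked off at the end
    v = v << np.uint64(2 * (8 * n_chunks - k))
    rc = np.zeros_like(v)
    for i in range(n_chunks):
        chunk = (v >> np.uint64(16 * i)) & np.uint64(0xFFFF)
        rc |= _RC16[chunk.astype(np.intp)] << np.uint64(16 * (n_chunks - 1 - i))
    return rc & np.uint64(4**k - 1)


def canonical_codes(vals: np.ndarray, k: int) -> np.ndarray:
    return np.minimum(np.asarray(vals, dtype=np.uint64), revcomp_codes(vals, k))


def decode_codes(vals: np.ndarray, k: int) -> np.ndarray:
    """Packed codes back to k-mer strings."""
    vals = np.asarray(vals, dtype=np.uint64)
    chars = np.empty((vals.size, k), dtype=np.uint8)
    for j in range(k):
        shift = np.uint64(2 * (k - 1 - j))
        chars[:, j] = _BYTE_LUT[((vals >> shift) & np.uint64(3)).astype(np.intp)]
    flat = np.ascontiguousarray(chars).reshape(-1).view(f"S{k}")
    return flat.astype(str)


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


def unique_counts(
    codes: np.ndarray, counts: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Sorted unique codes with aggregated counts (sort-based; large uint64
    arrays take a slow path through plain ``np.unique``)."""
    codes = np.asarray(codes, dtype=np.uint64)
    if codes.size == 0:
        return codes, np.zeros(0, dtype=np.int64)
    if counts is None:
        s = np.sort(codes)
        new = np.empty(s.size, dtype=bool)
        new[0] = True
        np.not_equal(s[1:], s[:-1], out=new[1:])
        starts = np.flatnonzero(new)
        tot = np.diff(np.append(starts, s.size)).astype(np.int64)
        return s[starts], tot
    order = np.argsort(codes, kind="stable")
    s = codes[order]
    c = np.asarray(counts, dtype=np.int64)[order]
    new = np.empty(s.size, dtype=bool)
    new[0] = True
    np.not_equal(s[1:], s[:-1], out=new[1:])
    starts = np.flatnonzero(new)
    tot = np.add.reduceat(c, starts)
    return s[starts], tot


def _sorted_union(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Union of two sorted unique uint64 arrays."""
    if a.size == 0:
        return b.copy()
    if b.size == 0:
        return a.copy()
    idx = np.searchsorted(a, b)
    in_a = np.zeros(b.size, dtype=bool)
    inside = idx < a.size
    in_a[inside] = a[idx[inside]] == b[inside]
    return np.sort(np.concatenate([a, b[~in_a]]))


def canonical_kmer(seq: str) -> str:
    rc = reverse_complement(seq)
    return seq if seq <= rc else rc


@dataclass
class KmerCountTable:
    """Canonical k-mer counts for one read pool.

    ``codes`` are sorted unique packed k-mers, ``counts`` the matching
    occurrence counts; ``library_size`` is the total number of counted k-mer
    instances (sum of counts unless an external counter supplied its own).
    """

    k: int
    codes: np.ndarray
    counts: np.ndarray
    library_size: int | None = None

    def __post_init__(self) -> None:
        _check_k(self.k)
        self.codes = np.asarray(self.codes, dtype=np.uint64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.codes.shape != self.counts.shape:
            raise ValueError("codes and counts must have identical shape")
        if self.counts.size and self.counts.min() < 1:
            raise ValueError("stored k-mer counts must be >= 1")
        if self.library_size is None:
            self.library_size = int(self.counts.sum())

    @classmethod
    def from_codes(
        cls, k: int, codes: np.ndarray, counts: np.ndarray | None = None
    ) -> "KmerCountTable":
        """Aggregate possibly duplicated (code, count) pairs into a table."""
        uniq, tot = unique_counts(codes, counts)
        keep = tot > 0
        return cls(k, uniq[keep], tot[keep])

    def __len__(self) -> int:
        return int(self.codes.size)

    def kmers(self) -> np.ndarray:
        return decode_codes(self.codes, self.k)

    def histogram(self) -> np.ndarray:
        """hist[d] = number of distinct k-mers observed exactly d times."""
        if self.counts.size == 0:
            return np.zeros(1, dtype=np.int64)
        return np.bincount(self.counts)

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"#k={self.k}\n#library_size={self.library_size}\n")
            for km, c in zip(self.kmers(), self.counts):
                fh.write(f"{km}\t{c}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KmerCountTable":
        k = None
        library_size = None
        kmers: list[str] = []
        counts: list[int] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    key, _, val = line[1:].partition("=")
                    if key == "k":
                        k = int(val)
                    elif key == "library_size":
                        library_size = int(val)
                    continue
                km, cnt = line.split("\t")
                kmers.append(km)
                counts.append(int(cnt))
        if k is None:
            if not kmers:
                raise ValueError(f"{path}: empty k-mer table without a #k header")
            k = len(kmers[0])
        codes = np.array(
            [int(kmer_codes(encode_bases(s), k)[0]) for s in kmers], dtype=np.uint64
        )
        order = np.argsort(codes)
        return cls(
            k,
            codes[order],
            np.asarray(counts, dtype=np.int64)[order],
            library_size=library_size,
        )


def _iter_sequences(reads) -> Iterable[str]:
    from Bio import SeqIO

    if isinstance(reads, (str, Path)):
        path = Path(reads)
        suffix = path.suffix.lower()
        fmt = "fastq" if suffix in {".fq", ".fastq"} else "fasta"
        for rec in SeqIO.parse(str(path), fmt):
            yield str(rec.seq)
        return
    for item in reads:
        yield item if isinstance(item, str) else str(item.seq)


def count_canonical_kmers(reads, k: int = DEFAULT_K) -> KmerCountTable:
    """Count canonical k-mers of a read pool.

    ``reads`` may be a FASTA/FASTQ path (format guessed from the extension)
    or any iterable of sequence strings / SeqRecords.  Reads shorter than k
    contribute nothing; k-mers containing non-ACGT symbols are skipped.
    """
    _check_k(k)
    chunks: list[np.ndarray] = []
    for seq in _iter_sequences(reads):
        vals = kmer_codes(encode_bases(seq), k)
        if vals.size:
            chunks.append(canonical_codes(vals, k))
    if not chunks:
        return KmerCountTable(k, np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64))
    return KmerCountTable.from_codes(k, np.concatenate(chunks))


# ---------------------------------------------------------------------------
# Genome size from the k-mer histogram
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeSizeEstimate:
    """Haploid genome size from a k-mer depth histogram.

    size_bp = (sum of d * hist[d] over d > error_threshold) / peak_depth.
    """

    peak_depth: float
    total_kmers: int
    size_bp: float
    error_threshold: int


def _dense_histogram(histogram) -> np.ndarray:
    if isinstance(histogram, Mapping):
        if not histogram:
            raise ValueError("empty k-mer histogram")
        max_d = max(int(d) for d in histogram)
        h = np.zeros(max_d + 1, dtype=float)
        for d, c in histogram.items():
            h[int(d)] = float(c)
        return h
    if isinstance(histogram, pd.Series):
        return _dense_histogram(histogram.to_dict())
    h = np.asarray(histogram, dtype=float)
    if h.ndim != 1:
        raise ValueError("histogram must be one-dimensional (index = depth)")
    return h


def estimate_genome_size(histogram) -> GenomeSizeEstimate:
    """Estimate haploid genome size from depth -> #distinct-k-mers counts.

    The error threshold is placed at the first depth (scanning upward from 1)
    where the histogram stops decreasing, which separates the low-depth error
    peak from the coverage peak.  The peak depth is the modal depth above the
    threshold, refined by a +-2-bin centroid because the raw mode of a
    near-Poisson histogram is unstable when adjacent bins are equiprobable.
    """
    h = _dense_histogram(histogram)
    if h.size < 3:
        raise ValueError("histogram too short to locate a coverage peak")
    h = h.copy()
    h[0] = 0.0
    threshold = None
    for d in range(1, h.size - 1):
        if h[d] <= h[d + 1]:
            threshold = d
            break
    if threshold is None:
        raise ValueError(
            "no local minimum separates an error peak from a coverage peak "
            "(monotone histogram); deeper coverage is needed"
        )
    upper = h[threshold + 1 :]
    if not upper.any():
        raise ValueError("no k-mers above the error threshold")
    mode = threshold + 1 + int(np.argmax(upper))
    lo = max(threshold + 1, mode - 2)
    hi = min(h.size - 1, mode + 2)
    d_win = np.arange(lo, hi + 1, dtype=float)
    w = h[lo : hi + 1]
    peak_depth = float((d_win * w).sum() / w.sum())
    depths = np.arange(h.size, dtype=float)
    mask = depths > threshold
    total = float((depths[mask] * h[mask]).sum())
    return GenomeSizeEstimate(
        peak_depth=peak_depth,
        total_kmers=int(round(total)),
        size_bp=total / peak_depth,
        error_threshold=threshold,
    )


# ---------------------------------------------------------------------------
# Sex-differential enrichment
# ---------------------------------------------------------------------------


def _binom_pmf_vector(n: int, p: float) -> np.ndarray:
    """Binomial pmf over 0..n via log-gamma (cheaper than the scipy
    distribution machinery when called for many distinct n)."""
    from scipy.special import gammaln

    i = np.arange(n + 1, dtype=float)
    logpmf = (
        gammaln(n + 1)
        - gammaln(i + 1)
        - gammaln(n - i + 1)
        + i * np.log(p)
        + (n - i) * np.log1p(-p)
    )
    return np.exp(logpmf)


def binom_two_sided(k_obs: np.ndarray, n: np.ndarray, p0: float) -> np.ndarray:
    """Vectorized exact two-sided binomial test.

    Sums all outcome probabilities not exceeding the probability of the
    observed outcome (the minlike convention, matching
    ``scipy.stats.binomtest``), grouped by trial count for speed.
    """
    k_obs = np.asarray(k_obs, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    out = np.empty(k_obs.size, dtype=float)
    rel = 1.0 + 1e-7
    for n_val in np.unique(n):
        sel = n == n_val
        pmf = _binom_pmf_vector(int(n_val), p0)
        order = np.argsort(pmf, kind="stable")
        sorted_pmf = pmf[order]
        cum = np.cumsum(sorted_pmf)
        idx = np.searchsorted(sorted_pmf, pmf[k_obs[sel]] * rel, side="right")
        out[sel] = cum[np.maximum(idx, 1) - 1]
    return np.clip(out, 0.0, 1.0)


def test_sex_enrichment(
    male: KmerCountTable,
    female: KmerCountTable,
    min_total: int = 10,
    fdr: float = 0.05,
    min_enrichment: float = 4.0,
) -> pd.DataFrame:
    """Per-k-mer exact binomial test of female enrichment.

    For every canonical k-mer with combined count >= ``min_total`` the female
    count is tested two-sided against the library-size null
    p0 = female_lib / (male_lib + female_lib); p-values are BH-corrected over
    all tested k-mers.  ``significant`` marks female-enriched calls:
    q <= fdr and rate enrichment (pseudocount 0.5 on both counts, ratio only)
    >= ``min_enrichment``.

    Returns a DataFrame with columns code, male_count, female_count,
    enrichment, p_value, q_value, significant, sorted by q then enrichment
    (descending); k and library sizes are stored in ``.attrs``.
    """
    if male.k != female.k:
        raise ValueError(f"k mismatch between pools: {male.k} vs {female.k}")
    m_lib = int(male.library_size)
    f_lib = int(female.library_size)
    if m_lib <= 0 or f_lib <= 0:
        raise ValueError("both pools must have positive library size")

    codes = _sorted_union(male.codes, female.codes)
    m = np.zeros(codes.size, dtype=np.int64)
    f = np.zeros(codes.size, dtype=np.int64)
    m[np.searchsorted(codes, male.codes)] = male.counts
    f[np.searchsorted(codes, female.codes)] = female.counts

    keep = (m + f) >= min_total
    codes, m, f = codes[keep], m[keep], f[keep]
    n = m + f
    p0 = f_lib / (m_lib + f_lib)

    if codes.size:
        # p-values depend on (f, n) only; test unique pairs once.
        pair = f * (n.max() + 1) + n
        uniq, inv = np.unique(pair, return_inverse=True)
        uf = uniq // (n.max() + 1)
        un = uniq % (n.max() + 1)
        pvals = binom_two_sided(uf, un, p0)[inv]
        qvals = multipletests(pvals, method="fdr_bh")[1]
    else:
        pvals = np.empty(0, dtype=float)
        qvals = np.empty(0, dtype=float)

    enrichment = ((f + 0.5) / f_lib) / ((m + 0.5) / m_lib)
    df = pd.DataFrame(
        {
            "code": codes,
            "male_count": m,
            "female_count": f,
            "enrichment": enrichment,
            "p_value": pvals,
            "q_value": qvals,
        }
    )
    df["significant"] = (df["q_value"] <= fdr) & (df["enrichment"] >= min_enrichment)
    df = df.sort_values(
        ["q_value", "enrichment"], ascending=[True, False], kind="stable"
    ).reset_index(drop=True)
    df.attrs.update(k=male.k, male_lib=m_lib, female_lib=f_lib, fdr=fdr,
                    min_enrichment=min_enrichment, min_total=min_total)
    return df


# ---------------------------------------------------------------------------
# Overlap clustering of significant k-mers
# ---------------------------------------------------------------------------


@dataclass
class RepeatFamilyCall:
    """A candidate W-linked repeat family: a connected set of significant
    k-mers under (k-1)-overlap, with a greedy consensus path."""

    family_id: str
    kmers: list[str]
    score: float  # median enrichment of member k-mers
    consensus: str
    total_female_count: int = 0

    def __len__(self) -> int:
        return len(self.kmers)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _greedy_consensus(members: Sequence[str], k: int, seed_kmer: str) -> str:
    """Assemble a representative path through the family's overlap graph."""
    unused = set(members)
    cur = seed_kmer
    unused.discard(seed_kmer)

    def extensions(end: str, side: str) -> list[tuple[str, str]]:
        hits = []
        for m in unused:
            for orient in (m, reverse_complement(m)):
                if side == "right" and orient[: k - 1] == end:
                    hits.append((m, orient))
                    break
                if side == "left" and orient[-(k - 1) :] == end:
                    hits.append((m, orient))
                    break
        return hits

    extended = True
    while extended:
        extended = False
        hits = extensions(cur[-(k - 1) :], "right")
        if len(hits) == 1:
            m, orient = hits[0]
            cur = cur + orient[-1]
            unused.discard(m)
            extended = True
            continue
        hits = extensions(cur[: k - 1], "left")
        if len(hits) == 1:
            m, orient = hits[0]
            cur = orient[0] + cur
            unused.discard(m)
            extended = True
    return cur


def cluster_enriched(
    records: pd.DataFrame,
    k: int | None = None,
    min_female_count: int | None = None,
) -> list[RepeatFamilyCall]:
    """Cluster significant female-enriched k-mers into candidate repeat
    families by single-linkage (k-1)-overlap.

    ``min_female_count`` optionally restricts clustering to high-abundance
    k-mers (counts above the single-copy coverage peak), the signature of
    repetitive sequence; without it every significant k-mer is clustered.
    Families are sorted by member count (descending), then score.
    """
    if k is None:
        k = records.attrs.get("k")
        if k is None:
            raise ValueError("k not given and not recorded on the records table")
    sig = records[records["significant"]] if "significant" in records else records
    if min_female_count is not None:
        sig = sig[sig["female_count"] >= min_female_count]
    if len(sig) == 0:
        return []
    strs = decode_codes(sig["code"].to_numpy(dtype=np.uint64), k)
    enr = sig["enrichment"].to_numpy()
    fcnt = sig["female_count"].to_numpy()

    uf = _UnionFind(len(strs))
    seen: dict[str, int] = {}
    for i, s in enumerate(strs):
        for sub in (s[: k - 1], s[1:]):
            key = canonical_kmer(sub)
            if key in seen:
                uf.union(seen[key], i)
            else:
                seen[key] = i

    groups: dict[int, list[int]] = {}
    for i in range(len(strs)):
        groups.setdefault(uf.find(i), []).append(i)

    families = []
    for idxs in groups.values():
        members = sorted(strs[i] for i in idxs)
        seed_kmer = members[0]
        fam = RepeatFamilyCall(
            family_id="",
            kmers=members,
            score=float(np.median(enr[idxs])),
            consensus=_greedy_consensus(members, k, seed_kmer),
            total_female_count=int(fcnt[idxs].sum()),
        )
        families.append(fam)
    families.sort(key=lambda f: (-len(f.kmers), -f.score, f.kmers[0]))
    for i, fam in enumerate(families, start=1):
        fam.family_id = f"W-fam-{i}"
    return families


def write_enrichment_tsv(records: pd.DataFrame, path: str | Path, only_significant: bool = True) -> None:
    df = records[records["significant"]] if only_significant else records
    k = records.attrs.get("k")
    out = df.copy()
    if k is not None and len(out):
        out.insert(0, "kmer", decode_codes(out.pop("code").to_numpy(dtype=np.uint64), k))
    elif "code" in out:
        out = out.rename(columns={"code": "kmer"})
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_families(families: Sequence[RepeatFamilyCall], tsv_path: str | Path, fasta_path: str | Path) -> None:
    rows = [
        {
            "family_id": f.family_id,
            "n_kmers": len(f.kmers),
            "score": f.score,
            "consensus_length": len(f.consensus),
            "total_female_count": f.total_female_count,
        }
        for f in families
    ]
    pd.DataFrame(rows, columns=["family_id", "n_kmers", "score", "consensus_length", "total_female_count"]).to_csv(
        tsv_path, sep="\t", index=False, float_format="%.6g"
    )
    with open(fasta_path, "w") as fh:
        for f in families:
            fh.write(f">{f.family_id} n_kmers={len(f.kmers)} score={f.score:.4g}\n{f.consensus}\n")
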