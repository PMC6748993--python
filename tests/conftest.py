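"""Shared fixtures: one default simulation reused across the suite.

The default configuration is the study condition for every recovery check
(27 autosomes + Z + W, 3 samples per sex, mean depth 30, three planted
fusions, two planted W repeat families); session scoping avoids paying for
the simulation more than once.
"""
from __future__ import annotations

import pytest

import zwscout as zw
from zwscout import kmers as km

FIXTURE_SEED = 1


@pytest.fixture(scope="session")
def default_config() -> zw.SimConfig:
    return zw.SimConfig(seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def default_model(default_config) -> zw.GenomeModel:
    return zw.build_genome_model(default_config)


@pytest.fixture(scope="session")
def default_depth(default_model):
    table, truth = zw.simulate_depth(default_model)
    return table, truth


@pytest.fixture(scope="session")
def default_labeled(default_depth):
    table, truth = default_depth
    norm = zw.normalize_by_sample_median(table)
    summary = zw.summarize_by_sex(norm)
    return zw.classify(summary), norm, truth


@pytest.fixture(scope="session")
def default_anchors(default_model):
    return zw.emit_anchor_map(default_model)


@pytest.fixture(scope="session")
def default_kmer_pools(default_model):
    male, female, truth = zw.simulate_kmer_pools(default_model)
    return male, female, truth


@pytest.fixture(scope="session")
def default_enrichment(default_kmer_pools):
    male, female, _ = default_kmer_pools
    return zw.test_sex_enrichment(male, female)


def planted_kmer_sets(model: zw.GenomeModel, k: int = 21) -> dict[str, set[str]]:
    """Canonical k-mer sets of each planted repeat family consensus."""
    out = {}
    for fam in model.planted_repeats:
        out[fam.family_id] = {
            km.canonical_kmer(fam.consensus[i : i + k])
            for i in range(len(fam.consensus) - k + 1)
        }
    return out


def family_recovery(families, planted: dict[str, set[str]], min_containment=0.9):
    """Match recovered families to planted ones by k-mer containment.

    A planted family counts as recovered when some called family has >=
    ``min_containment`` of its k-mers inside that planted set (boundary
    k-mers reaching one base into the flanking sequence are tolerated).
    """
    recovered = set()
    for fam in families:
        ks = set(fam.kmers)
        if not ks:
            continue
        best_id, best = None, 0.0
        for pid, pset in planted.items():
            frac = len(ks & pset) / len(ks)
            if frac > best:
                best_id, best = pid, frac
        if best_id is not None and best >= min_containment:
            recovered.add(best_id)
    return recovered
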