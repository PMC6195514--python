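"""Shared fixtures: small synthetic workspaces and random-interval helpers."""

from __future__ import annotations

import pytest

from peakcalibre.core import GenomicInterval, Peak
from peakcalibre.pipeline import PipelineConfig
from peakcalibre.simulate import SyntheticConfig, generate_workspace


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=100_000, max_len=2_000):
    out = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, span - max_len))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


def random_peaks(rng, n, prefix="p", **kwargs):
    ivs = random_intervals(rng, n, **kwargs)
    return [
        Peak(iv, f"{prefix}{i}", float(rng.uniform(1, 30)),
             float(rng.uniform(5, 50)), float(rng.uniform(2, 40)),
             int(rng.integers(0, len(iv))) if rng.random() < 0.8 else None)
        for i, iv in enumerate(ivs)
    ]


def brute_force_any_overlap(queries, subjects):
    def iv(x):
        return x.interval if isinstance(x, Peak) else x

    out = []
    for q in queries:
        qi = iv(q)
        out.append(any(
            qi.chrom == iv(s).chrom
            and max(0, min(qi.end, iv(s).end) - max(qi.start, iv(s).start)) > 0
            for s in subjects
        ))
    return out


@pytest.fixture(scope="session")
def small_workspace(tmp_path_factory):
    """A 300-peak synthetic workspace shared across pipeline-level tests."""
    outdir = tmp_path_factory.mktemp("ws")
    return generate_workspace(SyntheticConfig(seed=11, n_peaks=300), outdir)


@pytest.fixture(scope="session")
def small_pipeline_config(small_workspace):
    ws = small_workspace
    return PipelineConfig(
        peaks=ws.peaks, genes=ws.genes, modulated_genes=ws.modulated_genes,
        blacklist=ws.blacklist, states=ws.states,
        companion_b=ws.companion_b, companion_c=ws.companion_c,
        peak_sequences=ws.peak_sequences, pwms=ws.pwms,
    )
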