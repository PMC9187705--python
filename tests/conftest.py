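"""Shared fixtures: synthetic genomes reused across test modules.

Expensive simulations are session-scoped so acceptance and property
tests share them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import rtprofiler as rt


@pytest.fixture(scope="session")
def sim22():
    """22-chromosome genome (4 Mb each, 3 origins/chrom), 2e5 reads/phase,
    seed 1: raw reads, bin table, normalized profile and ground truth."""
    rng = np.random.default_rng(1)
    landscapes = {
        f"chr{i + 1}": rt.random_landscape(4_000_000, 3, rng) for i in range(22)
    }
    cfg = rt.SimConfig(n_reads_g1=200_000, n_reads_s=200_000, seed=1)
    g1, s = rt.simulate_genome(landscapes, cfg)
    bins, report = rt.bin_reads(g1, s)
    profile = rt.rt_profile_from_bins(bins)
    return {
        "landscapes": landscapes,
        "g1": g1,
        "s": s,
        "bins": bins,
        "report": report,
        "profile": profile,
    }


@pytest.fixture(scope="session")
def recovery_runs():
    """Ten seeds of the 100-Mb, 50-origin, 1e6-reads/phase simulation with
    the true landscape kept alongside the recovered profile."""
    runs = []
    for seed in range(10):
        rng = np.random.default_rng(1000 + seed)
        landscape = rt.random_landscape(100_000_000, 50, rng)
        cfg = rt.SimConfig(n_reads_g1=1_000_000, n_reads_s=1_000_000, seed=seed)
        g1 = rt.sample_reads(landscape, cfg, "G1")
        s = rt.sample_reads(landscape, cfg, "S")
        profile, _ = rt.rt_profile_from_reads(g1, s)
        runs.append({"landscape": landscape, "profile": profile, "seed": seed})
    return runs


def _offset_genome(offset: float, landscape_seed: int, cen: tuple[int, int]):
    """22 chromosomes sharing origin geometry; origins inside the
    centromeric interval get their firing time shifted by ``offset``."""
    rng = np.random.default_rng(landscape_seed)
    landscapes = {}
    for i in range(22):
        base = rt.random_landscape(4_000_000, 6, rng, firing_range=(0.2, 0.4))
        origins = tuple(
            (p, float(np.clip(t + offset, 0.0, 0.99)) if cen[0] <= p < cen[1] else t)
            for p, t in base.origins
        )
        landscapes[f"chr{i + 1}"] = rt.Landscape(4_000_000, origins, base.fork_speed)
    return landscapes


@pytest.fixture(scope="session")
def ranking_sim():
    """Three samples whose centromeric origins fire 0.1 earlier / as-is /
    0.1 later than a shared base landscape."""
    cen = (1_500_000, 2_500_000)
    regions = pd.DataFrame(
        {"chrom": [f"chr{i + 1}" for i in range(22)], "start": cen[0], "end": cen[1]}
    )
    profiles = {}
    for k, (name, offset) in enumerate(
        [("sampleA", -0.1), ("sampleB", 0.0), ("sampleC", 0.1)]
    ):
        landscapes = _offset_genome(offset, landscape_seed=42, cen=cen)
        cfg = rt.SimConfig(n_reads_g1=2_000_000, n_reads_s=2_000_000, seed=1 + k)
        g1, s = rt.simulate_genome(landscapes, cfg)
        profile, _ = rt.rt_profile_from_reads(g1, s)
        profiles[name] = profile
    return {"profiles": profiles, "regions": regions}
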