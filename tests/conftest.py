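"""Shared fixtures: a small synthetic study set reused across modules.

The 60 kb host keeps end-to-end tests fast; the full-scale 200 kb analogue
lives in the acceptance suite.
"""
from __future__ import annotations

import numpy as np
import pytest

import tdnakit as tk


@pytest.fixture(scope="session")
def refs60():
    hosts, pmap, aux = tk.make_references(seed=7, host_len=60_000)
    return hosts, pmap, aux


@pytest.fixture(scope="session")
def event60(refs60):
    """2-copy head-to-head event with a 36 bp deletion on the 60 kb host."""
    hosts, pmap, aux = refs60
    rng = np.random.default_rng(7)
    lo, hi = aux["site_zone"]
    site = tk.pick_clean_site(
        hosts[0], pmap, rng, lo=lo, hi=hi,
        exclude=[(iv.start, iv.end) for iv in aux["homolog_host_intervals"]],
    )
    genome, truth = tk.build_event_genome(hosts[0], pmap, site, 2, "head_to_head", 36)
    return genome, truth


@pytest.fixture(scope="session")
def run60(refs60, event60):
    """One full characterization of the 60 kb event (GM + WT)."""
    hosts, pmap, aux = refs60
    genome, truth = event60
    gm = tk.simulate_reads(genome, tk.SimConfig(depth=29.0, seed=11), "gm")
    wt = tk.simulate_reads(hosts[0], tk.SimConfig(depth=29.0, seed=12), "wt")
    report = tk.characterize(hosts, pmap, gm, wt, aux["sps_interval"])
    return report, truth
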