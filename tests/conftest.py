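"""Shared fixtures: quick repertoire builders and a small simulated experiment."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from clonetrace.repio import KeyMode, Repertoire, SampleMeta
from clonetrace.simulate import SimConfig, simulate_experiment

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def build_repertoire(
    counts,
    cdr3_aa=None,
    v_gene=None,
    j_gene=None,
    sample_id="s1",
    mouse_id="m1",
    group="syngeneic",
    tissue="blood",
    day=7,
    key=KeyMode.AA,
):
    """Construct a collapsed repertoire directly from template counts."""
    n = len(counts)
    aa = cdr3_aa if cdr3_aa is not None else [f"CASS{i:04d}F" for i in range(n)]
    v = v_gene if v_gene is not None else ["V12"] * n
    j = j_gene if j_gene is not None else ["J2-7"] * n
    df = pd.DataFrame(
        {
            "cdr3_nt": ["" for _ in range(n)],
            "cdr3_aa": aa,
            "v_gene": v,
            "d_gene": ["D1"] * n,
            "j_gene": j,
            "templates": list(counts),
        }
    )
    meta = SampleMeta(sample_id=sample_id, mouse_id=mouse_id, group=group, tissue=tissue, day=day)
    return Repertoire(meta, df, key=key)


def random_repertoire(rng: np.random.Generator, n_clones=None, sample_id="r1", **meta_kwargs):
    """A random repertoire with 5-200 clones and counts 1-10^4."""
    n = int(n_clones) if n_clones is not None else int(rng.integers(5, 201))
    counts = rng.integers(1, 10_001, size=n)
    v = rng.choice(["V12", "V13", "V26", "V31"], size=n)
    j = rng.choice(["J1-1", "J2-5", "J2-7"], size=n)
    aa = [f"CASS{i:05d}F" for i in range(n)]
    return build_repertoire(counts, cdr3_aa=aa, v_gene=list(v), j_gene=list(j),
                            sample_id=sample_id, **meta_kwargs)


@pytest.fixture
def make_rep():
    return build_repertoire


@pytest.fixture
def rng():
    return np.random.default_rng(20240501)


SMALL_SIM = SimConfig(
    n_clones=3000,
    n_syn=2,
    n_allo=2,
    depth_lymphoid=3000,
    depth_parenchymal=1500,
    donor_sample_depth=2000,
    activated_per_recipient=20,
    seed=7,
)


@pytest.fixture(scope="session")
def small_experiment():
    """A reduced-scale simulated experiment reused across integration tests."""
    return simulate_experiment(SMALL_SIM)
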