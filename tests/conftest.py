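"""Shared fixtures: parameterised simulations and synthetic CDS helpers."""

from __future__ import annotations

import numpy as np
import pytest

from oryzasyn.region import AnnotatedRegion, GeneFeature
from oryzasyn.simulate import (
    EvolutionParams,
    build_ancestor,
    evolve_lineages,
)

NONSTOP_CODONS = sorted(
    c
    for c in (a + b + d for a in "ACGT" for b in "ACGT" for d in "ACGT")
    if c not in ("TAA", "TAG", "TGA")
)


@pytest.fixture(scope="session")
def sim_factory():
    """Factory producing (params, ancestor, lineage A, lineage B, truth)."""

    cache: dict = {}

    def make(seed: int = 1, **overrides):
        key = (seed, tuple(sorted(overrides.items(), key=lambda kv: kv[0])))
        strkey = repr(key)
        if strkey not in cache:
            kw = dict(region_length=120_000, gene_count=20)
            kw.update(overrides)
            params = EvolutionParams(seed=seed, **kw)
            ancestor = build_ancestor(params)
            lin_a, lin_b, truth = evolve_lineages(ancestor, params)
            cache[strkey] = (params, ancestor, lin_a, lin_b, truth)
        return cache[strkey]

    return make


@pytest.fixture()
def rng():
    return np.random.default_rng(20260101)


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG-initiated CDS of non-stop codons (no trailing stop)."""
    body = "".join(rng.choice(NONSTOP_CODONS, size=n_codons - 1))
    return "ATG" + body


@pytest.fixture()
def toy_inversion_region() -> AnnotatedRegion:
    """100 kb region with inverted duplicate flank genes at 10-12 kb (+) and
    60-62 kb (-) and an internal marker gene at 30-31 kb (+)."""
    rng = np.random.default_rng(77)
    seq = list("".join(rng.choice(list("ACGT"), size=100_000)))
    flank = "ATG" + "".join(np.random.default_rng(78).choice(NONSTOP_CODONS, size=665)) + "TAA"
    assert len(flank) == 2001
    seq[9999:12000] = list(flank)  # 1-based [10000, 12000], '+' strand
    from oryzasyn.region import revcomp

    seq[59999:62000] = list(revcomp(flank))  # 1-based [60000, 62000], '-' strand
    region = AnnotatedRegion(
        id="toy",
        sequence="".join(seq),
        genes=[
            GeneFeature("flankA", (10_000, 12_000), "+"),
            GeneFeature("internal", (30_000, 31_000), "+", kind="pseudogene"),
            GeneFeature("flankB", (60_000, 62_000), "-"),
        ],
    )
    region.validate()
    return region
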