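"""Forward simulator: determinism, bookkeeping, and the inversion operator."""

import numpy as np
import pytest

from oryzasyn.region import revcomp, write_region_bundle
from oryzasyn.simulate import (
    DuplicationEvent,
    EvolutionParams,
    InversionSpec,
    apply_ectopic_inversion,
    build_ancestor,
    evolve_lineages,
    simulate_bes_library,
)


def test_zero_genes_empty_case():
    p = EvolutionParams(seed=0, region_length=10_000, gene_count=0)
    region = build_ancestor(p)
    assert region.length == 10_000
    assert region.genes == []


def test_same_seed_byte_identical_bundles(tmp_path):
    p = EvolutionParams(seed=42, region_length=60_000, gene_count=10)
    files = []
    for run in ("one", "two"):
        anc = build_ancestor(p)
        a, b, _ = evolve_lineages(anc, p)
        d = tmp_path / run
        paths = []
        for r in (anc, a, b):
            paths.extend(write_region_bundle(r, d))
        files.append(paths)
    for p1, p2 in zip(*files):
        assert open(p1).read() == open(p2).read()


def test_gene_spacing_matches_target_density():
    p = EvolutionParams(seed=7, region_length=600_000, gene_count=100)
    region = build_ancestor(p)
    starts = sorted(g.start for g in region.genes)
    spacing = np.diff(starts).mean()
    assert abs(spacing - 6000) / 6000 < 0.20


def test_infeasible_packing_is_an_explicit_error():
    with pytest.raises(ValueError, match="pack"):
        EvolutionParams(seed=0, region_length=10_000, gene_count=50)


def test_omega_length_mismatch_is_an_error():
    p = EvolutionParams(seed=0, region_length=60_000, gene_count=10)
    anc = build_ancestor(p)
    p2 = EvolutionParams(seed=0, region_length=60_000, gene_count=10)
    p2.omega_per_gene = [0.1] * 7  # bypass __post_init__ deliberately
    with pytest.raises(ValueError, match="omega"):
        evolve_lineages(anc, p2)


def test_zero_evolution_reproduces_the_ancestor():
    p = EvolutionParams(
        seed=3,
        region_length=60_000,
        gene_count=10,
        branch_sub_rate=0.0,
        te_insertions_per_branch=0,
        pack_mule_captures_per_branch=0,
    )
    anc = build_ancestor(p)
    a, b, truth = evolve_lineages(anc, p)
    assert a.sequence == anc.sequence == b.sequence
    assert [g.span for g in a.sorted_genes()] == [g.span for g in anc.sorted_genes()]
    assert truth.te_insertions == [] and truth.duplications == []


def test_length_bookkeeping_against_truth(sim_factory):
    _, anc, a, b, truth = sim_factory(seed=11)
    assert a.length == anc.length + truth.inserted_bp("A")
    assert b.length == anc.length + truth.inserted_bp("B")


def test_descendant_features_trace_to_truth_or_ancestor(sim_factory):
    params, anc, a, b, truth = sim_factory(seed=13)
    ancestral = {g.id for g in anc.genes}
    new_gene_ids = {r.pseudogene_id for r in truth.pack_mules if r.lineage == "A"} | {
        r.new_gene for r in truth.duplications if r.lineage in ("A", "ancestral")
    }
    for g in a.genes:
        assert g.id in ancestral or g.id in new_gene_ids
    te_ids = {r.te_id for r in truth.te_insertions if r.lineage == "A"} | {
        r.te_id for r in truth.pack_mules if r.lineage == "A"
    }
    assert {t.id for t in a.tes} == te_ids


def test_pack_mule_pseudogenes_are_te_enclosed(sim_factory):
    _, _, a, _, truth = sim_factory(seed=13)
    mules = {r.te_id: r for r in truth.pack_mules if r.lineage == "A"}
    psi = [g for g in a.genes if g.enclosed_in_te in mules]
    assert len(psi) == len(mules)
    for g in psi:
        host = next(t for t in a.tes if t.id == g.enclosed_in_te)
        assert host.start <= g.start and g.end <= host.end
        assert host.captured_gene is not None
        assert g.is_pseudogene


# ----- ectopic inversion -----------------------------------------------------


def test_inversion_toy_coordinate_arithmetic(toy_inversion_region):
    out = apply_ectopic_inversion(toy_inversion_region, "flankA", "flankB")
    assert out.length == toy_inversion_region.length == 100_000
    internal = out.gene("internal")
    assert internal.span == (41_000, 42_000)
    assert internal.strand == "-"


def test_inversion_is_an_involution(toy_inversion_region):
    once = apply_ectopic_inversion(toy_inversion_region, "flankA", "flankB")
    assert once.sequence != toy_inversion_region.sequence
    twice = apply_ectopic_inversion(once, "flankA", "flankB")
    assert twice.sequence == toy_inversion_region.sequence
    assert [g.span for g in twice.sorted_genes()] == [
        g.span for g in toy_inversion_region.sorted_genes()
    ]


def test_inversion_preserves_flank_cds(toy_inversion_region):
    before_a = toy_inversion_region.gene("flankA").cds(toy_inversion_region.sequence)
    before_b = toy_inversion_region.gene("flankB").cds(toy_inversion_region.sequence)
    out = apply_ectopic_inversion(toy_inversion_region, "flankA", "flankB")
    assert out.gene("flankA").cds(out.sequence) == before_a
    assert out.gene("flankB").cds(out.sequence) == before_b
    # internal sequence reverse-complemented: position y maps from 72000 - y
    assert out.sequence[34_999:36_000] == revcomp(toy_inversion_region.sequence[35_999:37_000])


def test_inversion_rejects_same_strand_and_overlap(toy_inversion_region):
    region = toy_inversion_region.copy()
    region.gene("flankB").strand = "+"
    with pytest.raises(ValueError, match="strand"):
        apply_ectopic_inversion(region, "flankA", "flankB")
    region2 = toy_inversion_region.copy()
    region2.gene("flankB").span = (11_000, 13_000)
    with pytest.raises(ValueError, match="overlap"):
        apply_ectopic_inversion(region2, "flankA", "flankB")


def test_evolved_inversion_truth_record(sim_factory):
    _, _, a, b, truth = sim_factory(
        seed=21, region_length=200_000, gene_count=33, inversion_spec=InversionSpec(45_000)
    )
    inv = truth.inversion
    assert inv is not None and inv.lineage == "A"
    left, right = inv.breakpoints
    assert 40_000 <= right - left <= 90_000  # 45 kb core plus inserted elements
    # flank genes exist in both lineages (ancestral duplication)
    for region in (a, b):
        assert region.gene(inv.flank_a) and region.gene(inv.flank_b)


# ----- BES library -----------------------------------------------------------


def test_bes_reads_are_fragment_ends(sim_factory):
    params, _, a, _, _ = sim_factory(seed=2)
    lib = simulate_bes_library(a, 5, params, seed=9)
    r = params.bes_read_length
    for pair in lib:
        s, e = pair.truth_interval
        frag = a.sequence[s - 1 : e]
        assert pair.read1 == frag[:r]
        assert pair.read2 == revcomp(frag[-r:])


def test_bes_library_deterministic(sim_factory):
    params, _, a, _, _ = sim_factory(seed=2)
    lib1 = simulate_bes_library(a, 10, params, seed=4)
    lib2 = simulate_bes_library(a, 10, params, seed=4)
    assert [(p.bac_id, p.read1, p.read2, p.truth_interval) for p in lib1] == [
        (p.bac_id, p.read1, p.read2, p.truth_interval) for p in lib2
    ]


def test_bes_library_rejects_nonpositive_n(sim_factory):
    params, _, a, _, _ = sim_factory(seed=2)
    with pytest.raises(ValueError):
        simulate_bes_library(a, 0, params, seed=1)


def test_duplication_modes(sim_factory):
    _, _, a, _, truth = sim_factory(
        seed=31,
        region_length=150_000,
        gene_count=25,
        duplication_events=[
            DuplicationEvent("g005", "tandem", "same", "A"),
            DuplicationEvent("g010", "dispersed", "opposite", "A"),
        ],
    )
    recs = {r.source_gene: r for r in truth.duplications if r.lineage == "A"}
    tandem_copy = a.gene(recs["g005"].new_gene)
    src = a.gene("g005")
    assert tandem_copy.strand == src.strand
    assert abs(tandem_copy.start - src.end) < 10_000
    disp_copy = a.gene(recs["g010"].new_gene)
    src2 = a.gene("g010")
    assert disp_copy.strand != src2.strand
    assert disp_copy.cds(a.sequence) == src2.cds(a.sequence)
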