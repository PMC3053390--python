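"""Gene-pair scoring, ortholog assignment, family clustering, disruptions."""

import pytest

from oryzasyn.collinearity import (
    assign_orthologs,
    classify_disruptions,
    cluster_families,
    family_from_members,
    score_gene_pairs,
    score_pair,
)
from oryzasyn.pipeline import family_separation_bp, published_family_table
from oryzasyn.simulate import DuplicationEvent
from tests.conftest import random_cds


def test_gene_vs_itself_scores_perfect(rng):
    cds = random_cds(rng, 150)
    identity, coverage, _ = score_pair(cds, cds)
    assert identity == 100.0
    assert coverage == 1.0


def test_one_mismatch_in_300_gives_99_667(rng):
    a = random_cds(rng, 100)  # 300 bp
    i = 150
    repl = {"A": "C", "C": "A", "G": "T", "T": "G"}[a[i]]
    b = a[:i] + repl + a[i + 1 :]
    identity, coverage, _ = score_pair(a, b)
    assert identity == pytest.approx(100 * 299 / 300, abs=1e-3)
    assert coverage == 1.0


def test_score_symmetry(rng):
    a = random_cds(rng, 120)
    b_list = list(a)
    for _ in range(20):
        i = int(rng.integers(0, len(a)))
        b_list[i] = str(rng.choice(list("ACGT")))
    b = "".join(b_list)
    ia, ca, _ = score_pair(a, b)
    ib, cb, _ = score_pair(b, a)
    assert ia == pytest.approx(ib)
    assert ca == pytest.approx(cb)


def test_region_without_genes_gives_empty_matrix(sim_factory):
    _, _, a, _, _ = sim_factory(seed=1)
    empty = a.copy()
    empty.genes = []
    assert score_gene_pairs(empty, a) == []


def test_identical_regions_all_orthologs_conserved(sim_factory):
    _, _, a, _, _ = sim_factory(seed=1)
    scores = score_gene_pairs(a, a.copy())
    table = assign_orthologs(scores, a, a.copy())
    n_comparable = sum(1 for g in a.genes if g.enclosed_in_te is None)
    assert len(table.orthologs()) == n_comparable
    assert table.conserved_order_fraction == 1.0
    assert table.unpaired("A") == [] and table.unpaired("B") == []


def test_zero_event_simulation_has_no_unpaired_genes(sim_factory):
    _, _, a, b, _ = sim_factory(
        seed=8,
        te_insertions_per_branch=0,
        pack_mule_captures_per_branch=0,
    )
    scores = score_gene_pairs(a, b)
    table = assign_orthologs(scores, a, b)
    assert table.unpaired("A") == [] and table.unpaired("B") == []
    assert table.conserved_order_fraction == 1.0
    report = classify_disruptions(table, a, b)
    assert report.is_empty()


def test_duplications_and_mule_captures_match_truth(sim_factory):
    _, _, a, b, truth = sim_factory(
        seed=14,
        region_length=150_000,
        gene_count=25,
        te_insertions_per_branch=0,
        pack_mule_captures_per_branch=2,
        duplication_events=[
            DuplicationEvent("g003", "tandem", "same", "A"),
            DuplicationEvent("g012", "tandem", "same", "A"),
            DuplicationEvent("g018", "tandem", "opposite", "A"),
        ],
    )
    scores = score_gene_pairs(a, b)
    table = assign_orthologs(scores, a, b)
    report = classify_disruptions(table, a, b)
    dup_copies = {r.new_gene for r in truth.duplications if r.lineage == "A"}
    extra_a = {g for g, _ in report.extra_in_a}
    # every tandem copy surfaces as extra-in-A (as ortholog or duplicate of its source)
    relations = {
        p.gene_a: p.relation for p in table.pairs if p.gene_a in dup_copies
    }
    for copy in dup_copies:
        assert relations.get(copy) in ("co-ortholog-duplicate", "ortholog") or copy in extra_a
    # pack-MULE pseudogenes are TE-enclosed and excluded from the matrix,
    # hence never orthologs
    psi = {r.pseudogene_id for r in truth.pack_mules if r.lineage == "A"}
    assert psi.isdisjoint({p.gene_a for p in table.orthologs()})


def test_te_enclosed_extra_genes_are_flagged(sim_factory):
    _, _, a, b, truth = sim_factory(
        seed=15,
        region_length=150_000,
        gene_count=25,
        te_insertions_per_branch=0,
        pack_mule_captures_per_branch=4,
    )
    # make the captured pseudogenes visible to the comparison by clearing the
    # enclosure tag on the gene (the enclosing pack-MULE annotation remains)
    psi = {r.pseudogene_id for r in truth.pack_mules if r.lineage == "A"}
    for g in a.genes:
        if g.id in psi:
            g.enclosed_in_te = None
    scores = score_gene_pairs(a, b)
    table = assign_orthologs(scores, a, b)
    report = classify_disruptions(table, a, b)
    flagged = {g for g, te in report.extra_in_a if te}
    assert psi <= flagged


# ----- families ---------------------------------------------------------------


def test_family_clustering_on_simulated_tandem_array(sim_factory):
    _, _, a, _, truth = sim_factory(
        seed=16,
        region_length=150_000,
        gene_count=25,
        te_insertions_per_branch=0,
        pack_mule_captures_per_branch=0,
        duplication_events=[
            DuplicationEvent("g007", "tandem", "same", "A"),
            DuplicationEvent("g019", "dispersed", "opposite", "A"),
        ],
    )
    fams = cluster_families(a)
    by_members = {frozenset(f.members) for f in fams}
    dup = {r.source_gene: r.new_gene for r in truth.duplications if r.lineage == "A"}
    assert frozenset({"g007", dup["g007"]}) in by_members
    assert frozenset({"g019", dup["g019"]}) in by_members
    tandem_fam = next(f for f in fams if "g007" in f.members)
    assert tandem_fam.arrangement == "tandem-cluster"
    assert tandem_fam.orientation_pattern == "same"
    disp_fam = next(f for f in fams if "g019" in f.members)
    assert disp_fam.orientation_pattern == "opposite"


def test_region_without_duplicates_has_no_families(sim_factory):
    _, _, a, _, _ = sim_factory(
        seed=17, te_insertions_per_branch=0, pack_mule_captures_per_branch=0
    )
    assert cluster_families(a) == []


# ----- printed coordinate table (published families) ---------------------------


def test_published_family_i_dispersed_opposite_154kb():
    table = published_family_table()
    rows = table[table["family"] == "I"]
    members = [
        (r["gene"], (int(r["start"]), int(r["end"])), r["strand"]) for _, r in rows.iterrows()
    ]
    fam = family_from_members("I", members)
    assert len(fam.members) == 2
    assert fam.arrangement == "dispersed"
    assert fam.orientation_pattern == "opposite"
    assert fam.max_separation == 154_391
    assert family_separation_bp(table, "I") == 315_435 - 161_044


def test_published_family_iv_same_orientation():
    table = published_family_table()
    rows = table[table["family"] == "IV"]
    members = [
        (r["gene"], (int(r["start"]), int(r["end"])), r["strand"]) for _, r in rows.iterrows()
    ]
    fam = family_from_members("IV", members)
    assert len(fam.members) == 7
    assert fam.orientation_pattern == "same"
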