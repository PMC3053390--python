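"""Dot plot, block chaining, inversion detection, TE attribution."""

import numpy as np
import pytest

from oryzasyn.collinearity import assign_orthologs, cluster_families, score_gene_pairs
from oryzasyn.region import revcomp
from oryzasyn.simulate import (
    EvolutionParams,
    InversionSpec,
    apply_ectopic_inversion,
    build_ancestor,
    evolve_lineages,
)
from oryzasyn.structure import (
    attribute_size_difference,
    compute_dotplot,
    detect_rearranged_segments,
)

K = 16


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def test_self_dotplot_contains_full_main_diagonal(rng):
    seq = _random_seq(rng, 3000)
    matches = compute_dotplot(seq, seq, k=K)
    diag = {(m.pos_a, m.pos_b) for m in matches if m.strand == "+"}
    for i in range(1, len(seq) - K + 2):
        assert (i, i) in diag


def test_revcomp_dotplot_all_minus_strand(rng):
    seq = _random_seq(rng, 3000)
    matches = compute_dotplot(seq, revcomp(seq), k=K)
    assert matches and all(m.strand == "-" for m in matches)


def test_short_sequence_gives_empty_list(rng):
    assert compute_dotplot("ACGTACGT", _random_seq(rng, 100), k=16) == []


def test_k_floor_enforced():
    with pytest.raises(ValueError):
        compute_dotplot("A" * 100, "C" * 100, k=4)


def test_chance_match_count_is_binomial(rng):
    """Unrelated 50 kb sequences share ~L^2/4^k k-mers per strand."""
    n = 50_000
    a, b = _random_seq(rng, n), _random_seq(rng, n)
    matches = compute_dotplot(a, b, k=K)
    n_kmers = n - K + 1
    expected = n_kmers * n_kmers / 4**K  # per strand
    sigma = np.sqrt(expected)
    for strand in "+-":
        observed = sum(1 for m in matches if m.strand == strand)
        assert abs(observed - expected) <= 3 * sigma + 1


def test_colinear_pair_single_plus_block_no_inversions(sim_factory):
    _, _, a, b, _ = sim_factory(
        seed=23,
        te_insertions_per_branch=0,
        pack_mule_captures_per_branch=0,
    )
    matches = compute_dotplot(a.sequence, b.sequence, k=K)
    blocks, calls = detect_rearranged_segments(matches)
    assert calls == []
    plus = [blk for blk in blocks if blk.orientation == "+"]
    assert len(plus) == 1
    covered = plus[0].ref_length()
    assert covered >= 0.99 * a.length


def test_simulated_45kb_inversion_is_recovered(sim_factory):
    _, _, a, b, truth = sim_factory(
        seed=7, region_length=200_000, gene_count=33, inversion_spec=InversionSpec(45_000)
    )
    matches = compute_dotplot(a.sequence, b.sequence, k=K)
    fams = cluster_families(a)
    blocks, calls = detect_rearranged_segments(
        matches, families=fams, ref_region=a, qry_region=b
    )
    assert len(calls) == 1
    call = calls[0]
    left, right = truth.inversion.breakpoints
    gap = 2000
    assert abs(call.ref_span[0] - left) <= K + gap
    assert abs(call.ref_span[1] - right) <= K + gap
    flank_fam = next(
        f for f in fams if truth.inversion.flank_a in f.members
    )
    assert call.flanking_duplicate_family == flank_fam.family_id


def test_inversion_detection_is_involutive(sim_factory):
    """One call on (region, inverted region); zero calls after re-inverting."""
    _, _, a, _, truth = sim_factory(
        seed=7, region_length=200_000, gene_count=33, inversion_spec=InversionSpec(45_000)
    )
    inv = truth.inversion
    back = apply_ectopic_inversion(a, inv.flank_a, inv.flank_b)  # undo
    m1 = compute_dotplot(back.sequence, a.sequence, k=K)
    _, calls1 = detect_rearranged_segments(m1)
    assert len(calls1) == 1
    again = apply_ectopic_inversion(back, inv.flank_a, inv.flank_b)  # redo
    m2 = compute_dotplot(again.sequence, a.sequence, k=K)
    _, calls2 = detect_rearranged_segments(m2)
    assert calls2 == []


def test_nested_inversions_do_not_crash(rng):
    """Two nested inverted segments: outer and inner signals both reported."""
    n = 120_000
    a = _random_seq(rng, n)
    b = list(a)
    # outer inversion 30k..90k
    b[30_000:90_000] = list(revcomp(a[30_000:90_000]))
    b = "".join(b)
    c = list(b)
    # inner segment (relative to b) re-inverted: appears '+' inside '-'
    c[50_000:70_000] = list(revcomp(b[50_000:70_000]))
    c = "".join(c)
    matches = compute_dotplot(a, c, k=K)
    blocks, calls = detect_rearranged_segments(matches, join_gap=5000)
    assert len(calls) >= 1
    total_minus = sum(c_.size for c_ in calls)
    assert total_minus >= 30_000


def test_identical_regions_have_zero_specific_te(sim_factory):
    _, _, a, _, _ = sim_factory(seed=25)
    twin = a.copy()
    scores = score_gene_pairs(a, twin)
    table = assign_orthologs(scores, a, twin)
    report = attribute_size_difference(a, twin, table)
    assert report.specific_bp == {"A": 0, "B": 0}


def test_asymmetric_te_load_recovered_within_one_element(sim_factory):
    _, _, a, b, truth = sim_factory(
        seed=26,
        region_length=150_000,
        gene_count=25,
        te_insertions_per_branch=(6, 0),
        pack_mule_captures_per_branch=0,
    )
    scores = score_gene_pairs(a, b)
    table = assign_orthologs(scores, a, b)
    report = attribute_size_difference(a, b, table)
    true_bp = sum(r.length for r in truth.te_insertions if r.lineage == "A")
    max_te = max((r.length for r in truth.te_insertions), default=0)
    assert report.specific_bp["B"] == 0
    assert abs(report.specific_bp["A"] - true_bp) <= max_te
    assert report.fraction["A"] == pytest.approx(report.specific_bp["A"] / a.length)


def test_te_fraction_arithmetic_single_element(sim_factory):
    _, _, a, b, truth = sim_factory(
        seed=27,
        region_length=150_000,
        gene_count=25,
        te_insertions_per_branch=(1, 0),
        pack_mule_captures_per_branch=0,
    )
    scores = score_gene_pairs(a, b)
    table = assign_orthologs(scores, a, b)
    report = attribute_size_difference(a, b, table)
    te = truth.te_insertions[0]
    assert report.specific_bp["A"] == te.length
    assert report.fraction["A"] == pytest.approx(te.length / a.length)


def test_attribution_requires_two_anchors(sim_factory):
    _, _, a, b, _ = sim_factory(seed=25)
    from oryzasyn.collinearity import OrthologTable

    with pytest.raises(ValueError, match="anchor"):
        attribute_size_difference(a, b, OrthologTable(pairs=[], conserved_order_fraction=1.0))


def test_dotplot_transpose_symmetry(rng):
    a, b = _random_seq(rng, 5000), _random_seq(rng, 5000)
    ab = {(m.pos_a, m.pos_b, m.strand) for m in compute_dotplot(a, b, k=12)}
    ba = {(m.pos_b, m.pos_a, m.strand) for m in compute_dotplot(b, a, k=12)}
    assert ab == ba
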