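"""Nei-Gojobori Ka/Ks against an exhaustive pathway enumerator, plus the
region summaries and the rank-based region comparison."""

import math
from fractions import Fraction
from itertools import permutations

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from oryzasyn.divergence import (
    DivergenceRecord,
    classify_selection,
    codon_differences,
    compare_regions,
    compute_ka_ks,
    jukes_cantor,
    pooled_omega,
    summarize_and_flag,
    synonymous_site_count,
)
from tests.conftest import NONSTOP_CODONS, random_cds

# ----- independent oracle ----------------------------------------------------


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_sites(codon: str) -> Fraction:
    """Synonymous site count by direct enumeration of all 9 mutations."""
    total = Fraction(0)
    for i in range(3):
        muts = [codon[:i] + b + codon[i + 1 :] for b in "ACGT" if b != codon[i]]
        valid = [m for m in muts if _aa(m) != "*"]
        if valid:
            total += Fraction(sum(_aa(m) == _aa(codon) for m in valid), len(valid))
    return total


def oracle_diffs(c1: str, c2: str) -> tuple[float, float]:
    """(nonsyn, syn) differences averaged over substitution orderings."""
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    paths = []
    for order in permutations(positions):
        cur, nd, sd, blocked = c1, 0, 0, False
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1 :]
            blocked = blocked or _aa(nxt) == "*"
            if _aa(nxt) == _aa(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((blocked, nd, sd))
    usable = [(n, s) for b, n, s in paths if not b] or [(n, s) for _, n, s in paths]
    return (
        sum(n for n, _ in usable) / len(usable),
        sum(s for _, s in usable) / len(usable),
    )


def test_ng86_oracle_equivalence_500_random_codon_pairs(rng):
    codons = rng.choice(NONSTOP_CODONS, size=(500, 2))
    for c1, c2 in codons:
        assert synonymous_site_count(c1) == pytest.approx(float(oracle_sites(c1)), abs=1e-12)
        nd, sd = codon_differences(c1, c2)
        ond, osd = oracle_diffs(c1, c2)
        assert nd == pytest.approx(ond, abs=1e-12)
        assert sd == pytest.approx(osd, abs=1e-12)


# ----- whole-CDS behaviour ---------------------------------------------------


def test_identical_cds_zero_rates(rng):
    cds = random_cds(rng, 100)
    r = compute_ka_ks(cds, cds)
    assert r.nd == r.sd == 0
    assert r.ka == r.ks == 0.0
    assert r.n_sites + r.s_sites == pytest.approx(3 * r.aligned_codons)


def test_single_synonymous_third_position_change():
    """GGG->GGA in a run of unambiguous codons: Sd=1, Nd=0, Ks=JC(1/S)."""
    a = "ATG" + "GGG" * 99
    b = a[:-1] + "A"
    r = compute_ka_ks(a, b)
    assert r.sd == 1 and r.nd == 0
    expected_s = float(oracle_sites("ATG") + 98 * oracle_sites("GGG") + oracle_sites("GGA") / 2 + oracle_sites("GGG") / 2)
    assert r.s_sites == pytest.approx(expected_s, abs=1e-9)
    assert r.ka == 0.0
    assert r.ks == pytest.approx(jukes_cantor(1 / r.s_sites))


def test_single_nonsynonymous_first_position_change():
    a = "ATG" + "GGG" * 99
    b = a[:3] + "AGG" + a[6:]  # Gly -> Arg at codon 2
    r = compute_ka_ks(a, b)
    assert r.nd == 1 and r.sd == 0
    assert r.ks == 0.0
    assert r.ka == pytest.approx(jukes_cantor(1 / r.n_sites))


def test_symmetry(rng):
    a = random_cds(rng, 80)
    b_list = list(a)
    for _ in range(12):
        i = int(rng.integers(3, len(a)))
        b_list[i] = str(rng.choice(list("ACGT")))
    b = "".join(b_list)
    r1, r2 = compute_ka_ks(a, b), compute_ka_ks(b, a)
    for attr in ("n_sites", "s_sites", "nd", "sd", "ka", "ks"):
        assert getattr(r1, attr) == pytest.approx(getattr(r2, attr), abs=1e-9)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1), st.integers(min_value=10, max_value=80))
def test_sites_partition_exactly(seed, n_codons):
    """N + S == 3 x aligned codons, exactly, for random CDS pairs."""
    rng = np.random.default_rng(seed)
    a = random_cds(rng, n_codons)
    b = random_cds(rng, n_codons)
    r = compute_ka_ks(a, b)
    assert r.n_sites + r.s_sites == pytest.approx(3 * r.aligned_codons, abs=1e-9)


def test_jc_strictly_increasing_on_valid_range():
    ps = np.linspace(0.0, 0.74, 200)
    ds = [jukes_cantor(p) for p in ps]
    assert all(b > a for a, b in zip(ds, ds[1:]))
    assert jukes_cantor(0.75) is None
    assert jukes_cantor(0.9) is None


def test_gapped_codons_are_excluded(rng):
    a = random_cds(rng, 60)
    b = a[:30] + a[33:]  # delete one codon
    r = compute_ka_ks(a, b)
    assert r.aligned_codons == 59
    assert r.excluded_codons >= 1


def test_biopython_ng86_agrees_loosely(rng):
    """Independent implementation cross-check (conventions differ slightly)."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
    for _ in range(5):
        a = random_cds(rng, 120)
        b_list = list(a)
        for _ in range(20):
            i = int(rng.integers(3, len(a)))
            b_list[i] = str(rng.choice(list("ACGT")))
        b = "".join(b_list)
        if "*" in _aa(b[: len(b) // 3 * 3]) or "*" in str(Seq(b).translate()):
            continue
        dn, ds = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86")
        r = compute_ka_ks(a, b)
        if ds > 0.005 and r.ks and r.ks > 0.005:
            assert r.ka == pytest.approx(dn, rel=0.15, abs=0.01)
            assert r.ks == pytest.approx(ds, rel=0.15, abs=0.01)


# ----- summaries and classification ------------------------------------------


def _rec(pair_id, ka, ks):
    omega = None if ks in (None, 0) or ka is None else ka / ks
    return DivergenceRecord(pair_id, 300, 100, 0, 0, 0, 0, ka, ks, omega, 100, 0)


def test_two_times_mean_flagging():
    records = [_rec("p1", 0.01, 0.03), _rec("p2", 0.01, 0.03), _rec("p3", 0.04, 0.03)]
    s = summarize_and_flag(records)
    assert s.mean_ka == pytest.approx(0.02)
    assert [e[0] for e in s.elevated] == ["p3"]
    assert s.elevated[0][1] == "Ka"


def test_equal_values_are_never_flagged():
    records = [_rec(f"p{i}", 0.02, 0.05) for i in range(5)]
    s = summarize_and_flag(records)
    assert s.elevated == []


def test_selection_classification_bands():
    assert classify_selection(_rec("a", 0.003, 0.03)) == "purifying"
    assert classify_selection(_rec("b", 0.03, 0.04)) == "neutral"
    assert classify_selection(_rec("c", 0.08, 0.04)) == "positive-or-relaxed"
    assert classify_selection(_rec("d", 0.0, 0.0)) == "undefined"
    # configurable thresholds
    assert classify_selection(_rec("e", 0.03, 0.04), thresholds=(0.8, 1.2)) == "purifying"


def test_pooled_omega_uses_summed_counts():
    r1 = DivergenceRecord("a", 200, 100, 2, 4, 0.01, 0.04, 0.01, 0.04, 0.25, 100, 0)
    r2 = DivergenceRecord("b", 200, 100, 0, 0, 0, 0, 0.0, 0.0, None, 100, 0)
    ka, ks, om = pooled_omega([r1, r2])
    assert ka == pytest.approx(jukes_cantor(2 / 400))
    assert ks == pytest.approx(jukes_cantor(4 / 200))
    assert om == pytest.approx(ka / ks)


# ----- Kruskal-Wallis ---------------------------------------------------------


def test_kruskal_wallis_closed_form_example():
    res = compare_regions({"g1": [1, 2, 3], "g2": [4, 5, 6]})
    assert res.statistic == pytest.approx(3.857, abs=0.001)
    assert res.df == 1
    assert 0 < res.p_value <= 1


def test_kruskal_wallis_identical_groups():
    res = compare_regions({"g1": [2.0, 2.0], "g2": [2.0, 2.0, 2.0]})
    assert res.statistic == 0.0
    assert res.p_value == 1.0
    assert not res.significant


def test_kruskal_wallis_type_i_error_rate():
    rng = np.random.default_rng(123)
    alpha = 0.05
    rejections = 0
    n_rep = 1000
    for _ in range(n_rep):
        groups = {k: list(rng.normal(size=12)) for k in ("a", "b", "c")}
        if compare_regions(groups, alpha=alpha).significant:
            rejections += 1
    assert 0.035 <= rejections / n_rep <= 0.065


def test_compare_regions_validates_input():
    with pytest.raises(ValueError):
        compare_regions({"only": [1.0, 2.0]})
    with pytest.raises(ValueError):
        compare_regions({"a": [1.0], "b": []})
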