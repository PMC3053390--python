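"""Pairwise coding-sequence divergence: Nei-Gojobori (1986) Ka/Ks.

For each ortholog pair the two CDSs are translated, the proteins globally
aligned (BLOSUM62, affine gaps), and the alignment back-threaded onto
codons.  Synonymous (S) and nonsynonymous (N) site counts follow the NG86
counting scheme: at each codon position the fraction of single-nucleotide
changes that are synonymous is accumulated, changes creating stop codons
are excluded from the denominator, and site counts are averaged between
the two sequences.  Observed differences in codons that differ at more
than one position are averaged over all substitution orderings, with
orderings that pass through a stop codon excluded.  Proportions are
corrected for multiple hits with the Jukes-Cantor formula

    d = -(3/4) * ln(1 - (4/3) p),

undefined for p >= 3/4.  omega = Ka/Ks summarises selective pressure:
far below 1 purifying selection, near 1 neutral evolution, above 1
positive selection or relaxed constraint.

Region-level summaries reproduce the flagging rule used for the rice
orthologous-region comparison (a pair is flagged when its Ka or Ks is at
least twice the region mean) and the rank-based Kruskal-Wallis comparison
of Ka/Ks distributions between regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable
from scipy import stats

# Standard genetic code; stops mapped to '*'.
_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"

_BASES = "ACGT"


class DivergenceError(ValueError):
    """Raised when no aligned codons survive the exclusion rules."""


@dataclass
class DivergenceRecord:
    pair_id: str
    n_sites: float  # nonsynonymous sites (N)
    s_sites: float  # synonymous sites (S)
    nd: float  # observed nonsynonymous differences
    sd: float  # observed synonymous differences
    pn: float
    ps: float
    ka: float | None  # None when pn >= 3/4 (JC undefined)
    ks: float | None
    omega: float | None  # Ka/Ks; None when Ks == 0 or either rate undefined
    aligned_codons: int
    excluded_codons: int

    @property
    def defined(self) -> bool:
        return self.ka is not None and self.ks is not None


@dataclass
class RegionDivergenceSummary:
    label: str
    n_pairs: int
    mean_ka: float
    mean_ks: float
    elevated: list[tuple[str, str]]  # (pair_id, reason in {'Ka','Ks','Ka+Ks'})
    class_counts: dict[str, int] = field(default_factory=dict)


@dataclass
class RegionComparisonResult:
    statistic: float  # tie-corrected Kruskal-Wallis H
    df: int
    p_value: float
    groups: list[tuple[str, int]]  # (label, size)
    alpha: float
    significant: bool


# ----- NG86 per-codon machinery ------------------------------------------


def synonymous_site_count(codon: str) -> float:
    """NG86 synonymous site count for one codon.

    At each position, the fraction of the possible single-nucleotide
    changes that are synonymous, with changes to stop codons removed from
    the denominator.  Total sites per codon = 3 (synonymous + nonsynonymous).
    """
    aa = CODON_TO_AA[codon]
    s = 0.0
    for i in range(3):
        syn = 0
        valid = 0
        for b in _BASES:
            if b == codon[i]:
                continue
            mut = codon[:i] + b + codon[i + 1 :]
            if CODON_TO_AA[mut] == "*":
                continue
            valid += 1
            if CODON_TO_AA[mut] == aa:
                syn += 1
        if valid:
            s += syn / valid
    return s


def codon_differences(c1: str, c2: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) differences between two codons, NG86 style.

    Averages over all orderings of the substitutions; orderings passing
    through a stop codon are excluded (all orderings are used if every one
    passes through a stop).
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    pathways = []
    for order in permutations(diff):
        cur = c1
        nd = sd = 0
        blocked = False
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1 :]
            if CODON_TO_AA[nxt] == "*":
                blocked = True
            if CODON_TO_AA[nxt] == CODON_TO_AA[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        pathways.append((blocked, nd, sd))
    open_paths = [(nd, sd) for blocked, nd, sd in pathways if not blocked]
    if not open_paths:
        open_paths = [(nd, sd) for _, nd, sd in pathways]
    nd = sum(p[0] for p in open_paths) / len(open_paths)
    sd = sum(p[1] for p in open_paths) / len(open_paths)
    return nd, sd


def jukes_cantor(p: float) -> float | None:
    """JC69 multiple-hit correction; None when p >= 3/4 (saturated)."""
    if p >= 0.75:
        return None
    if p <= 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


# ----- alignment back-threading -------------------------------------------


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def _codons(cds: str) -> list[str]:
    cds = cds.upper()
    usable = len(cds) - len(cds) % 3
    return [cds[i : i + 3] for i in range(0, usable, 3)]


def _translate(codons: list[str]) -> str:
    return "".join(CODON_TO_AA.get(c, "X") for c in codons)


def aligned_codon_pairs(cds_a: str, cds_b: str) -> tuple[list[tuple[str, str]], int]:
    """Codon pairs from the protein-level global alignment of two CDSs.

    Returns (pairs, excluded) where excluded counts aligned columns dropped
    for gaps, stops or ambiguous bases.
    """
    codons_a = _codons(cds_a)
    codons_b = _codons(cds_b)
    # Trim one trailing stop if present so it does not align as a residue.
    if codons_a and CODON_TO_AA.get(codons_a[-1]) == "*":
        codons_a = codons_a[:-1]
    if codons_b and CODON_TO_AA.get(codons_b[-1]) == "*":
        codons_b = codons_b[:-1]
    prot_a = _translate(codons_a)
    prot_b = _translate(codons_b)
    if not prot_a or not prot_b:
        raise DivergenceError("empty CDS after codon trimming")
    pairs: list[tuple[str, str]] = []
    excluded = 0
    if prot_a == prot_b or ("X" not in prot_a and "*" not in prot_a and prot_a == prot_b):
        pass  # handled by general path below; kept for clarity
    aligner = _protein_aligner()
    # PairwiseAligner cannot score 'X'/'*'; substitute a neutral residue for
    # alignment purposes only (the codons themselves are still filtered).
    safe_a = prot_a.replace("X", "A").replace("*", "A")
    safe_b = prot_b.replace("X", "A").replace("*", "A")
    alignment = aligner.align(safe_a, safe_b)[0]
    ia, ib = alignment.aligned
    for (sa, ea), (sb, eb) in zip(ia, ib):
        for off in range(ea - sa):
            ca = codons_a[sa + off]
            cb = codons_b[sb + off]
            if set(ca + cb) - set(_BASES):
                excluded += 1
                continue
            if CODON_TO_AA[ca] == "*" or CODON_TO_AA[cb] == "*":
                excluded += 1
                continue
            pairs.append((ca, cb))
    # gapped columns
    excluded += (len(codons_a) - sum(e - s for s, e in ia)) + (
        len(codons_b) - sum(e - s for s, e in ib)
    )
    return pairs, excluded


# ----- main operations ----------------------------------------------------


def compute_ka_ks(cds_a: str, cds_b: str, pair_id: str = "") -> DivergenceRecord:
    """NG86 Ka/Ks with Jukes-Cantor correction for one CDS pair."""
    pairs, excluded = aligned_codon_pairs(cds_a, cds_b)
    if not pairs:
        raise DivergenceError(f"{pair_id or 'pair'}: no aligned codons after exclusions")
    s_a = sum(synonymous_site_count(ca) for ca, _ in pairs)
    s_b = sum(synonymous_site_count(cb) for _, cb in pairs)
    s_sites = (s_a + s_b) / 2.0
    n_sites = 3.0 * len(pairs) - s_sites
    nd = sd = 0.0
    for ca, cb in pairs:
        d_n, d_s = codon_differences(ca, cb)
        nd += d_n
        sd += d_s
    pn = nd / n_sites if n_sites else 0.0
    ps = sd / s_sites if s_sites else 0.0
    ka = jukes_cantor(pn)
    ks = jukes_cantor(ps)
    omega = None
    if ka is not None and ks is not None and ks > 0:
        omega = ka / ks
    return DivergenceRecord(
        pair_id=pair_id,
        n_sites=n_sites,
        s_sites=s_sites,
        nd=nd,
        sd=sd,
        pn=pn,
        ps=ps,
        ka=ka,
        ks=ks,
        omega=omega,
        aligned_codons=len(pairs),
        excluded_codons=excluded,
    )


def pooled_omega(records: list[DivergenceRecord]) -> tuple[float | None, float | None, float | None]:
    """(Ka, Ks, omega) from NG86 counts pooled over a set of gene pairs.

    Sums sites and differences across pairs before the Jukes-Cantor step.
    This is the estimator of choice for a *set*-level omega: averaging
    per-gene ratios is biased upward because the synonymous denominator is
    noisy at low divergence.
    """
    n = sum(r.n_sites for r in records)
    s = sum(r.s_sites for r in records)
    nd = sum(r.nd for r in records)
    sd = sum(r.sd for r in records)
    if n == 0 or s == 0:
        return None, None, None
    ka = jukes_cantor(nd / n)
    ks = jukes_cantor(sd / s)
    omega = ka / ks if ka is not None and ks not in (None, 0.0) else None
    return ka, ks, omega


def classify_selection(
    record: DivergenceRecord, thresholds: tuple[float, float] = (0.5, 1.0)
) -> str:
    """Selection class from omega: purifying / neutral / positive-or-relaxed.

    omega < thresholds[0] -> purifying; <= thresholds[1] -> neutral;
    above -> positive-or-relaxed.  Undefined rates or Ks = 0 -> 'undefined'.
    """
    if record.ka is None or record.ks is None or record.ks == 0:
        return "undefined"
    low, high = thresholds
    omega = record.ka / record.ks
    if omega < low:
        return "purifying"
    if omega <= high:
        return "neutral"
    return "positive-or-relaxed"


def summarize_and_flag(
    records: list[DivergenceRecord],
    label: str = "region",
    factor: float = 2.0,
    thresholds: tuple[float, float] = (0.5, 1.0),
) -> RegionDivergenceSummary:
    """Region means plus the two-times-the-mean elevation flags.

    Means are arithmetic means over pairs whose rate is defined; a pair is
    flagged when Ka >= factor * mean(Ka) or Ks >= factor * mean(Ks), with
    the triggering rate(s) recorded as the reason.
    """
    if not any(r.defined for r in records):
        raise DivergenceError("no records with defined rates")
    kas = [r.ka for r in records if r.ka is not None]
    kss = [r.ks for r in records if r.ks is not None]
    mean_ka = sum(kas) / len(kas) if kas else 0.0
    mean_ks = sum(kss) / len(kss) if kss else 0.0
    elevated: list[tuple[str, str]] = []
    for r in records:
        reasons = []
        if r.ka is not None and mean_ka > 0 and r.ka >= factor * mean_ka:
            reasons.append("Ka")
        if r.ks is not None and mean_ks > 0 and r.ks >= factor * mean_ks:
            reasons.append("Ks")
        if reasons:
            elevated.append((r.pair_id, "+".join(reasons)))
    counts: dict[str, int] = {
        "purifying": 0,
        "neutral": 0,
        "positive-or-relaxed": 0,
        "undefined": 0,
    }
    for r in records:
        counts[classify_selection(r, thresholds)] += 1
    return RegionDivergenceSummary(
        label=label,
        n_pairs=len(records),
        mean_ka=mean_ka,
        mean_ks=mean_ks,
        elevated=elevated,
        class_counts=counts,
    )


def compare_regions(
    groups: dict[str, list[float]], alpha: float = 0.05
) -> RegionComparisonResult:
    """Tie-corrected Kruskal-Wallis comparison of rate distributions.

    All-identical values across every group give H = 0, p = 1 (no evidence
    of heterogeneity) rather than an error.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    samples = [list(groups[k]) for k in labels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group needs at least one value")
    flat = [v for s in samples for v in s]
    df = len(labels) - 1
    if all(v == flat[0] for v in flat):
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*samples)
    return RegionComparisonResult(
        statistic=float(h),
        df=df,
        p_value=float(p),
        groups=[(k, len(groups[k])) for k in labels],
        alpha=alpha,
        significant=bool(p < alpha),
    )
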