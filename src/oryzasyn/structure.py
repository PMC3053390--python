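"""Nucleotide-level structural comparison of two regions.

Exact shared k-mers form a dot plot; matches are chained into collinear
blocks on both strands; maximal reverse-strand chains are emitted as
inversion calls with breakpoint *intervals* (exact points are unknowable
when breakpoints fall inside duplicated genes, which is precisely how
ectopic-recombination inversions arise); and lineage-specific TE content
is summed by projecting each element through the bracketing ortholog
anchors into the other region.
"""

from __future__ import annotations

from dataclasses import dataclass

from .collinearity import GeneFamily, OrthologTable
from .region import AnnotatedRegion, Span, revcomp

K_DEFAULT = 16
GAP_DEFAULT = 2000  # chain gap tolerance g (same diagonal)
JOIN_GAP_DEFAULT = 20_000  # order-consistent block join across TE-scale indels
MIN_BLOCK_DEFAULT = 5000
MAX_KMER_OCCURRENCES = 50  # repetitive k-mers dropped before chaining


@dataclass
class Match:
    pos_a: int  # 1-based k-mer start on A, forward coordinates
    pos_b: int  # 1-based k-mer start on B, forward coordinates
    strand: str  # '+' : A[pa:pa+k] == B[pb:pb+k]; '-' : == revcomp(B[pb:pb+k])


@dataclass
class SyntenyBlock:
    ref_span: Span
    qry_span: Span
    orientation: str
    match_count: int
    mean_diag: float

    def ref_length(self) -> int:
        return self.ref_span[1] - self.ref_span[0] + 1


@dataclass
class InversionCall:
    ref_span: Span
    qry_span: Span
    breakpoint_left_ref: Span
    breakpoint_right_ref: Span
    breakpoint_left_qry: Span
    breakpoint_right_qry: Span
    flanking_duplicate_family: str | None
    size: int  # ref_span length

    orientation: str = "-"


@dataclass
class TEAccountingReport:
    specific_bp: dict[str, int]
    specific_count: dict[str, int]
    fraction: dict[str, float]
    region_length: dict[str, int]
    calls: list[tuple[str, str, str]]  # (lineage, te_id, 'lineage-specific'|'shared')


# ----- dot plot -------------------------------------------------------------


def compute_dotplot(seq_a: str, seq_b: str, k: int = K_DEFAULT) -> list[Match]:
    """All exact shared k-mers between two sequences, both strands.

    Positions are 1-based k-mer starts on forward coordinates.  K-mers
    occurring more than MAX_KMER_OCCURRENCES times on either sequence are
    dropped (repeat shadows would otherwise swamp the chaining).  Sequences
    shorter than k yield an empty list.  K-mers containing N never match.
    """
    if k < 8:
        raise ValueError("k must be >= 8")
    seq_a = seq_a.upper()
    seq_b = seq_b.upper()
    if len(seq_a) < k or len(seq_b) < k:
        return []
    index: dict[str, list[int]] = {}
    for i in range(len(seq_a) - k + 1):
        kmer = seq_a[i : i + k]
        index.setdefault(kmer, []).append(i + 1)
    overused = {km for km, pos in index.items() if len(pos) > MAX_KMER_OCCURRENCES or "N" in km}
    b_count: dict[str, int] = {}
    rc_b = revcomp(seq_b)
    for i in range(len(seq_b) - k + 1):
        for kmer in (seq_b[i : i + k], rc_b[len(seq_b) - k - i : len(seq_b) - i]):
            if kmer in index:
                b_count[kmer] = b_count.get(kmer, 0) + 1
    overused |= {km for km, c in b_count.items() if c > MAX_KMER_OCCURRENCES}
    matches: list[Match] = []
    for i in range(len(seq_b) - k + 1):
        fwd = seq_b[i : i + k]
        if fwd in index and fwd not in overused:
            for pa in index[fwd]:
                matches.append(Match(pa, i + 1, "+"))
        rev = revcomp(fwd)
        if rev in index and rev not in overused and "N" not in rev:
            for pa in index[rev]:
                matches.append(Match(pa, i + 1, "-"))
    matches.sort(key=lambda m: (m.pos_a, m.pos_b, m.strand))
    return matches


# ----- chaining and inversion calls -----------------------------------------


def _micro_blocks(matches: list[Match], strand: str, k: int, gap: int) -> list[SyntenyBlock]:
    """Split same-diagonal match runs at gaps > ``gap`` into micro-blocks."""
    groups: dict[int, list[Match]] = {}
    for m in matches:
        if m.strand != strand:
            continue
        diag = (m.pos_b - m.pos_a) if strand == "+" else (m.pos_b + m.pos_a)
        groups.setdefault(diag, []).append(m)
    blocks: list[SyntenyBlock] = []
    for diag, ms in groups.items():
        ms.sort(key=lambda m: m.pos_a)
        run = [ms[0]]
        for m in ms[1:]:
            if m.pos_a - run[-1].pos_a <= gap:
                run.append(m)
            else:
                blocks.append(_run_to_block(run, strand, diag, k))
                run = [m]
        blocks.append(_run_to_block(run, strand, diag, k))
    return blocks


def _run_to_block(run: list[Match], strand: str, diag: int, k: int) -> SyntenyBlock:
    pa0, pa1 = run[0].pos_a, run[-1].pos_a + k - 1
    bs = min(m.pos_b for m in run)
    be = max(m.pos_b for m in run) + k - 1
    return SyntenyBlock((pa0, pa1), (bs, be), strand, len(run), float(diag))


def _merge_blocks(blocks: list[SyntenyBlock], gap: int) -> list[SyntenyBlock]:
    """Merge consecutive same-strand micro-blocks across small indels."""
    if not blocks:
        return []
    blocks = sorted(blocks, key=lambda b: (b.ref_span[0], -b.match_count))
    merged = [blocks[0]]
    for b in blocks[1:]:
        last = merged[-1]
        ref_gap = b.ref_span[0] - last.ref_span[1]
        diag_shift = abs(b.mean_diag - last.mean_diag)
        if ref_gap <= gap and diag_shift <= 10 * gap:
            merged[-1] = SyntenyBlock(
                (last.ref_span[0], max(last.ref_span[1], b.ref_span[1])),
                (min(last.qry_span[0], b.qry_span[0]), max(last.qry_span[1], b.qry_span[1])),
                last.orientation,
                last.match_count + b.match_count,
                (last.mean_diag * last.match_count + b.mean_diag * b.match_count)
                / (last.match_count + b.match_count),
            )
        else:
            merged.append(b)
    return merged


def _join_blocks(blocks: list[SyntenyBlock], join_gap: int) -> list[SyntenyBlock]:
    """Join same-strand blocks separated by TE-scale insertions.

    Blocks are joined when both the reference gap and the query gap are at
    most ``join_gap`` and the query intervals advance in the direction the
    orientation dictates (increasing for '+', decreasing for '-').  This
    keeps one inversion one call even when lineage-specific elements have
    landed inside it.
    """
    if not blocks:
        return []
    blocks = sorted(blocks, key=lambda b: b.ref_span[0])
    out = [blocks[0]]
    for b in blocks[1:]:
        last = out[-1]
        ref_gap = b.ref_span[0] - last.ref_span[1]
        if last.orientation == "+":
            qry_gap = b.qry_span[0] - last.qry_span[1]
        else:
            qry_gap = last.qry_span[0] - b.qry_span[1]
        if -200 <= ref_gap <= join_gap and -200 <= qry_gap <= join_gap:
            out[-1] = SyntenyBlock(
                (last.ref_span[0], max(last.ref_span[1], b.ref_span[1])),
                (min(last.qry_span[0], b.qry_span[0]), max(last.qry_span[1], b.qry_span[1])),
                last.orientation,
                last.match_count + b.match_count,
                (last.mean_diag * last.match_count + b.mean_diag * b.match_count)
                / (last.match_count + b.match_count),
            )
        else:
            out.append(b)
    return out


def _drop_te_blocks(
    blocks: list[SyntenyBlock],
    ref_region: AnnotatedRegion | None,
    qry_region: AnnotatedRegion | None,
) -> list[SyntenyBlock]:
    """Drop blocks lying mostly (>=80%) inside one annotated TE on either side."""

    def inside_te(span: Span, region: AnnotatedRegion | None) -> bool:
        if region is None:
            return False
        length = span[1] - span[0] + 1
        for t in region.tes:
            ov = min(span[1], t.end) - max(span[0], t.start) + 1
            if ov >= 0.8 * length:
                return True
        return False

    return [
        b
        for b in blocks
        if not inside_te(b.ref_span, ref_region) and not inside_te(b.qry_span, qry_region)
    ]


def _cluster_by_ref_gap(
    blocks: list[SyntenyBlock], join_gap: int
) -> list[list[SyntenyBlock]]:
    """Group blocks whose reference spans lie within ``join_gap`` of each other."""
    if not blocks:
        return []
    blocks = sorted(blocks, key=lambda b: b.ref_span[0])
    clusters = [[blocks[0]]]
    for b in blocks[1:]:
        if b.ref_span[0] - max(m.ref_span[1] for m in clusters[-1]) <= join_gap:
            clusters[-1].append(b)
        else:
            clusters.append([b])
    return clusters


def _cluster_to_block(members: list[SyntenyBlock]) -> SyntenyBlock:
    total = sum(m.match_count for m in members)
    return SyntenyBlock(
        (min(m.ref_span[0] for m in members), max(m.ref_span[1] for m in members)),
        (min(m.qry_span[0] for m in members), max(m.qry_span[1] for m in members)),
        members[0].orientation,
        total,
        sum(m.mean_diag * m.match_count for m in members) / total,
    )


def _span_coverage(spans: list[Span], width: int) -> float:
    """Fraction of a width covered by the union of spans."""
    if width <= 0:
        return 0.0
    merged: list[list[int]] = []
    for s, e in sorted(spans):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return sum(e - s + 1 for s, e in merged) / width


def _drop_contained(blocks: list[SyntenyBlock]) -> list[SyntenyBlock]:
    """Same-orientation blocks must not overlap on the reference."""
    out: list[SyntenyBlock] = []
    for b in sorted(blocks, key=lambda b: (-(b.ref_length()), -b.match_count)):
        if any(
            o.orientation == b.orientation
            and not (b.ref_span[1] < o.ref_span[0] or b.ref_span[0] > o.ref_span[1])
            for o in out
        ):
            continue
        out.append(b)
    out.sort(key=lambda b: b.ref_span[0])
    return out


def detect_rearranged_segments(
    matches: list[Match],
    min_block: int = MIN_BLOCK_DEFAULT,
    gap: int = GAP_DEFAULT,
    k: int = K_DEFAULT,
    families: list[GeneFamily] | None = None,
    ref_region: AnnotatedRegion | None = None,
    qry_region: AnnotatedRegion | None = None,
    join_gap: int = JOIN_GAP_DEFAULT,
) -> tuple[list[SyntenyBlock], list[InversionCall]]:
    """Chain dot-plot matches into blocks and call inversions.

    Maximal reverse-strand chains spanning at least ``min_block`` bp on the
    reference become InversionCalls.  Breakpoint intervals are the gaps
    between the inverted block and its neighbouring forward blocks; when a
    duplicated gene family (from cluster_families) has members overlapping
    both reference breakpoint intervals, the call is annotated with that
    family — the signature of an ectopic-recombination origin.
    """
    plus = _merge_blocks(_micro_blocks(matches, "+", k, gap), gap)
    minus = _merge_blocks(_micro_blocks(matches, "-", k, gap), gap)
    noise_floor = 2 * k  # single stray k-mer hits are not blocks

    def solid(b: SyntenyBlock) -> bool:
        # genuine homologous runs are exact-match dense (a 2k-bp exact run
        # already yields 2k-k+1 matches); scattered chance hits that merge
        # across nearby diagonals are not blocks
        return (
            b.ref_length() >= noise_floor
            and b.match_count >= 10
            and b.match_count >= b.ref_length() / 100
        )

    plus = [b for b in plus if solid(b)]
    minus = [b for b in minus if solid(b)]
    # repeat masking: matches produced by mobile elements (e.g. captured
    # gene fragments inside pack-MULEs) are not positional homology
    plus = _drop_te_blocks(plus, ref_region, qry_region)
    minus = _drop_te_blocks(minus, ref_region, qry_region)
    plus = _join_blocks(plus, join_gap)
    # reverse-strand blocks from one inversion need no query monotonicity:
    # near-identical breakpoint duplicates match both query copies, so the
    # query intervals of adjacent '-' fragments legitimately overlap
    def plausible_inversion(members: list[SyntenyBlock]) -> bool:
        # a genuine inverted segment covers comparable, densely matched
        # extents on both sequences (up to lineage-specific insertions);
        # chains of scattered duplicate-gene artifacts do not
        b = _cluster_to_block(members)
        qry_len = b.qry_span[1] - b.qry_span[0] + 1
        ref_cov = _span_coverage([m.ref_span for m in members], b.ref_length())
        qry_cov = _span_coverage([m.qry_span for m in members], qry_len)
        return (
            b.ref_length() >= min_block
            and abs(qry_len - b.ref_length()) <= 2 * join_gap
            and ref_cov >= 0.5
            and qry_cov >= 0.5
        )

    minus = [
        _cluster_to_block(members)
        for members in _cluster_by_ref_gap(minus, join_gap)
        if plausible_inversion(members)
    ]
    blocks = _drop_contained(plus + minus)
    calls: list[InversionCall] = []
    plus_kept = [b for b in blocks if b.orientation == "+"]
    for b in blocks:
        if b.orientation != "-" or b.ref_length() < min_block:
            continue
        left_nb = [p for p in plus_kept if p.ref_span[1] < b.ref_span[0]]
        right_nb = [p for p in plus_kept if p.ref_span[0] > b.ref_span[1]]
        left_ref = (
            (left_nb[-1].ref_span[1], b.ref_span[0]) if left_nb else (1, b.ref_span[0])
        )
        right_ref = (
            (b.ref_span[1], right_nb[0].ref_span[0])
            if right_nb
            else (b.ref_span[1], b.ref_span[1])
        )
        left_qry = (
            (left_nb[-1].qry_span[1], b.qry_span[0]) if left_nb else (1, b.qry_span[0])
        )
        right_qry = (
            (b.qry_span[1], right_nb[0].qry_span[0])
            if right_nb
            else (b.qry_span[1], b.qry_span[1])
        )
        family = None
        if families and ref_region is not None:
            # breakpoints fall *inside* duplicated genes, so the block edge
            # lands at a gene boundary; search the interval widened inward
            # by the positional uncertainty k+gap
            slack = k + gap
            left_probe = (left_ref[0], left_ref[1] + slack)
            right_probe = (max(1, right_ref[0] - slack), right_ref[1])
            gene_span = {g.id: g.span for g in ref_region.genes}
            for fam in families:
                spans = [gene_span[m] for m in fam.members if m in gene_span]
                hits_left = any(_overlaps(s, left_probe) for s in spans)
                hits_right = any(_overlaps(s, right_probe) for s in spans)
                if hits_left and hits_right:
                    family = fam.family_id
                    break
        calls.append(
            InversionCall(
                ref_span=b.ref_span,
                qry_span=b.qry_span,
                breakpoint_left_ref=left_ref,
                breakpoint_right_ref=right_ref,
                breakpoint_left_qry=left_qry,
                breakpoint_right_qry=right_qry,
                flanking_duplicate_family=family,
                size=b.ref_length(),
            )
        )
    return blocks, calls


def _overlaps(a: Span, b: Span) -> bool:
    return not (a[1] < b[0] or a[0] > b[1])


# ----- TE size-difference attribution ---------------------------------------


def attribute_size_difference(
    region_a: AnnotatedRegion,
    region_b: AnnotatedRegion,
    table: OrthologTable,
) -> TEAccountingReport:
    """Classify each TE as lineage-specific or shared; sum specific bp.

    A TE is lineage-specific when no TE of the same class overlaps the
    interval obtained by projecting its bracketing ortholog anchors into
    the other region.  Requires at least two ortholog anchors.
    """
    orth = table.orthologs()
    if len(orth) < 2:
        raise ValueError("need at least 2 ortholog anchors to project intervals")
    gene_a = {g.id: g for g in region_a.genes}
    gene_b = {g.id: g for g in region_b.genes}
    anchors = sorted(
        (
            ((gene_a[p.gene_a].start + gene_a[p.gene_a].end) // 2,
             (gene_b[p.gene_b].start + gene_b[p.gene_b].end) // 2)
            for p in orth
        )
    )

    def classify(tes_here, region_here, tes_there, region_there, flip_anchor):
        calls = []
        for t in tes_here:
            prev_mid, next_mid = None, None
            for am, bm in anchors:
                here_mid, there_mid = (am, bm) if not flip_anchor else (bm, am)
                if here_mid <= t.start:
                    prev_mid = (here_mid, there_mid)
                if here_mid >= t.end and next_mid is None:
                    next_mid = (here_mid, there_mid)
            lo = prev_mid[1] if prev_mid else 1
            hi = next_mid[1] if next_mid else region_there.length
            proj = (min(lo, hi), max(lo, hi))
            shared = any(
                o.te_class == t.te_class and _overlaps(o.span, proj) for o in tes_there
            )
            calls.append((t, "shared" if shared else "lineage-specific"))
        return calls

    calls_a = classify(region_a.tes, region_a, region_b.tes, region_b, flip_anchor=False)
    calls_b = classify(region_b.tes, region_b, region_a.tes, region_a, flip_anchor=True)
    report = TEAccountingReport(
        specific_bp={"A": 0, "B": 0},
        specific_count={"A": 0, "B": 0},
        fraction={"A": 0.0, "B": 0.0},
        region_length={"A": region_a.length, "B": region_b.length},
        calls=[],
    )
    for lab, calls in (("A", calls_a), ("B", calls_b)):
        for t, verdict in calls:
            report.calls.append((lab, t.id, verdict))
            if verdict == "lineage-specific":
                report.specific_bp[lab] += t.length()
                report.specific_count[lab] += 1
        length = report.region_length[lab]
        report.fraction[lab] = report.specific_bp[lab] / length if length else 0.0
    return report


# ----- plotting --------------------------------------------------------------


def plot_dotplot(matches: list[Match], out_path: str, title: str = "") -> str:
    """Scatter dot plot of k-mer matches (forward black, reverse red)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 7))
    for strand, color in (("+", "black"), ("-", "red")):
        xs = [m.pos_a for m in matches if m.strand == strand]
        ys = [m.pos_b for m in matches if m.strand == strand]
        ax.plot(xs, ys, ".", ms=1, color=color, label=f"{strand} strand")
    ax.set_xlabel("reference position (bp)")
    ax.set_ylabel("query position (bp)")
    if title:
        ax.set_title(title)
    ax.legend(markerscale=10, loc="upper left")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
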