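"""Gene-level comparison of two annotated regions.

All-vs-all CDS similarity scores, reciprocal-best-hit ortholog assignment,
single-linkage clustering of duplicated gene families, and classification
of the events that disrupt microcollinearity (extra genes, TE-enclosed
gene copies, inversions, local order swaps).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from .region import AnnotatedRegion, GeneFeature, Span

# Reporting floor for pairwise scores; pairs below it are not emitted.
MIN_IDENTITY = 60.0
MIN_COVERAGE = 0.3
# Family membership thresholds (within-region paralogs).
FAMILY_IDENTITY = 70.0
FAMILY_COVERAGE = 0.5
# Tandem vs dispersed: max intervening non-member genes between neighbours.
TANDEM_MAX_INTERVENING = 10

_PREFILTER_K = 12


@dataclass
class GenePairScore:
    gene_a: str
    gene_b: str
    identity: float  # percent, gap-excluded
    coverage: float  # aligned (gap-free) columns / length of shorter CDS
    score: float


@dataclass
class OrthologPair:
    gene_a: str | None
    gene_b: str | None
    identity: float | None
    relation: str  # ortholog | co-ortholog-duplicate | unpaired-A | unpaired-B


@dataclass
class OrthologTable:
    pairs: list[OrthologPair]
    conserved_order_fraction: float

    def orthologs(self) -> list[OrthologPair]:
        return [p for p in self.pairs if p.relation == "ortholog"]

    def unpaired(self, side: str) -> list[str]:
        rel = f"unpaired-{side}"
        gid = {"A": "gene_a", "B": "gene_b"}[side]
        return [getattr(p, gid) for p in self.pairs if p.relation == rel]


@dataclass
class GeneFamily:
    family_id: str
    members: list[str]  # sorted by position
    arrangement: str  # tandem-cluster | dispersed
    orientation_pattern: str  # same | opposite | mixed
    max_separation: int  # bp between closest edges of the two farthest members


@dataclass
class DisruptionReport:
    extra_in_a: list[tuple[str, bool]] = field(default_factory=list)  # (gene, te_enclosed)
    extra_in_b: list[tuple[str, bool]] = field(default_factory=list)
    inverted: list[tuple[str, str]] = field(default_factory=list)  # ortholog pairs in '-' blocks
    rearranged: list[tuple[str, str]] = field(default_factory=list)

    def is_empty(self) -> bool:
        return not (self.extra_in_a or self.extra_in_b or self.inverted or self.rearranged)


# ----- scoring -------------------------------------------------------------


def _cds_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1.0
    aligner.mismatch_score = -2.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -2.0
    return aligner


def _comparable_genes(region: AnnotatedRegion) -> list[GeneFeature]:
    """Genes entering the similarity matrix: TE-enclosed copies are excluded."""
    return [g for g in region.sorted_genes() if g.enclosed_in_te is None]


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def score_pair(cds_a: str, cds_b: str) -> tuple[float, float, float] | None:
    """(identity %, coverage, score) of the best local alignment, or None if empty."""
    if not cds_a or not cds_b:
        return None
    aligner = _cds_aligner()
    alignments = aligner.align(cds_a, cds_b)
    if len(alignments) == 0:
        return None
    aln = alignments[0]
    counts = aln.counts()
    aligned = counts.identities + counts.mismatches
    if aligned == 0:
        return None
    identity = 100.0 * counts.identities / aligned
    coverage = aligned / min(len(cds_a), len(cds_b))
    return identity, coverage, float(aln.score)


def score_gene_pairs(
    region_a: AnnotatedRegion,
    region_b: AnnotatedRegion | None = None,
    min_identity: float = MIN_IDENTITY,
    min_coverage: float = MIN_COVERAGE,
) -> list[GenePairScore]:
    """All-vs-all CDS similarity between two regions (or within one).

    A shared-k-mer prefilter skips alignment of unrelated gene pairs; pairs
    below the reporting floor (identity or coverage) are omitted.  A region
    without genes yields an empty list.
    """
    self_mode = region_b is None
    genes_a = _comparable_genes(region_a)
    genes_b = genes_a if self_mode else _comparable_genes(region_b)
    cds_a = {g.id: g.cds(region_a.sequence).upper() for g in genes_a}
    cds_b = cds_a if self_mode else {g.id: g.cds(region_b.sequence).upper() for g in genes_b}
    kmers_b = {gid: _kmers(s, _PREFILTER_K) for gid, s in cds_b.items()}
    out: list[GenePairScore] = []
    for i, ga in enumerate(genes_a):
        ka = _kmers(cds_a[ga.id], _PREFILTER_K)
        others = genes_b[i + 1 :] if self_mode else genes_b
        for gb in others:
            if not (ka & kmers_b[gb.id]):
                continue
            res = score_pair(cds_a[ga.id], cds_b[gb.id])
            if res is None:
                continue
            identity, coverage, score = res
            if identity < min_identity or coverage < min_coverage:
                continue
            out.append(GenePairScore(ga.id, gb.id, identity, coverage, score))
    return out


# ----- ortholog assignment -------------------------------------------------


def _longest_increasing(seq: list[int]) -> set[int]:
    """Indices of one longest strictly increasing subsequence of ``seq``."""
    import bisect

    if not seq:
        return set()
    tails: list[int] = []  # values
    tails_idx: list[int] = []
    prev = [-1] * len(seq)
    for i, v in enumerate(seq):
        j = bisect.bisect_left(tails, v)
        if j == len(tails):
            tails.append(v)
            tails_idx.append(i)
        else:
            tails[j] = v
            tails_idx[j] = i
        prev[i] = tails_idx[j - 1] if j > 0 else -1
    out = set()
    i = tails_idx[-1]
    while i != -1:
        out.add(i)
        i = prev[i]
    return out


def assign_orthologs(
    scores: list[GenePairScore],
    region_a: AnnotatedRegion,
    region_b: AnnotatedRegion,
) -> OrthologTable:
    """Reciprocal-best-hit ortholog assignment.

    Reciprocal best hits become orthologs; a gene whose best hit is already
    taken becomes a co-ortholog duplicate; everything else is reported
    unpaired.  Ties on score are broken by coverage, then by smaller
    positional distance between the candidate partners; an unresolved tie
    leaves the gene unpaired.  conserved_order_fraction is the fraction of
    ortholog pairs whose rank order (longest increasing subsequence of
    partner ranks) and strand agree in both regions.
    """
    genes_a = {g.id: g for g in _comparable_genes(region_a)}
    genes_b = {g.id: g for g in _comparable_genes(region_b)}

    def best(candidates: list[GenePairScore], partner_of: str, side: str) -> str | None:
        if not candidates:
            return None

        def key(s: GenePairScore):
            other = s.gene_b if side == "a" else s.gene_a
            me = genes_a[s.gene_a] if side == "a" else genes_b[s.gene_b]
            partner = genes_b[other] if side == "a" else genes_a[other]
            return (s.score, s.coverage, -abs(me.start - partner.start))

        ranked = sorted(candidates, key=key, reverse=True)
        if len(ranked) > 1 and key(ranked[0]) == key(ranked[1]):
            return None  # unresolved tie: reported unpaired
        return ranked[0].gene_b if side == "a" else ranked[0].gene_a

    by_a: dict[str, list[GenePairScore]] = {}
    by_b: dict[str, list[GenePairScore]] = {}
    for s in scores:
        by_a.setdefault(s.gene_a, []).append(s)
        by_b.setdefault(s.gene_b, []).append(s)
    best_a = {ga: best(cands, ga, "a") for ga, cands in by_a.items()}
    best_b = {gb: best(cands, gb, "b") for gb, cands in by_b.items()}

    ident = {(s.gene_a, s.gene_b): s.identity for s in scores}
    pairs: list[OrthologPair] = []
    paired_a: set[str] = set()
    paired_b: set[str] = set()
    for ga in sorted(genes_a, key=lambda g: genes_a[g].start):
        gb = best_a.get(ga)
        if gb is not None and best_b.get(gb) == ga:
            pairs.append(OrthologPair(ga, gb, ident[(ga, gb)], "ortholog"))
            paired_a.add(ga)
            paired_b.add(gb)
    for ga in sorted(genes_a, key=lambda g: genes_a[g].start):
        if ga in paired_a:
            continue
        gb = best_a.get(ga)
        if gb is not None and gb in paired_b:
            pairs.append(OrthologPair(ga, gb, ident[(ga, gb)], "co-ortholog-duplicate"))
            paired_a.add(ga)
    for gb in sorted(genes_b, key=lambda g: genes_b[g].start):
        if gb in paired_b:
            continue
        ga = best_b.get(gb)
        if ga is not None and ga in paired_a:
            pairs.append(OrthologPair(ga, gb, ident[(ga, gb)], "co-ortholog-duplicate"))
            paired_b.add(gb)
    for ga in sorted(genes_a, key=lambda g: genes_a[g].start):
        if ga not in paired_a:
            pairs.append(OrthologPair(ga, None, None, "unpaired-A"))
    for gb in sorted(genes_b, key=lambda g: genes_b[g].start):
        if gb not in paired_b:
            pairs.append(OrthologPair(None, gb, None, "unpaired-B"))

    orth = [p for p in pairs if p.relation == "ortholog"]
    frac = 1.0
    if orth:
        orth.sort(key=lambda p: genes_a[p.gene_a].start)
        b_order = sorted((p.gene_b for p in orth), key=lambda g: genes_b[g].start)
        b_rank = {g: i for i, g in enumerate(b_order)}
        ranks = [b_rank[p.gene_b] for p in orth]
        lis = _longest_increasing(ranks)
        conserved = sum(
            1
            for i, p in enumerate(orth)
            if i in lis and genes_a[p.gene_a].strand == genes_b[p.gene_b].strand
        )
        frac = conserved / len(orth)
    return OrthologTable(pairs=pairs, conserved_order_fraction=frac)


# ----- duplicated gene families --------------------------------------------


def orientation_pattern(strands: list[str]) -> str:
    if len(set(strands)) == 1:
        return "same"
    return "opposite" if len(strands) == 2 else "mixed"


def family_from_members(
    family_id: str, members: list[tuple[str, Span, str]], region_gene_order: list[str] | None = None
) -> GeneFamily:
    """Build a GeneFamily from (gene_id, span, strand) member rows.

    ``region_gene_order`` (all gene ids sorted by position) drives the
    tandem/dispersed call; without it, members more than 50 kb apart are
    called dispersed.
    """
    members = sorted(members, key=lambda m: m[1][0])
    ids = [m[0] for m in members]
    spans = [m[1] for m in members]
    strands = [m[2] for m in members]
    max_sep = max(0, spans[-1][0] - spans[0][1])
    if region_gene_order is not None:
        pos = {g: i for i, g in enumerate(region_gene_order)}
        tandem = all(
            pos[b] - pos[a] - 1 <= TANDEM_MAX_INTERVENING for a, b in zip(ids, ids[1:])
        )
    else:
        tandem = all(s2 - e1 <= 50_000 for (s1, e1), (s2, e2) in zip(spans, spans[1:]))
    return GeneFamily(
        family_id=family_id,
        members=ids,
        arrangement="tandem-cluster" if tandem else "dispersed",
        orientation_pattern=orientation_pattern(strands),
        max_separation=max_sep,
    )


def cluster_families(
    region: AnnotatedRegion,
    self_scores: list[GenePairScore] | None = None,
    min_identity: float = FAMILY_IDENTITY,
    min_coverage: float = FAMILY_COVERAGE,
) -> list[GeneFamily]:
    """Single-linkage clusters of within-region paralogs.

    Edges are self-comparison scores with identity >= 70% and coverage
    >= 0.5; clusters of at least two genes become families, numbered by the
    position of their first member.
    """
    if self_scores is None:
        self_scores = score_gene_pairs(region)
    genes = {g.id: g for g in _comparable_genes(region)}
    parent = {gid: gid for gid in genes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for s in self_scores:
        if s.gene_a in genes and s.gene_b in genes:
            if s.identity >= min_identity and s.coverage >= min_coverage:
                parent[find(s.gene_a)] = find(s.gene_b)
    clusters: dict[str, list[str]] = {}
    for gid in genes:
        clusters.setdefault(find(gid), []).append(gid)
    order = [g.id for g in region.sorted_genes()]
    families = []
    multi = [sorted(m, key=lambda g: genes[g].start) for m in clusters.values() if len(m) >= 2]
    multi.sort(key=lambda m: genes[m[0]].start)
    for i, member_ids in enumerate(multi, 1):
        members = [(gid, genes[gid].span, genes[gid].strand) for gid in member_ids]
        fam = family_from_members(f"fam{i:02d}", members, region_gene_order=order)
        families.append(fam)
    return families


# ----- disruption classification -------------------------------------------


def _inside_pack_mule(gene: GeneFeature, region: AnnotatedRegion) -> bool:
    if gene.enclosed_in_te is not None:
        return True
    return any(
        t.te_class == "pack-MULE" and t.start <= gene.start and gene.end <= t.end
        for t in region.tes
    )


def classify_disruptions(
    table: OrthologTable,
    region_a: AnnotatedRegion,
    region_b: AnnotatedRegion,
    blocks: list | None = None,
) -> DisruptionReport:
    """Label every collinearity disruption.

    Non-ortholog genes are extra-in-A / extra-in-B (with a te-enclosed
    sub-flag when the gene lies inside an annotated pack-MULE); ortholog
    pairs inside a '-' synteny block are inverted; ortholog pairs breaking
    the dominant order (outside the longest increasing subsequence) are
    rearranged.
    """
    report = DisruptionReport()
    genes_a = {g.id: g for g in region_a.genes}
    genes_b = {g.id: g for g in region_b.genes}
    orth_a = {p.gene_a for p in table.pairs if p.relation == "ortholog"}
    orth_b = {p.gene_b for p in table.pairs if p.relation == "ortholog"}
    for p in table.pairs:
        if p.relation == "unpaired-A":
            g = genes_a[p.gene_a]
            report.extra_in_a.append((g.id, _inside_pack_mule(g, region_a)))
        elif p.relation == "unpaired-B":
            g = genes_b[p.gene_b]
            report.extra_in_b.append((g.id, _inside_pack_mule(g, region_b)))
        elif p.relation == "co-ortholog-duplicate":
            # the duplicate copy is extra on the side lacking its own partner
            if p.gene_a not in orth_a:
                g = genes_a[p.gene_a]
                report.extra_in_a.append((g.id, _inside_pack_mule(g, region_a)))
            elif p.gene_b not in orth_b:
                g = genes_b[p.gene_b]
                report.extra_in_b.append((g.id, _inside_pack_mule(g, region_b)))

    neg_spans: list[Span] = []
    if blocks:
        neg_spans = [b.ref_span for b in blocks if getattr(b, "orientation", "+") == "-"]

    orth = table.orthologs()
    orth.sort(key=lambda p: genes_a[p.gene_a].start)
    if orth:
        b_order = sorted((p.gene_b for p in orth), key=lambda g: genes_b[g].start)
        b_rank = {g: i for i, g in enumerate(b_order)}
        lis = _longest_increasing([b_rank[p.gene_b] for p in orth])
    else:
        lis = set()
    for i, p in enumerate(orth):
        ga = genes_a[p.gene_a]
        gb = genes_b[p.gene_b]
        in_neg = any(s <= ga.start and ga.end <= e for s, e in neg_spans)
        if in_neg or (ga.strand != gb.strand):
            report.inverted.append((p.gene_a, p.gene_b))
        elif i not in lis:
            report.rearranged.append((p.gene_a, p.gene_b))
    return report
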