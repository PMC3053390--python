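"""Forward simulator of two-lineage regional genome divergence.

Produces an ancestral gene-dense region and two descendant lineages that
carry the event classes the comparative analysis is designed to detect:

* per-gene codon substitutions with a target Ka/Ks (omega) realised by a
  propose-accept scheme (nonsynonymous proposals accepted with
  probability omega when omega <= 1, synonymous proposals thinned by
  1/omega when omega > 1; proposals creating stop codons always rejected);
* lineage-specific TE insertions over a mixed length distribution (MITEs,
  DNA transposons, LTR retroelements, helitrons), occasionally nested
  inside resident elements;
* pack-MULE elements that capture a frameshifted fragment of a host gene
  (emitted as a TE-enclosed pseudogene);
* tandem and dispersed gene duplications in either orientation;
* one paracentric inversion created by ectopic recombination between an
  inverted duplicated gene pair, the duplication being ancestral so both
  lineages share the flanking family while only one carries the inversion.

Every event is logged in a TruthSet keyed by feature id; spans reported in
the truth tables are resolved against the *final* descendant coordinate
systems, so breakpoints and insertion spans are exact.  A single master
seed drives named substreams (shared ancestral events, lineage A,
lineage B, BES libraries), making all outputs byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .divergence import CODON_TO_AA
from .region import AnnotatedRegion, GeneFeature, Span, TEFeature, revcomp

_BASES = np.array(list("ACGT"))
_NONSTOP_CODONS = sorted(c for c, aa in CODON_TO_AA.items() if aa != "*" and c != "ATG")
_STOP_CODONS = ("TAA", "TAG", "TGA")

# TE class sampling: (class, probability, min_len, max_len)
TE_LENGTH_DIST = (
    ("MITE", 0.40, 100, 500),
    ("DNA-transposon", 0.30, 1000, 5000),
    ("LTR-retrotransposon", 0.20, 5000, 15000),
    ("helitron", 0.10, 5000, 20000),
)


@dataclass
class DuplicationEvent:
    source_gene: str
    mode: str  # 'tandem' or 'dispersed'
    orientation: str  # 'same' or 'opposite'
    lineage: str = "A"


@dataclass
class InversionSpec:
    internal_span: int = 45000
    source_gene: str | None = None  # flank family seed gene; auto-chosen if None
    family_id: str = "famINV"


@dataclass
class EvolutionParams:
    """Parameters of the two-lineage divergence simulation.

    Defaults emulate a gene-dense rice region: one gene per ~6 kb, pairwise
    synonymous divergence around 0.035, a mostly purifying omega spectrum,
    a ~10% lineage-specific TE load and a 45 kb ectopic inversion.
    """

    seed: int = 0
    region_length: int = 600_000
    gene_count: int = 100
    mean_cds_length: int = 900
    exons_per_gene: tuple[int, int] = (1, 5)
    branch_sub_rate: float = 0.0175
    omega_per_gene: list[float] | None = None
    # one count for both branches, or (lineage A, lineage B) for asymmetric loads
    te_insertions_per_branch: int | tuple[int, int] = 12
    te_nesting_prob: float = 0.1
    te_deletions_per_branch: int = 0
    pack_mule_captures_per_branch: int = 3
    duplication_events: list[DuplicationEvent] = field(default_factory=list)
    inversion_spec: InversionSpec | None = None
    bac_length: tuple[float, float] = (130_000.0, 10_000.0)
    bes_read_length: int = 500
    gc_content: float = 0.44

    def __post_init__(self):
        if self.gene_count and self.region_length < self.gene_count * (self.mean_cds_length + 1000):
            raise ValueError(
                f"region_length {self.region_length} cannot pack {self.gene_count} genes "
                f"of mean CDS {self.mean_cds_length} bp plus intergenic space"
            )
        if not (0.0 <= self.branch_sub_rate < 0.2):
            raise ValueError("branch_sub_rate must lie in [0, 0.2)")
        if self.omega_per_gene is not None:
            if len(self.omega_per_gene) != self.gene_count:
                raise ValueError(
                    f"omega_per_gene has {len(self.omega_per_gene)} values for "
                    f"{self.gene_count} genes"
                )
            if any(w < 0 for w in self.omega_per_gene):
                raise ValueError("all omega values must be >= 0")

    def resolved_omegas(self) -> list[float]:
        """Per-gene omega targets; the default mix is mostly purifying."""
        if self.omega_per_gene is not None:
            return list(self.omega_per_gene)
        rng = np.random.default_rng(np.random.SeedSequence((self.seed, 777)))
        draws = rng.choice([0.12, 0.7, 1.3], size=self.gene_count, p=[0.85, 0.09, 0.06])
        return [float(w) for w in draws]


@dataclass
class SubstitutionSummary:
    gene_id: str
    lineage: str
    omega_target: float
    syn: int
    nonsyn: int


@dataclass
class TEInsertionRecord:
    lineage: str
    te_id: str
    te_class: str
    length: int
    nested_in: str | None
    span: Span | None = None  # resolved in final coordinates


@dataclass
class DuplicationRecord:
    lineage: str  # 'A', 'B' or 'ancestral'
    source_gene: str
    new_gene: str
    mode: str
    orientation: str
    span: Span | None = None


@dataclass
class PackMuleRecord:
    lineage: str
    te_id: str
    captured_gene: str
    pseudogene_id: str
    frameshifts: int
    span: Span | None = None


@dataclass
class InversionRecord:
    lineage: str
    flank_a: str
    flank_b: str
    family_id: str
    breakpoints: Span  # exact (left, right) recombination points, lineage coords
    ancestral_breakpoints: Span  # same points in the pre-inversion arrangement


@dataclass
class TruthSet:
    seed: int
    ortholog_map: dict[str, dict[str, str]] = field(default_factory=dict)
    substitutions: list[SubstitutionSummary] = field(default_factory=list)
    te_insertions: list[TEInsertionRecord] = field(default_factory=list)
    duplications: list[DuplicationRecord] = field(default_factory=list)
    pack_mules: list[PackMuleRecord] = field(default_factory=list)
    inversion: InversionRecord | None = None
    substream_seeds: dict[str, int] = field(default_factory=dict)

    def inserted_bp(self, lineage: str) -> int:
        total = sum(r.length for r in self.te_insertions if r.lineage == lineage)
        for r in self.duplications:
            if r.lineage == lineage and r.span:
                total += r.span[1] - r.span[0] + 1
        for r in self.pack_mules:
            if r.lineage == lineage and r.span:
                total += r.span[1] - r.span[0] + 1
        return total


# ----- ancestor construction ----------------------------------------------


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p)) if n else ""


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + non-stop codons + stop; no internal stops by construction."""
    body = rng.choice(_NONSTOP_CODONS, size=max(n_codons - 2, 0))
    stop = _STOP_CODONS[rng.integers(0, 3)]
    return "ATG" + "".join(body) + stop


def _build_gene(
    rng: np.random.Generator, gid: str, params: EvolutionParams
) -> tuple[str, str, list[Span]]:
    """Return (genomic_segment, strand, exon spans relative to segment start=1)."""
    lo, hi = params.exons_per_gene
    n_ex = int(rng.integers(lo, hi + 1))
    n_codons = max(50, int(round(rng.normal(params.mean_cds_length, params.mean_cds_length / 5) / 3)))
    cds = _random_cds(rng, n_codons)
    # split CDS into n_ex pieces, each at least 30 bp
    n_ex = min(n_ex, len(cds) // 30)
    cuts = sorted(rng.choice(np.arange(30, len(cds) - 29), size=n_ex - 1, replace=False)) if n_ex > 1 else []
    pieces, prev = [], 0
    for c in list(cuts) + [len(cds)]:
        pieces.append(cds[prev:c])
        prev = c
    introns = [_random_seq(rng, int(rng.integers(80, 400)), params.gc_content) for _ in range(n_ex - 1)]
    segment = pieces[0]
    exons: list[Span] = [(1, len(pieces[0]))]
    for intron, piece in zip(introns, pieces[1:]):
        start = len(segment) + len(intron) + 1
        segment += intron + piece
        exons.append((start, start + len(piece) - 1))
    strand = "+" if rng.random() < 0.5 else "-"
    if strand == "-":
        L = len(segment)
        segment = revcomp(segment)
        exons = sorted((L - e + 1, L - s + 1) for s, e in exons)
    return segment, strand, exons


def build_ancestor(params: EvolutionParams) -> AnnotatedRegion:
    """Ancestral gene-dense region: non-overlapping genes over random intergenic DNA."""
    rng = np.random.default_rng(np.random.SeedSequence((params.seed, 1)))
    if params.gene_count == 0:
        return AnnotatedRegion(
            id="ancestor", sequence=_random_seq(rng, params.region_length, params.gc_content)
        )
    built = [_build_gene(rng, f"g{i:03d}", params) for i in range(params.gene_count)]
    total_gene_bp = sum(len(seg) for seg, _, _ in built)
    spare = params.region_length - total_gene_bp
    min_gap = 200
    if spare < min_gap * (params.gene_count + 1):
        raise ValueError(
            f"infeasible packing: {params.gene_count} genes need {total_gene_bp} bp "
            f"plus gaps but region is {params.region_length} bp"
        )
    # near-even intergenic gaps with +-30% jitter, exact total preserved
    raw = rng.uniform(0.7, 1.3, size=params.gene_count + 1)
    gaps = np.floor(raw / raw.sum() * spare).astype(int)
    gaps[-1] += spare - int(gaps.sum())
    chunks: list[str] = []
    genes: list[GeneFeature] = []
    pos = 0
    for i, (seg, strand, exons) in enumerate(built):
        gap = int(gaps[i])
        chunks.append(_random_seq(rng, gap, params.gc_content))
        pos += gap
        genes.append(
            GeneFeature(
                id=f"g{i:03d}",
                span=(pos + 1, pos + len(seg)),
                strand=strand,
                exons=[(pos + s, pos + e) for s, e in exons],
            )
        )
        chunks.append(seg)
        pos += len(seg)
    chunks.append(_random_seq(rng, int(gaps[-1]), params.gc_content))
    region = AnnotatedRegion(id="ancestor", sequence="".join(chunks), genes=genes)
    region.validate()
    return region


# ----- ectopic inversion ---------------------------------------------------


def _inversion_points(a: GeneFeature, b: GeneFeature) -> Span:
    d = min(a.end - a.start + 1, b.end - b.start + 1) // 2
    return a.start + d, b.end - d


def apply_ectopic_inversion(
    region: AnnotatedRegion, flank_a: str, flank_b: str
) -> AnnotatedRegion:
    """Invert the segment between two inverted duplicated genes in place.

    Models ectopic (non-allelic) homologous recombination: the crossover
    falls at the homologous midpoint of the two gene bodies, so each flank
    gene stays intact but acquires the other's upstream sequence, the
    internal segment is reverse-complemented, and total length is
    conserved.  Applying the operation twice restores the input.
    """
    a = region.gene(flank_a)
    b = region.gene(flank_b)
    if a.start > b.start:
        a, b = b, a
    if a.strand == b.strand:
        raise ValueError(f"flank genes {a.id}/{b.id} are on the same strand")
    if a.end >= b.start:
        raise ValueError(f"flank genes {a.id}/{b.id} overlap")
    p1, p2 = _inversion_points(a, b)
    out = region.copy()
    # invert the open interval (p1, p2): 1-based [p1+1, p2-1]
    seq = out.sequence
    out.sequence = seq[:p1] + revcomp(seq[p1 : p2 - 1]) + seq[p2 - 1 :]
    assert len(out.sequence) == len(seq)

    def remap(span: Span) -> Span:
        s, e = span
        return (p1 + p2 - e, p1 + p2 - s)

    flanks = {a.id, b.id}
    for g in out.genes:
        inside = p1 < g.start and g.end < p2
        if g.id in flanks:
            continue  # intact by construction of the crossover point
        if inside:
            g.span = remap(g.span)
            g.exons = sorted(remap(e) for e in g.exons)
            g.strand = "+" if g.strand == "-" else "-"
        elif g.end > p1 and g.start < p2:
            raise ValueError(f"feature {g.id} straddles an inversion breakpoint")
    for t in out.tes:
        if p1 < t.start and t.end < p2:
            t.span = remap(t.span)
            t.strand = "+" if t.strand == "-" else "-"
        elif t.end > p1 and t.start < p2:
            raise ValueError(f"feature {t.id} straddles an inversion breakpoint")
    return out


# ----- lineage evolution ---------------------------------------------------


def _cds_position_map(gene: GeneFeature) -> list[int]:
    """Genomic (1-based) position of each CDS base in reading order."""
    positions: list[int] = []
    for s, e in sorted(gene.exons):
        positions.extend(range(s, e + 1))
    if gene.strand == "-":
        positions.reverse()
    return positions


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _mutate_gene(
    seq: bytearray,
    gene: GeneFeature,
    omega: float,
    rate: float,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Apply propose-accept codon substitutions; returns (syn, nonsyn) accepted."""
    posmap = _cds_position_map(gene)
    n = len(posmap) - len(posmap) % 3
    if n == 0 or rate <= 0:
        return 0, 0
    cds = list(
        "".join(
            chr(seq[p - 1]) if gene.strand == "+" else _COMP[chr(seq[p - 1])]
            for p in posmap[:n]
        )
    )
    n_prop = rng.poisson(rate * n)
    p_syn, p_nonsyn = (1.0, omega) if omega <= 1.0 else (1.0 / omega, 1.0)
    syn = nonsyn = 0
    for _ in range(n_prop):
        i = int(rng.integers(0, n))
        ci = i - i % 3
        codon = "".join(cds[ci : ci + 3])
        if CODON_TO_AA.get(codon, "*") == "*":
            continue  # never mutate away from within a broken codon
        alts = [b for b in "ACGT" if b != cds[i]]
        b = alts[int(rng.integers(0, 3))]
        mutant = codon[: i - ci] + b + codon[i - ci + 1 :]
        if CODON_TO_AA[mutant] == "*":
            continue  # stops always rejected
        synonymous = CODON_TO_AA[mutant] == CODON_TO_AA[codon]
        accept_p = p_syn if synonymous else p_nonsyn
        if rng.random() >= accept_p:
            continue
        cds[i] = b
        gpos = posmap[i]
        seq[gpos - 1] = ord(b if gene.strand == "+" else _COMP[b])
        if synonymous:
            syn += 1
        else:
            nonsyn += 1
    return syn, nonsyn


def _insertion_position(
    region: AnnotatedRegion,
    rng: np.random.Generator,
    avoid_gene_bodies: bool = False,
    avoid_ids: frozenset[str] = frozenset(),
) -> int:
    """Uniform random 1-based insertion point that never splits a CDS exon.

    An insertion at ``pos`` lands between pos-1 and pos, so a span (s, e) is
    split iff s < pos <= e.  ``avoid_gene_bodies`` additionally excludes
    whole gene spans (used for gene duplications, which must not nest inside
    another gene); ``avoid_ids`` excludes named genes entirely (the
    inversion flank genes, whose homologous structure must stay intact).
    """
    forbidden: list[Span] = []
    for g in region.genes:
        if avoid_gene_bodies or g.id in avoid_ids:
            forbidden.append(g.span)
        else:
            forbidden.extend(g.exons)
    for _ in range(2000):
        pos = int(rng.integers(1, region.length + 2))
        if not any(s < pos <= e for s, e in forbidden):
            return pos
    raise RuntimeError("could not find a valid insertion point")


def _copy_gene_segment(region: AnnotatedRegion, gene: GeneFeature) -> tuple[str, list[Span], str]:
    """(segment sequence, exon spans relative to segment start=1, strand)."""
    seg = region.sequence[gene.start - 1 : gene.end]
    rel = [(s - gene.start + 1, e - gene.start + 1) for s, e in gene.exons]
    return seg, rel, gene.strand


def _insert_gene_copy(
    region: AnnotatedRegion,
    source: GeneFeature,
    new_id: str,
    pos: int,
    flip: bool,
) -> GeneFeature:
    seg, rel, strand = _copy_gene_segment(region, source)
    if flip:
        L = len(seg)
        seg = revcomp(seg)
        rel = sorted((L - e + 1, L - s + 1) for s, e in rel)
        strand = "+" if strand == "-" else "-"
    region.insert(pos, seg)
    # after insertion, positions at/after pos shifted; new gene occupies [pos, pos+L-1]
    g = GeneFeature(
        id=new_id,
        span=(pos, pos + len(seg) - 1),
        strand=strand,
        exons=[(pos + s - 1, pos + e - 1) for s, e in rel],
        kind=source.kind,
        product=source.product,
    )
    region.genes.append(g)
    return g


def _sample_te(rng: np.random.Generator, gc: float) -> tuple[str, str]:
    r = rng.random()
    acc = 0.0
    for cls, p, lo, hi in TE_LENGTH_DIST:
        acc += p
        if r < acc:
            return cls, _random_seq(rng, int(rng.integers(lo, hi + 1)), gc)
    cls, _, lo, hi = TE_LENGTH_DIST[-1]
    return cls, _random_seq(rng, int(rng.integers(lo, hi + 1)), gc)


def _frameshifted_fragment(rng: np.random.Generator, cds: str) -> tuple[str, int]:
    lo = min(200, max(30, len(cds) // 4))
    hi = min(800, len(cds))
    if hi <= lo:
        frag = cds
    else:
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, len(cds) - length + 1))
        frag = cds[start : start + length]
    n_fs = int(rng.integers(1, 3))  # 1 or 2 frameshifts
    for _ in range(n_fs):
        i = int(rng.integers(1, len(frag)))
        if rng.random() < 0.5:
            frag = frag[:i] + frag[i + 1 :]  # 1-bp deletion
        else:
            frag = frag[:i] + "ACGT"[int(rng.integers(0, 4))] + frag[i:]
    return frag, n_fs


def _ensure_broken_frame(frag: str) -> str:
    """Guarantee the captured fragment cannot read as an intact frame."""
    return frag if len(frag) % 3 else frag + "A"


def _evolve_one_lineage(
    ancestor: AnnotatedRegion,
    lineage: str,
    params: EvolutionParams,
    omegas: dict[str, float],
    rng: np.random.Generator,
    truth: TruthSet,
    protected: frozenset[str] = frozenset(),
) -> AnnotatedRegion:
    region = ancestor.copy()
    region.id = f"lineage{lineage}"
    # 1. codon substitutions
    seq = bytearray(region.sequence.encode())
    for gene in region.sorted_genes():
        if gene.is_pseudogene:
            continue
        syn, nonsyn = _mutate_gene(seq, gene, omegas.get(gene.id, 0.2), params.branch_sub_rate, rng)
        if syn or nonsyn:
            truth.substitutions.append(
                SubstitutionSummary(gene.id, lineage, omegas.get(gene.id, 0.2), syn, nonsyn)
            )
    region.sequence = seq.decode()
    # 2. duplications for this lineage
    dup_counter = 0
    for ev in params.duplication_events:
        if ev.lineage != lineage:
            continue
        src = region.gene(ev.source_gene)
        dup_counter += 1
        new_id = f"{ev.source_gene}_dup{lineage}{dup_counter}"
        if ev.mode == "tandem":
            pos = min(src.end + int(rng.integers(100, 400)), region.length + 1)
            # nudge out of any gene body so the copy never nests in a gene
            while any(
                s < pos <= e for g in region.genes for s, e in [g.span]
            ) and pos <= region.length:
                pos += 97
            pos = min(pos, region.length + 1)
        else:
            pos = _insertion_position(region, rng, avoid_gene_bodies=True)
        flip = ev.orientation == "opposite"
        _insert_gene_copy(region, src, new_id, pos, flip)
        truth.duplications.append(
            DuplicationRecord(lineage, ev.source_gene, new_id, ev.mode, ev.orientation)
        )
    # 3. TE insertions
    n_te = params.te_insertions_per_branch
    if isinstance(n_te, (tuple, list)):
        n_te = n_te[0] if lineage == "A" else n_te[1]
    for i in range(n_te):
        cls, te_seq = _sample_te(rng, 0.5)
        te_id = f"te{lineage}{i:03d}"
        nested_host = None
        if region.tes and rng.random() < params.te_nesting_prob:
            host = region.tes[int(rng.integers(0, len(region.tes)))]
            pos = int(rng.integers(host.start + 1, host.end + 1))
            nested_host = host.id
        else:
            pos = _insertion_position(region, rng, avoid_ids=protected)
        region.insert(pos, te_seq)
        region.tes.append(
            TEFeature(
                id=te_id,
                span=(pos, pos + len(te_seq) - 1),
                strand="+" if rng.random() < 0.5 else "-",
                te_class=cls,
                nested_in=nested_host,
            )
        )
        truth.te_insertions.append(
            TEInsertionRecord(lineage, te_id, cls, len(te_seq), nested_host)
        )
    # 4. pack-MULE captures
    coding = [g for g in region.sorted_genes() if not g.is_pseudogene]
    for i in range(params.pack_mule_captures_per_branch):
        if not coding:
            break
        src = coding[int(rng.integers(0, len(coding)))]
        frag, n_fs = _frameshifted_fragment(rng, src.cds(region.sequence))
        frag = _ensure_broken_frame(frag)
        left = _random_seq(rng, int(rng.integers(400, 1200)), 0.5)
        right = _random_seq(rng, int(rng.integers(400, 1200)), 0.5)
        element = left + frag + right
        pos = _insertion_position(region, rng, avoid_gene_bodies=True)
        te_id = f"mule{lineage}{i:02d}"
        psi_id = f"{src.id}_psi{lineage}{i:02d}"
        region.insert(pos, element)
        region.tes.append(
            TEFeature(
                id=te_id,
                span=(pos, pos + len(element) - 1),
                strand="+",
                te_class="pack-MULE",
                captured_gene=src.id,
            )
        )
        frag_start = pos + len(left)
        region.genes.append(
            GeneFeature(
                id=psi_id,
                span=(frag_start, frag_start + len(frag) - 1),
                strand="+",
                exons=[(frag_start, frag_start + len(frag) - 1)],
                kind="pseudogene",
                enclosed_in_te=te_id,
            )
        )
        truth.pack_mules.append(PackMuleRecord(lineage, te_id, src.id, psi_id, n_fs))
    return region


def evolve_lineages(
    ancestor: AnnotatedRegion, params: EvolutionParams
) -> tuple[AnnotatedRegion, AnnotatedRegion, TruthSet]:
    """Evolve the ancestor down two independent lineages A and B.

    Raises ValueError when omega_per_gene does not match the ancestor's
    gene count.  The inversion (when configured) is seeded by an ancestral
    inverted duplication shared by both lineages and applied to lineage A
    only, mirroring an inversion fixed in one species.
    """
    n_coding = sum(1 for g in ancestor.genes if not g.is_pseudogene)
    if params.omega_per_gene is not None and len(params.omega_per_gene) != n_coding:
        raise ValueError(
            f"omega list length {len(params.omega_per_gene)} != gene count {n_coding}"
        )
    ss = np.random.SeedSequence((params.seed, 2))
    shared_seed, seed_a, seed_b = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3)]
    truth = TruthSet(
        seed=params.seed,
        substream_seeds={"shared": shared_seed, "A": seed_a, "B": seed_b},
    )
    coding_sorted = [g for g in ancestor.sorted_genes() if not g.is_pseudogene]
    omega_list = (
        list(params.omega_per_gene) if params.omega_per_gene is not None else params.resolved_omegas()[:n_coding]
    )
    omegas = {g.id: w for g, w in zip(coding_sorted, omega_list)}

    base = ancestor.copy()
    flank_ids: tuple[str, str] | None = None
    if params.inversion_spec is not None:
        spec = params.inversion_spec
        rng_shared = np.random.default_rng(shared_seed)
        src_id = spec.source_gene
        if src_id is None:
            # pick a gene with >= internal_span of room downstream
            candidates = [
                g
                for g in base.sorted_genes()
                if g.end + spec.internal_span + (g.end - g.start + 1) + 2000 < base.length
                and not g.is_pseudogene
            ]
            src_id = candidates[len(candidates) // 3].id
        src = base.gene(src_id)
        pos = src.end + spec.internal_span
        # nudge fully out of any gene body: the flank copy must not nest
        while any(g.start < pos <= g.end for g in base.genes):
            pos += 137
        if pos > base.length + 1:
            raise ValueError("inversion_spec internal_span leaves no room for the flank copy")
        dup_id = f"{src_id}_invdup"
        _insert_gene_copy(base, src, dup_id, pos, flip=True)
        omegas[dup_id] = omegas.get(src_id, 0.2)
        truth.duplications.append(
            DuplicationRecord("ancestral", src_id, dup_id, "dispersed", "opposite")
        )
        flank_ids = (src_id, dup_id)
        del rng_shared

    protected = frozenset(flank_ids) if flank_ids else frozenset()
    lin_a = _evolve_one_lineage(
        base, "A", params, omegas, np.random.default_rng(seed_a), truth, protected
    )
    lin_b = _evolve_one_lineage(
        base, "B", params, omegas, np.random.default_rng(seed_b), truth, protected
    )

    if flank_ids is not None:
        fa, fb = flank_ids
        ga, gb = lin_a.gene(fa), lin_a.gene(fb)
        pre_points = _inversion_points(*((ga, gb) if ga.start < gb.start else (gb, ga)))
        lin_a = apply_ectopic_inversion(lin_a, fa, fb)
        truth.inversion = InversionRecord(
            lineage="A",
            flank_a=fa,
            flank_b=fb,
            family_id=params.inversion_spec.family_id,
            breakpoints=pre_points,  # length-conserving: same coords after inversion
            ancestral_breakpoints=pre_points,
        )

    # ortholog map: ancestor/base gene ids persist into both lineages
    for lab, lin in (("A", lin_a), ("B", lin_b)):
        ids = {g.id for g in lin.genes}
        truth.ortholog_map[lab] = {g.id: g.id for g in base.genes if g.id in ids}
    _resolve_truth_spans(truth, lin_a, lin_b)
    lin_a.validate()
    lin_b.validate()
    return lin_a, lin_b, truth


def _resolve_truth_spans(truth: TruthSet, lin_a: AnnotatedRegion, lin_b: AnnotatedRegion) -> None:
    regions = {"A": lin_a, "B": lin_b}
    for rec in truth.te_insertions:
        te = next(t for t in regions[rec.lineage].tes if t.id == rec.te_id)
        rec.span = te.span
    for rec in truth.pack_mules:
        te = next(t for t in regions[rec.lineage].tes if t.id == rec.te_id)
        rec.span = te.span
    for rec in truth.duplications:
        if rec.lineage in regions:
            rec.span = regions[rec.lineage].gene(rec.new_gene).span
        else:  # ancestral duplication: resolve in lineage B (non-inverted)
            rec.span = regions["B"].gene(rec.new_gene).span


# ----- BES library ---------------------------------------------------------


def simulate_bes_library(
    genome: AnnotatedRegion,
    n_bacs: int,
    params: EvolutionParams,
    seed: int,
    species: str | None = None,
):
    """Uniformly placed BAC fragments with paired end reads.

    Read 1 is the first ``bes_read_length`` bp of the fragment on the
    forward strand; read 2 is the reverse complement of the last
    ``bes_read_length`` bp, matching how paired end reads of a clone insert
    face each other.
    """
    from .bes import BesPair  # local import to avoid a cycle

    if n_bacs <= 0:
        raise ValueError("n_bacs must be positive")
    mean, sd = params.bac_length
    if mean >= genome.length:
        raise ValueError("bac_length exceeds region length")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 3)))
    pairs: list = []
    label = species or genome.id
    for i in range(n_bacs):
        L = int(np.clip(rng.normal(mean, sd), params.bes_read_length * 2, genome.length))
        start = int(rng.integers(1, genome.length - L + 2))
        frag = genome.sequence[start - 1 : start + L - 1]
        r = params.bes_read_length
        pairs.append(
            BesPair(
                bac_id=f"{label}_bac{i:04d}",
                species=label,
                read1=frag[:r],
                read2=revcomp(frag[-r:]),
                truth_interval=(start, start + L - 1),
            )
        )
    return pairs
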