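"""Annotated genomic regions: containers, validation and FASTA+GFF3 I/O.

A region is one contiguous DNA sequence together with its gene and
transposable-element (TE) annotations.  Coordinates are 1-based and
inclusive throughout (GFF3 convention); ``span = (start, end)`` with
``start <= end`` regardless of strand.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

Span = tuple[int, int]

TE_CLASSES = (
    "LTR-retrotransposon",
    "non-LTR",
    "DNA-transposon",
    "MITE",
    "helitron",
    "pack-MULE",
)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


class RegionValidationError(ValueError):
    """Raised when a region bundle violates its structural invariants.

    Carries the list of per-feature violation messages in ``offenders``.
    """

    def __init__(self, offenders: list[str]):
        self.offenders = list(offenders)
        super().__init__("invalid region: " + "; ".join(self.offenders))


@dataclass
class GeneFeature:
    id: str
    span: Span
    strand: str  # '+' or '-'
    exons: list[Span] = field(default_factory=list)
    kind: str = "gene"  # 'gene' or 'pseudogene'
    product: str = ""
    enclosed_in_te: str | None = None

    def __post_init__(self):
        if not self.exons:
            self.exons = [self.span]

    @property
    def start(self) -> int:
        return self.span[0]

    @property
    def end(self) -> int:
        return self.span[1]

    @property
    def is_pseudogene(self) -> bool:
        return self.kind == "pseudogene"

    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def cds(self, sequence: str) -> str:
        """Spliced CDS in reading orientation (reverse-complemented on '-')."""
        parts = [sequence[s - 1 : e] for s, e in self.exons]
        cds = "".join(parts)
        return revcomp(cds) if self.strand == "-" else cds


@dataclass
class TEFeature:
    id: str
    span: Span
    strand: str
    te_class: str
    nested_in: str | None = None
    captured_gene: str | None = None

    @property
    def start(self) -> int:
        return self.span[0]

    @property
    def end(self) -> int:
        return self.span[1]

    def length(self) -> int:
        return self.span[1] - self.span[0] + 1


@dataclass
class AnnotatedRegion:
    id: str
    sequence: str
    genes: list[GeneFeature] = field(default_factory=list)
    tes: list[TEFeature] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def gene(self, gene_id: str) -> GeneFeature:
        for g in self.genes:
            if g.id == gene_id:
                return g
        raise KeyError(gene_id)

    def sorted_genes(self) -> list[GeneFeature]:
        return sorted(self.genes, key=lambda g: (g.start, g.end, g.id))

    def copy(self) -> "AnnotatedRegion":
        return AnnotatedRegion(
            id=self.id,
            sequence=self.sequence,
            genes=[replace(g, span=tuple(g.span), exons=[tuple(e) for e in g.exons]) for g in self.genes],
            tes=[replace(t, span=tuple(t.span)) for t in self.tes],
        )

    # ----- validation ---------------------------------------------------

    def validate(self) -> None:
        """Check all structural invariants; raise RegionValidationError listing offenders."""
        bad: list[str] = []
        n = self.length
        if set(self.sequence.upper()) - set("ACGTN"):
            bad.append(f"{self.id}: sequence contains non-ACGTN characters")
        te_by_id = {t.id: t for t in self.tes}
        for g in self.genes:
            if not (1 <= g.start <= g.end <= n):
                bad.append(f"{g.id}: span {g.span} outside [1, {n}]")
                continue
            if g.strand not in "+-":
                bad.append(f"{g.id}: bad strand {g.strand!r}")
            ex = sorted(g.exons)
            for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
                if s2 <= e1:
                    bad.append(f"{g.id}: overlapping exons {(s1, e1)} and {(s2, e2)}")
            if any(not (g.start <= s <= e <= g.end) for s, e in g.exons):
                bad.append(f"{g.id}: exon outside gene span")
            elif not g.is_pseudogene and g.cds_length() % 3 != 0:
                bad.append(f"{g.id}: CDS length {g.cds_length()} not divisible by 3")
        for t in self.tes:
            if not (1 <= t.start <= t.end <= n):
                bad.append(f"{t.id}: span {t.span} outside [1, {n}]")
            if t.nested_in is not None:
                host = te_by_id.get(t.nested_in)
                if host is None:
                    bad.append(f"{t.id}: nested_in {t.nested_in} does not exist")
                elif not (host.start <= t.start and t.end <= host.end):
                    bad.append(f"{t.id}: not contained in host {t.nested_in}")
        if bad:
            raise RegionValidationError(bad)

    def insert(self, pos: int, seq: str) -> None:
        """Insert ``seq`` so that it occupies [pos, pos+len-1]; shift all features at/after pos.

        Features strictly containing the insertion point are stretched
        (insertion lands inside them); callers avoid CDS positions.
        """
        ins = len(seq)
        if not (1 <= pos <= self.length + 1):
            raise ValueError(f"insertion position {pos} outside [1, {self.length + 1}]")
        self.sequence = self.sequence[: pos - 1] + seq + self.sequence[pos - 1 :]

        def shift_span(span: Span) -> Span:
            s, e = span
            if e < pos:
                return (s, e)
            if s >= pos:
                return (s + ins, e + ins)
            return (s, e + ins)  # straddles the insertion point

        for g in self.genes:
            g.span = shift_span(g.span)
            g.exons = [shift_span(e) for e in g.exons]
        for t in self.tes:
            t.span = shift_span(t.span)


# ----- FASTA + GFF3 bundle I/O ------------------------------------------


def write_region_bundle(region: AnnotatedRegion, out_dir: str | os.PathLike) -> tuple[str, str]:
    """Write region as ``<id>.fasta`` + ``<id>.gff3``; deterministic field order.

    Returns (fasta_path, gff3_path).
    """
    os.makedirs(out_dir, exist_ok=True)
    fasta_path = os.path.join(out_dir, f"{region.id}.fasta")
    gff3_path = os.path.join(out_dir, f"{region.id}.gff3")
    rec = SeqRecord(Seq(region.sequence), id=region.id, description="")
    with open(fasta_path, "w") as fh:
        SeqIO.write([rec], fh, "fasta")
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {region.id} 1 {region.length}\n")
        rows = []
        for g in sorted(region.genes, key=lambda g: (g.start, g.end, g.id)):
            attrs = [f"ID={g.id}"]
            if g.product:
                attrs.append(f"product={g.product}")
            if g.enclosed_in_te:
                attrs.append(f"enclosed_in_te={g.enclosed_in_te}")
            rows.append((g.start, 0, region.id, "oryzasyn", g.kind, g.start, g.end, ".", g.strand, ".", ";".join(attrs)))
            for i, (s, e) in enumerate(sorted(g.exons), 1):
                rows.append((g.start, i, region.id, "oryzasyn", "CDS", s, e, ".", g.strand, "0", f"ID={g.id}.cds{i};Parent={g.id}"))
        for t in sorted(region.tes, key=lambda t: (t.start, t.end, t.id)):
            attrs = [f"ID={t.id}", f"class={t.te_class}"]
            if t.nested_in:
                attrs.append(f"nested_in={t.nested_in}")
            if t.captured_gene:
                attrs.append(f"captured_gene={t.captured_gene}")
            rows.append((t.start, 2, region.id, "oryzasyn", "repeat_region", t.start, t.end, ".", t.strand, ".", ";".join(attrs)))
        rows.sort(key=lambda r: (r[0], r[1], r[10]))
        for row in rows:
            fh.write("\t".join(str(x) for x in row[2:]) + "\n")
    return fasta_path, gff3_path


def read_region_bundle(fasta_path: str, gff3_path: str) -> AnnotatedRegion:
    """Read and validate a FASTA+GFF3 bundle into an AnnotatedRegion."""
    records = list(SeqIO.parse(fasta_path, "fasta"))
    if len(records) != 1:
        raise RegionValidationError([f"{fasta_path}: expected exactly 1 FASTA record, found {len(records)}"])
    rec = records[0]
    db = gffutils.create_db(
        gff3_path,
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: dict[str, GeneFeature] = {}
    tes: list[TEFeature] = []
    offenders: list[str] = []
    for feat in db.all_features():
        if feat.seqid != rec.id:
            offenders.append(f"{feat.id}: seqid {feat.seqid!r} does not match FASTA id {rec.id!r}")
            continue
        if feat.featuretype in ("gene", "pseudogene"):
            genes[feat.id] = GeneFeature(
                id=feat.id,
                span=(feat.start, feat.end),
                strand=feat.strand,
                exons=[],
                kind=feat.featuretype,
                product=feat.attributes.get("product", [""])[0],
                enclosed_in_te=feat.attributes.get("enclosed_in_te", [None])[0],
            )
        elif feat.featuretype == "repeat_region":
            tes.append(
                TEFeature(
                    id=feat.id,
                    span=(feat.start, feat.end),
                    strand=feat.strand,
                    te_class=feat.attributes.get("class", ["DNA-transposon"])[0],
                    nested_in=feat.attributes.get("nested_in", [None])[0],
                    captured_gene=feat.attributes.get("captured_gene", [None])[0],
                )
            )
    cds_exons: dict[str, list[Span]] = {}
    for feat in db.features_of_type("CDS"):
        parent = feat.attributes.get("Parent", [None])[0]
        if parent in genes:
            cds_exons.setdefault(parent, []).append((feat.start, feat.end))
        else:
            offenders.append(f"{feat.id}: CDS with unknown Parent {parent!r}")
    if offenders:
        raise RegionValidationError(offenders)
    for gid, exons in cds_exons.items():
        genes[gid].exons = sorted(exons)
    region = AnnotatedRegion(id=rec.id, sequence=str(rec.seq), genes=list(genes.values()), tes=tes)
    region.validate()
    return region
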