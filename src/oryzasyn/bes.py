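"""BAC-end-sequence (BES) mapping and inversion-structure calling.

A BAC clone is represented by its two end reads.  Mapped onto a reference
region, a pair whose two ends fall on either side of an inversion
breakpoint (one end inside the inverted span, one outside, within a
plausible clone span) is informative about the arrangement of the source
genome: ends in opposite orientation mean the source is organised like the
reference; ends in identical orientation mean the source carries the
opposite (inverted) arrangement.  Per-species verdicts are majority votes
over informative clones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib

from .region import AnnotatedRegion, Span, revcomp

MIN_IDENTITY = 90.0
MIN_LENGTH = 100
MAX_SPAN = 300_000  # mapped-span filter for breakpoint-spanning pairs
UNIQUENESS_MARGIN = 0.05  # second hit within 5% of best score -> unmapped


@dataclass
class BesPair:
    bac_id: str
    species: str
    read1: str
    read2: str
    truth_interval: Span | None = None

    def __post_init__(self):
        if not self.read1 or not self.read2:
            raise ValueError(f"{self.bac_id}: both reads must be non-empty")


@dataclass
class BesHit:
    position: int  # 1-based start on the reference forward strand
    strand: str
    identity: float
    length: int


@dataclass
class BesCall:
    bac_id: str
    species: str
    hit1: BesHit | None
    hit2: BesHit | None
    mapped_span: int | None = None
    spanning: bool = False
    orientation_class: str = "unmapped"  # opposite | identical | unmapped
    structure_call: str = "uninformative"  # reference-like | inverted | uninformative
    reason: str = ""


# ----- read placement -------------------------------------------------------


def _align_once(query: str, reference: str) -> tuple[int, list[Span]]:
    res = edlib.align(query, reference, mode="HW", task="locations")
    ed = res["editDistance"]
    locs = [(s, e) for s, e in res["locations"]] if ed >= 0 else []
    # collapse locations that describe the same placement
    dedup: list[Span] = []
    for s, e in sorted(locs):
        if dedup and s - dedup[-1][0] < len(query) // 2:
            continue
        dedup.append((s, e))
    return ed, dedup


def place_read(
    read: str,
    reference: AnnotatedRegion | str,
    min_identity: float = MIN_IDENTITY,
    min_length: int = MIN_LENGTH,
) -> BesHit | None:
    """Best unique local placement of one read on either strand.

    Returns None when the read does not reach the identity/length floor or
    when its best placement is not unique (a second placement scores within
    5% of the best) — repeat-derived ends must not vote on structure.
    """
    ref = reference.sequence if isinstance(reference, AnnotatedRegion) else reference
    read = read.upper()
    if len(read) < min_length:
        return None
    candidates: list[tuple[float, int, str]] = []  # (score, position, strand)
    for strand, query in (("+", read), ("-", revcomp(read))):
        ed, locs = _align_once(query, ref)
        if not locs:
            continue
        score = len(query) - ed
        for s, _e in locs:
            candidates.append((score, s + 1, strand))
        # probe for a distinct second-best placement by masking the best hit
        if len(locs) == 1:
            s, e = locs[0]
            masked = ref[:s] + "N" * (e - s + 1) + ref[e + 1 :]
            ed2, locs2 = _align_once(query, masked)
            if locs2:
                for s2, _ in locs2:
                    candidates.append((len(query) - ed2, s2 + 1, strand))
    if not candidates:
        return None
    candidates.sort(reverse=True)
    best_score, pos, strand = candidates[0]
    identity = 100.0 * best_score / len(read)
    if identity < min_identity:
        return None
    runners = [c for c in candidates[1:] if abs(c[1] - pos) > len(read) // 2 or c[2] != strand]
    if runners and runners[0][0] >= (1.0 - UNIQUENESS_MARGIN) * best_score:
        return None  # ambiguous placement
    return BesHit(position=pos, strand=strand, identity=identity, length=len(read))


def map_bes_pairs(
    pairs: list[BesPair],
    reference: AnnotatedRegion,
    min_identity: float = MIN_IDENTITY,
    min_length: int = MIN_LENGTH,
) -> list[BesCall]:
    """Place both ends of every pair on the reference (hits only).

    Unmapped is a state, never an error; orientation_class is filled from
    the two strands when both ends place uniquely.
    """
    calls = []
    for p in pairs:
        h1 = place_read(p.read1, reference, min_identity, min_length)
        h2 = place_read(p.read2, reference, min_identity, min_length)
        call = BesCall(bac_id=p.bac_id, species=p.species, hit1=h1, hit2=h2)
        if h1 and h2:
            call.mapped_span = abs(h2.position - h1.position)
            call.orientation_class = "opposite" if h1.strand != h2.strand else "identical"
        else:
            call.reason = "unmapped read"
        calls.append(call)
    return calls


# ----- spanning-pair classification ------------------------------------------


def classify_spanning_pair(
    call: BesCall, inversion: Span, max_span: int = MAX_SPAN
) -> BesCall:
    """Complete a call against an inversion span on the reference.

    A pair is breakpoint-spanning when exactly one end lies inside the
    inversion span and the mapped span is below ``max_span``.  Spanning
    pairs with ends in opposite orientation are reference-like; identical
    orientation means the source genome carries the inverted arrangement.
    Everything else is uninformative.
    """
    if call.hit1 is None or call.hit2 is None:
        call.structure_call = "uninformative"
        call.reason = call.reason or "unmapped read"
        return call
    lo, hi = inversion
    inside1 = lo <= call.hit1.position <= hi
    inside2 = lo <= call.hit2.position <= hi
    call.spanning = (inside1 != inside2) and call.mapped_span < max_span
    if not call.spanning:
        call.structure_call = "uninformative"
        if inside1 == inside2:
            call.reason = "both ends on the same side of the inversion"
        else:
            call.reason = f"mapped span {call.mapped_span} >= {max_span}"
        return call
    if call.orientation_class == "opposite":
        call.structure_call = "reference-like"
    else:
        call.structure_call = "inverted"
    call.reason = ""
    return call


@dataclass
class SpeciesVerdict:
    species: str
    verdict: str  # reference-like | inverted | ambiguous | no-data
    n_reference_like: int = 0
    n_inverted: int = 0


def call_species_structure(calls: list[BesCall]) -> dict[str, SpeciesVerdict]:
    """Majority vote over informative calls, per species; ties are ambiguous."""
    by_species: dict[str, list[BesCall]] = {}
    for c in calls:
        by_species.setdefault(c.species, []).append(c)
    out: dict[str, SpeciesVerdict] = {}
    for sp, group in sorted(by_species.items()):
        ref = sum(1 for c in group if c.structure_call == "reference-like")
        inv = sum(1 for c in group if c.structure_call == "inverted")
        if ref == inv == 0:
            verdict = "no-data"
        elif ref == inv:
            verdict = "ambiguous"
        else:
            verdict = "reference-like" if ref > inv else "inverted"
        out[sp] = SpeciesVerdict(sp, verdict, ref, inv)
    return out


# ----- plain-text I/O ---------------------------------------------------------


def write_bes_library(pairs: list[BesPair], fasta_path: str, tsv_path: str) -> None:
    """FASTA of end reads plus a pairing TSV (bac_id, species, read1_id, read2_id)."""
    with open(fasta_path, "w") as fa, open(tsv_path, "w") as tsv:
        tsv.write("bac_id\tspecies\tread1_id\tread2_id\n")
        for p in pairs:
            r1, r2 = f"{p.bac_id}.r1", f"{p.bac_id}.r2"
            fa.write(f">{r1}\n{p.read1}\n>{r2}\n{p.read2}\n")
            tsv.write(f"{p.bac_id}\t{p.species}\t{r1}\t{r2}\n")


def read_bes_library(fasta_path: str, tsv_path: str) -> list[BesPair]:
    from Bio import SeqIO

    reads = {rec.id: str(rec.seq) for rec in SeqIO.parse(fasta_path, "fasta")}
    pairs = []
    with open(tsv_path) as fh:
        header = fh.readline()
        for line in fh:
            bac_id, species, r1, r2 = line.rstrip("\n").split("\t")
            pairs.append(BesPair(bac_id, species, reads[r1], reads[r2]))
    return pairs
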