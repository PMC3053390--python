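"""Minimum-tiling-path assembly of finished BAC sequences.

Finished large-insert clones overlap by long, essentially error-free
stretches, so assembly reduces to ordering the clones by exact
suffix-prefix overlaps and merging.  N bases never match, reflecting
their meaning as unknown sequence.
"""

from __future__ import annotations

from dataclasses import dataclass


class AssemblyError(ValueError):
    """Raised when the overlap graph admits no unique linear layout."""


@dataclass
class LayoutRow:
    bac_id: str
    offset: int  # 0-based offset of this BAC in the contig
    strand: str
    overlap_with_previous: int


def _suffix_prefix_overlap(a: str, b: str, min_overlap: int) -> int:
    """Length of the longest exact suffix of ``a`` equal to a prefix of ``b``.

    Returns 0 if no overlap of at least ``min_overlap``.  Overlaps containing
    'N' on either side are rejected.
    """
    max_ov = min(len(a), len(b))
    # Anchor on the first min_overlap bases of b and check candidate
    # positions right-to-left so the longest overlap wins.
    anchor = b[:min_overlap]
    if "N" in anchor.upper():
        return 0
    start = len(a) - max_ov
    best = 0
    pos = a.find(anchor, start)
    while pos != -1:
        ov = len(a) - pos
        if ov >= min_overlap and a[pos:] == b[:ov] and "N" not in a[pos:].upper():
            best = max(best, ov)
        pos = a.find(anchor, pos + 1)
    return best


def assemble_tiling_path(
    bacs: list[tuple[str, str]], min_overlap: int = 2000
) -> tuple[str, list[LayoutRow]]:
    """Order BACs by exact suffix-prefix overlaps and merge into one contig.

    Parameters
    ----------
    bacs : list of (id, sequence)
    min_overlap : minimum exact overlap length accepted (default 2,000 bp).

    Returns (contig_sequence, layout) where layout rows give each BAC's
    0-based offset in the contig.  The contig length always equals the sum
    of BAC lengths minus the sum of merged overlap lengths.

    Raises AssemblyError when the overlap graph is ambiguous (a BAC with
    two equally long successors) or disconnected (no single linear chain);
    the error message lists the connected components.
    """
    if not bacs:
        raise AssemblyError("no input sequences")
    ids = [b[0] for b in bacs]
    if len(set(ids)) != len(ids):
        raise AssemblyError("duplicate BAC ids")
    seqs = dict(bacs)
    n = len(bacs)
    if n == 1:
        bid, seq = bacs[0]
        return seq, [LayoutRow(bid, 0, "+", 0)]

    # Best successor of each BAC: the longest qualifying overlap; equal-best
    # ties are a hard error (never a silent choice).
    succ: dict[str, tuple[str, int]] = {}
    pred_count: dict[str, int] = {i: 0 for i in ids}
    for a in ids:
        candidates: list[tuple[int, str]] = []
        for b in ids:
            if a == b:
                continue
            ov = _suffix_prefix_overlap(seqs[a], seqs[b], min_overlap)
            if ov:
                candidates.append((ov, b))
        if candidates:
            candidates.sort(reverse=True)
            if len(candidates) > 1 and candidates[0][0] == candidates[1][0]:
                raise AssemblyError(
                    f"ambiguous layout: {a} overlaps {candidates[0][1]} and "
                    f"{candidates[1][1]} equally ({candidates[0][0]} bp)"
                )
            ov, b = candidates[0]
            succ[a] = (b, ov)
            pred_count[b] += 1

    starts = [i for i in ids if pred_count[i] == 0]
    if len(starts) != 1:
        comps = _components(ids, succ)
        raise AssemblyError(
            f"no unique linear layout: {len(starts)} chain starts; components: "
            + "; ".join(",".join(sorted(c)) for c in comps)
        )
    order = [starts[0]]
    seen = {starts[0]}
    while order[-1] in succ:
        nxt, _ = succ[order[-1]]
        if nxt in seen:
            raise AssemblyError(f"cyclic overlap graph at {nxt}")
        order.append(nxt)
        seen.add(nxt)
    if len(order) != n:
        comps = _components(ids, succ)
        raise AssemblyError(
            "disconnected overlap graph; components: "
            + "; ".join(",".join(sorted(c)) for c in comps)
        )

    contig = seqs[order[0]]
    layout = [LayoutRow(order[0], 0, "+", 0)]
    for prev, cur in zip(order, order[1:]):
        _, ov = succ[prev]
        offset = len(contig) - ov
        contig += seqs[cur][ov:]
        layout.append(LayoutRow(cur, offset, "+", ov))
    return contig, layout


def _components(ids: list[str], succ: dict[str, tuple[str, int]]) -> list[set[str]]:
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, (b, _) in succ.items():
        parent[find(a)] = find(b)
    comps: dict[str, set[str]] = {}
    for i in ids:
        comps.setdefault(find(i), set()).add(i)
    return list(comps.values())
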