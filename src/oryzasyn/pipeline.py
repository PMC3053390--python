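"""End-to-end pipeline: simulate, assemble, compare, and report.

Orchestrates the stage modules in dependency order under one seeded
configuration, writes every stage's tables under an output directory, and
renders a consolidated human-readable report.  Also hosts the small
arithmetic helpers used to reproduce the published summary numbers from
printed coordinate tables (gene-family separations, gene density,
orthologous-interval length), which ship with the package as plain TSVs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import importlib.resources
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import assembly, bes, collinearity, divergence, structure
from .region import AnnotatedRegion, write_region_bundle
from .simulate import (
    DuplicationEvent,
    EvolutionParams,
    InversionSpec,
    TruthSet,
    build_ancestor,
    evolve_lineages,
    simulate_bes_library,
)

ALL_STAGES = ("simulate", "assemble", "collinearity", "structure", "divergence", "bes-scan", "report")


# ----- kb formatting ---------------------------------------------------------


def floor_kb(bp: int) -> int:
    """Whole kilobases by floor division (813,654 bp -> 813 kb)."""
    return int(bp) // 1000


def nearest_kb(bp: float) -> int:
    """Nearest whole kilobase (5,685 bp/gene -> 6 kb)."""
    return int(round(bp / 1000.0))


def interval_length(start: int, end: int) -> int:
    """1-based inclusive interval length."""
    return end - start + 1


def gene_density_bp(region_bp: int, n_genes: int) -> float:
    return region_bp / n_genes


# ----- published coordinate tables ------------------------------------------


def _data_path(name: str):
    return importlib.resources.files("oryzasyn.data") / name


def published_family_table() -> pd.DataFrame:
    """Printed gene-family coordinate table for the African-rice contig."""
    return pd.read_csv(_data_path("gene_families_cg14.tsv"), sep="\t")


def published_landmarks() -> dict[str, int]:
    df = pd.read_csv(_data_path("published_landmarks.tsv"), sep="\t")
    return dict(zip(df["name"], df["value"].astype(int)))


def family_separation_bp(table: pd.DataFrame, family: str) -> int:
    """Genomic separation between the two farthest members of a family:
    distance from the end of the first member to the start of the last."""
    rows = table[table["family"] == family].sort_values("start")
    if len(rows) < 2:
        raise ValueError(f"family {family} has fewer than 2 members")
    return int(rows.iloc[-1]["start"] - rows.iloc[0]["end"])


def published_families() -> list[collinearity.GeneFamily]:
    """GeneFamily objects built from the printed coordinate table."""
    table = published_family_table()
    fams = []
    for fam_id, rows in table.groupby("family", sort=False):
        members = [
            (r["gene"], (int(r["start"]), int(r["end"])), r["strand"])
            for _, r in rows.iterrows()
        ]
        fams.append(collinearity.family_from_members(str(fam_id), members))
    return fams


# ----- configuration ---------------------------------------------------------


@dataclass
class PipelineConfig:
    """All pipeline inputs and thresholds; round-trips losslessly via YAML."""

    seed: int = 0
    out_dir: str = "results/pipeline"
    stages: tuple[str, ...] = ALL_STAGES
    # simulation
    params: EvolutionParams = field(default_factory=EvolutionParams)
    n_bacs_tiling: int = 8
    tiling_overlap: int = 20_000
    n_bacs_bes: int = 60
    # structure thresholds
    k: int = structure.K_DEFAULT
    gap: int = structure.GAP_DEFAULT
    min_block: int = structure.MIN_BLOCK_DEFAULT
    # collinearity thresholds
    min_identity: float = collinearity.MIN_IDENTITY
    min_coverage: float = collinearity.MIN_COVERAGE
    family_identity: float = collinearity.FAMILY_IDENTITY
    family_coverage: float = collinearity.FAMILY_COVERAGE
    # divergence
    flag_factor: float = 2.0
    omega_bands: tuple[float, float] = (0.5, 1.0)
    alpha: float = 0.05
    # BES
    bes_min_identity: float = bes.MIN_IDENTITY
    bes_min_length: int = bes.MIN_LENGTH
    bes_max_span: int = bes.MAX_SPAN

    def to_yaml(self, path: str) -> None:
        d = dataclasses.asdict(self)
        d["params"]["duplication_events"] = [
            dataclasses.asdict(e) if not isinstance(e, dict) else e
            for e in d["params"]["duplication_events"]
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(d), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        p = d.pop("params")
        dups = [DuplicationEvent(**e) for e in p.pop("duplication_events", [])]
        inv = p.pop("inversion_spec", None)
        params = EvolutionParams(
            **{**p, "exons_per_gene": tuple(p["exons_per_gene"]), "bac_length": tuple(p["bac_length"])},
        )
        params.duplication_events = dups
        params.inversion_spec = InversionSpec(**inv) if inv else None
        d["stages"] = tuple(d["stages"])
        d["omega_bands"] = tuple(d["omega_bands"])
        return cls(params=params, **d)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def default_study_params(seed: int = 0) -> EvolutionParams:
    """Simulation defaults emulating the studied orthologous rice regions:
    gene-dense 600 kb, a handful of tandem/dispersed duplications, pack-MULE
    captures and a 45 kb ectopic inversion between inverted duplicates."""
    return EvolutionParams(
        seed=seed,
        duplication_events=[
            DuplicationEvent("g020", "tandem", "same", "A"),
            DuplicationEvent("g021", "tandem", "same", "A"),
            DuplicationEvent("g045", "tandem", "opposite", "A"),
            DuplicationEvent("g070", "dispersed", "opposite", "A"),
            DuplicationEvent("g080", "tandem", "same", "B"),
        ],
        inversion_spec=InversionSpec(internal_span=45_000),
    )


# ----- pipeline --------------------------------------------------------------


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {cause}")


@dataclass
class PipelineResult:
    config: PipelineConfig
    ancestor: AnnotatedRegion | None = None
    lineage_a: AnnotatedRegion | None = None
    lineage_b: AnnotatedRegion | None = None
    truth: TruthSet | None = None
    contig_length: int | None = None
    assembly_exact: bool | None = None
    scores: list | None = None
    ortholog_table: collinearity.OrthologTable | None = None
    families_a: list | None = None
    blocks: list | None = None
    inversion_calls: list | None = None
    te_report: structure.TEAccountingReport | None = None
    disruptions: collinearity.DisruptionReport | None = None
    divergence_records: list | None = None
    divergence_summary: divergence.RegionDivergenceSummary | None = None
    bes_calls: list | None = None
    bes_verdicts: dict | None = None
    report_text: str | None = None


def tile_region(
    region: AnnotatedRegion, n_bacs: int, overlap: int
) -> list[tuple[str, str]]:
    """Deterministically cut a region into n overlapping clone sequences."""
    L = region.length
    if n_bacs == 1:
        return [(f"{region.id}_bac1", region.sequence)]
    step = (L - overlap) // n_bacs + 1
    bac_len = step + overlap
    bacs = []
    for i in range(n_bacs):
        s = min(i * step, L - bac_len)
        bacs.append((f"{region.id}_bac{i + 1}", region.sequence[s : s + bac_len]))
    return bacs


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the requested stages in dependency order; deterministic per seed.

    A stage failure raises StageFailure naming the stage; outputs written
    before the failure are preserved in out_dir.
    """
    res = PipelineResult(config=config)
    os.makedirs(config.out_dir, exist_ok=True)
    config.to_yaml(os.path.join(config.out_dir, "config.yaml"))
    stages = config.stages

    def want(stage: str) -> bool:
        return stage in stages

    try:
        if want("simulate"):
            params = config.params
            res.ancestor = build_ancestor(params)
            res.lineage_a, res.lineage_b, res.truth = evolve_lineages(res.ancestor, params)
            for r in (res.ancestor, res.lineage_a, res.lineage_b):
                write_region_bundle(r, config.out_dir)
            _write_truth_tables(res.truth, config.out_dir)
    except StageFailure:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageFailure("simulate", e) from e

    try:
        if want("assemble") and res.lineage_a is not None:
            bacs = tile_region(res.lineage_a, config.n_bacs_tiling, config.tiling_overlap)
            contig, layout = assembly.assemble_tiling_path(bacs, min_overlap=2000)
            res.contig_length = len(contig)
            res.assembly_exact = contig == res.lineage_a.sequence
            pd.DataFrame(
                [(r.bac_id, r.offset, r.strand, r.overlap_with_previous) for r in layout],
                columns=["bac_id", "offset", "strand", "overlap_with_previous"],
            ).to_csv(os.path.join(config.out_dir, "assembly_layout.tsv"), sep="\t", index=False)
    except Exception as e:  # noqa: BLE001
        raise StageFailure("assemble", e) from e

    try:
        if want("collinearity") and res.lineage_a is not None:
            res.scores = collinearity.score_gene_pairs(
                res.lineage_a, res.lineage_b, config.min_identity, config.min_coverage
            )
            res.ortholog_table = collinearity.assign_orthologs(
                res.scores, res.lineage_a, res.lineage_b
            )
            res.families_a = collinearity.cluster_families(
                res.lineage_a,
                min_identity=config.family_identity,
                min_coverage=config.family_coverage,
            )
            _write_collinearity_tables(res, config.out_dir)
    except Exception as e:  # noqa: BLE001
        raise StageFailure("collinearity", e) from e

    try:
        if want("structure") and res.lineage_a is not None:
            matches = structure.compute_dotplot(
                res.lineage_a.sequence, res.lineage_b.sequence, k=config.k
            )
            res.blocks, res.inversion_calls = structure.detect_rearranged_segments(
                matches,
                min_block=config.min_block,
                gap=config.gap,
                k=config.k,
                families=res.families_a,
                ref_region=res.lineage_a,
                qry_region=res.lineage_b,
            )
            if res.ortholog_table is not None:
                res.te_report = structure.attribute_size_difference(
                    res.lineage_a, res.lineage_b, res.ortholog_table
                )
                res.disruptions = collinearity.classify_disruptions(
                    res.ortholog_table, res.lineage_a, res.lineage_b, res.blocks
                )
            _write_structure_tables(res, config.out_dir)
    except Exception as e:  # noqa: BLE001
        raise StageFailure("structure", e) from e

    try:
        if want("divergence") and res.ortholog_table is not None:
            recs = []
            ga = {g.id: g for g in res.lineage_a.genes}
            gb = {g.id: g for g in res.lineage_b.genes}
            for p in res.ortholog_table.orthologs():
                a, b = ga[p.gene_a], gb[p.gene_b]
                if a.is_pseudogene or b.is_pseudogene:
                    continue
                if len(a.exons) != len(b.exons):
                    continue  # clearly distinct annotated structure
                recs.append(
                    divergence.compute_ka_ks(
                        a.cds(res.lineage_a.sequence),
                        b.cds(res.lineage_b.sequence),
                        pair_id=f"{p.gene_a}|{p.gene_b}",
                    )
                )
            res.divergence_records = recs
            res.divergence_summary = divergence.summarize_and_flag(
                recs, label="simulated", factor=config.flag_factor, thresholds=config.omega_bands
            )
            _write_divergence_tables(res, config.out_dir)
    except Exception as e:  # noqa: BLE001
        raise StageFailure("divergence", e) from e

    try:
        if want("bes-scan") and res.lineage_a is not None and res.inversion_calls:
            call = max(res.inversion_calls, key=lambda c: c.size)
            inv_span = call.ref_span
            params = config.params
            lib_ref = simulate_bes_library(
                res.lineage_a, config.n_bacs_bes, params, seed=config.seed * 7 + 1, species="same-arrangement"
            )
            lib_alt = simulate_bes_library(
                res.lineage_b, config.n_bacs_bes, params, seed=config.seed * 7 + 2, species="other-arrangement"
            )
            calls = bes.map_bes_pairs(
                lib_ref + lib_alt, res.lineage_a, config.bes_min_identity, config.bes_min_length
            )
            res.bes_calls = [
                bes.classify_spanning_pair(c, inv_span, config.bes_max_span) for c in calls
            ]
            res.bes_verdicts = bes.call_species_structure(res.bes_calls)
            _write_bes_tables(res, config.out_dir)
    except Exception as e:  # noqa: BLE001
        raise StageFailure("bes-scan", e) from e

    if want("report"):
        res.report_text = generate_report(res)
        with open(os.path.join(config.out_dir, "report.txt"), "w") as fh:
            fh.write(res.report_text)
    return res


# ----- table writers ---------------------------------------------------------


def _write_truth_tables(truth: TruthSet, out_dir: str) -> None:
    pd.DataFrame(
        [(r.lineage, r.te_id, r.te_class, r.length, r.nested_in or "", r.span[0], r.span[1])
         for r in truth.te_insertions],
        columns=["lineage", "te_id", "class", "length", "nested_in", "start", "end"],
    ).to_csv(os.path.join(out_dir, "truth_te_insertions.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [(r.lineage, r.source_gene, r.new_gene, r.mode, r.orientation, r.span[0], r.span[1])
         for r in truth.duplications],
        columns=["lineage", "source_gene", "new_gene", "mode", "orientation", "start", "end"],
    ).to_csv(os.path.join(out_dir, "truth_duplications.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [(r.gene_id, r.lineage, r.omega_target, r.syn, r.nonsyn) for r in truth.substitutions],
        columns=["gene", "lineage", "omega_target", "syn", "nonsyn"],
    ).to_csv(os.path.join(out_dir, "truth_substitutions.tsv"), sep="\t", index=False)
    rows = []
    if truth.inversion:
        i = truth.inversion
        rows.append((i.lineage, i.flank_a, i.flank_b, i.family_id, i.breakpoints[0], i.breakpoints[1]))
    pd.DataFrame(
        rows, columns=["lineage", "flank_a", "flank_b", "family", "left", "right"]
    ).to_csv(os.path.join(out_dir, "truth_inversion.tsv"), sep="\t", index=False)


def _write_collinearity_tables(res: PipelineResult, out_dir: str) -> None:
    pd.DataFrame(
        [(s.gene_a, s.gene_b, round(s.identity, 3), round(s.coverage, 3), s.score) for s in res.scores],
        columns=["gene_a", "gene_b", "identity", "coverage", "score"],
    ).to_csv(os.path.join(out_dir, "gene_pair_scores.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [(p.gene_a or "", p.gene_b or "", p.identity if p.identity is not None else "", p.relation)
         for p in res.ortholog_table.pairs],
        columns=["gene_a", "gene_b", "identity", "relation"],
    ).to_csv(os.path.join(out_dir, "ortholog_table.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [(f.family_id, ",".join(f.members), f.arrangement, f.orientation_pattern, f.max_separation)
         for f in res.families_a],
        columns=["family", "members", "arrangement", "orientation", "max_separation"],
    ).to_csv(os.path.join(out_dir, "gene_families.tsv"), sep="\t", index=False)


def _write_structure_tables(res: PipelineResult, out_dir: str) -> None:
    pd.DataFrame(
        [(b.ref_span[0], b.ref_span[1], b.qry_span[0], b.qry_span[1], b.orientation, b.match_count)
         for b in res.blocks],
        columns=["ref_start", "ref_end", "qry_start", "qry_end", "orientation", "matches"],
    ).to_csv(os.path.join(out_dir, "synteny_blocks.tsv"), sep="\t", index=False)
    # BED companion: 0-based half-open
    with open(os.path.join(out_dir, "synteny_blocks.bed"), "w") as fh:
        fh.write("# 0-based half-open companion of synteny_blocks.tsv (reference coordinates)\n")
        for b in res.blocks:
            fh.write(f"ref\t{b.ref_span[0] - 1}\t{b.ref_span[1]}\tblock\t{b.match_count}\t{b.orientation}\n")
    pd.DataFrame(
        [
            (c.ref_span[0], c.ref_span[1], c.qry_span[0], c.qry_span[1], c.size,
             c.breakpoint_left_ref[0], c.breakpoint_left_ref[1],
             c.breakpoint_right_ref[0], c.breakpoint_right_ref[1],
             c.flanking_duplicate_family or "")
            for c in (res.inversion_calls or [])
        ],
        columns=["ref_start", "ref_end", "qry_start", "qry_end", "size",
                 "bp_left_lo", "bp_left_hi", "bp_right_lo", "bp_right_hi", "flank_family"],
    ).to_csv(os.path.join(out_dir, "inversion_calls.tsv"), sep="\t", index=False)
    if res.te_report:
        pd.DataFrame(res.te_report.calls, columns=["lineage", "te_id", "verdict"]).to_csv(
            os.path.join(out_dir, "te_attribution.tsv"), sep="\t", index=False
        )


def _write_divergence_tables(res: PipelineResult, out_dir: str) -> None:
    pd.DataFrame(
        [
            (r.pair_id, round(r.n_sites, 2), round(r.s_sites, 2), r.nd, r.sd,
             "" if r.ka is None else round(r.ka, 5),
             "" if r.ks is None else round(r.ks, 5),
             "" if r.omega is None else round(r.omega, 4),
             divergence.classify_selection(r, res.config.omega_bands))
            for r in res.divergence_records
        ],
        columns=["pair", "N", "S", "Nd", "Sd", "Ka", "Ks", "omega", "selection_class"],
    ).to_csv(os.path.join(out_dir, "divergence_records.tsv"), sep="\t", index=False)


def _write_bes_tables(res: PipelineResult, out_dir: str) -> None:
    pd.DataFrame(
        [
            (c.bac_id, c.species,
             c.hit1.position if c.hit1 else "", c.hit1.strand if c.hit1 else "",
             c.hit2.position if c.hit2 else "", c.hit2.strand if c.hit2 else "",
             c.mapped_span or "", c.spanning, c.orientation_class, c.structure_call, c.reason)
            for c in res.bes_calls
        ],
        columns=["bac_id", "species", "pos1", "strand1", "pos2", "strand2",
                 "span", "spanning", "orientation", "structure_call", "reason"],
    ).to_csv(os.path.join(out_dir, "bes_calls.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [(v.species, v.verdict, v.n_reference_like, v.n_inverted) for v in res.bes_verdicts.values()],
        columns=["species", "verdict", "n_reference_like", "n_inverted"],
    ).to_csv(os.path.join(out_dir, "bes_verdicts.tsv"), sep="\t", index=False)


# ----- consolidated report ----------------------------------------------------


def generate_report(res: PipelineResult) -> str:
    """One human-readable document summarising every computed stage.

    Kilobase values are reported both as floor-kb and exact bp, because
    rounding conventions differ between summaries (a 5,685 bp/gene density
    reads as '1 gene per 5 kb' under floor but '6 kb' under nearest-kb).
    """
    lines: list[str] = ["# Regional comparison report", ""]
    if res.lineage_a is not None:
        for lab, region in (("A", res.lineage_a), ("B", res.lineage_b)):
            n_genes = len(region.genes)
            lines.append(f"Region {lab} ({region.id}): {region.length:,} bp, {n_genes} genes, {len(region.tes)} TEs")
            if n_genes:
                d = gene_density_bp(region.length, n_genes)
                lines.append(
                    f"  gene density: 1 gene per {floor_kb(region.length // n_genes)} kb "
                    f"(exact {d:,.0f} bp/gene; nearest-kb: {nearest_kb(d)} kb)"
                )
        lines.append("")
    if res.contig_length is not None:
        status = "exact" if res.assembly_exact else "MISMATCH"
        lines.append(f"Tiling-path assembly: contig {res.contig_length:,} bp ({status} reconstruction)")
        lines.append("")
    if res.families_a is not None:
        lines.append(f"Duplicated gene families in region A: {len(res.families_a)}")
        for f in res.families_a:
            lines.append(
                f"  {f.family_id}: {len(f.members)} members, {f.arrangement}, "
                f"{f.orientation_pattern} orientation, max separation {f.max_separation:,} bp"
            )
        lines.append("")
    if res.ortholog_table is not None:
        t = res.ortholog_table
        lines.append(
            f"Orthologs: {len(t.orthologs())} pairs; conserved order+orientation: "
            f"{100 * t.conserved_order_fraction:.1f}%"
        )
        if res.disruptions is not None:
            d = res.disruptions
            te_a = sum(1 for _, te in d.extra_in_a if te)
            lines.append(
                f"Disruptions: {len(d.extra_in_a)} extra in A ({te_a} TE-enclosed), "
                f"{len(d.extra_in_b)} extra in B, {len(d.inverted)} inverted pairs, "
                f"{len(d.rearranged)} rearranged"
            )
        lines.append("")
    if res.inversion_calls is not None:
        if res.inversion_calls:
            for c in res.inversion_calls:
                fam = f", flanked by duplicate family {c.flanking_duplicate_family}" if c.flanking_duplicate_family else ""
                lines.append(
                    f"Inversion: ref {c.ref_span[0]:,}-{c.ref_span[1]:,} "
                    f"({floor_kb(c.size)} kb; exact {c.size:,} bp){fam}"
                )
        else:
            lines.append("no inversions detected")
        lines.append("")
    if res.te_report is not None:
        r = res.te_report
        for lab in ("A", "B"):
            lines.append(
                f"Lineage-specific TE in {lab}: {r.specific_bp[lab]:,} bp "
                f"({100 * r.fraction[lab]:.1f}% of region; {r.specific_count[lab]} elements)"
            )
        lines.append("")
    if res.divergence_summary is not None:
        s = res.divergence_summary
        lines.append(
            f"Divergence over {s.n_pairs} pairs: mean Ka = {s.mean_ka:.4f}, mean Ks = {s.mean_ks:.4f}"
        )
        lines.append(
            f"  flagged (>= {res.config.flag_factor}x mean): "
            + (", ".join(f"{pid} ({why})" for pid, why in s.elevated) or "none")
        )
        lines.append(f"  selection classes: {s.class_counts}")
        lines.append("")
    if res.bes_verdicts is not None:
        lines.append("BES arrangement verdicts:")
        for v in res.bes_verdicts.values():
            lines.append(
                f"  {v.species}: {v.verdict} ({v.n_reference_like} reference-like : {v.n_inverted} inverted)"
            )
        lines.append("")
    return "\n".join(lines)


def report_checksum(res: PipelineResult) -> str:
    return hashlib.sha256((res.report_text or "").encode()).hexdigest()
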