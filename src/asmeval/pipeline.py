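"""End-to-end pipeline: simulate -> collapse/expand -> read movement ->
base validation -> variant transitions.

Each stage is a pure function of files under a working directory with a
fixed layout (written by the simulate stage), so re-running a single stage
from cached upstream outputs is bit-identical to a full run.  The summary
JSON records every resolved default and threshold, plus a truth-versus-
called concordance section computed against the simulator's manifest.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import pysam
import yaml
from pyfaidx import Fasta

from . import base_validation as bv
from . import collapse_expand as ce
from . import read_movement as rm
from . import simulate as sim
from . import variant_remap as vr
from .formats import (
    GenomicInterval,
    VariantSite,
    invert_block,
    load_primary_placements,
    parse_agp,
    parse_alignment_table,
    parse_vcf_sites,
    read_bed,
    read_role_table,
    write_vcf_sites,
)

SCHEMA_VERSION = 1


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "asmeval_out"
    simulate: dict = field(default_factory=dict)
    region_filter: dict = field(default_factory=dict)
    movement: dict = field(default_factory=dict)
    classifier: dict = field(default_factory=dict)
    coverage: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def resolved(self) -> dict:
        """Every parameter with defaults filled in, for the summary JSON."""
        sim_cfg = _sim_config(self)
        return {
            "schema_version": SCHEMA_VERSION,
            "seed": self.seed,
            "simulate": dataclasses.asdict(sim_cfg),
            "simulate_extra": {
                "n_candidate_sites": self.simulate.get("n_candidate_sites", 24),
                "type_mix": self.simulate.get("type_mix", {"SNV": 0.6, "INS": 0.2, "DEL": 0.2}),
                "genotype_mix": self.simulate.get(
                    "genotype_mix", {"HOM_REF": 0.25, "HET": 0.5, "HOM_ALT": 0.25}
                ),
                "novel_length": self.simulate.get("novel_length", 0),
            },
            "region_filter": dataclasses.asdict(
                ce.RegionFilterParams(**self.region_filter)
            ),
            "movement": {
                "min_mapq": self.movement.get("min_mapq", 20),
                "primary_only": self.movement.get("primary_only", True),
            },
            "classifier": dataclasses.asdict(bv.ClassifierParams(**self.classifier)),
            "coverage": {
                "min_mapq": self.coverage.get("min_mapq", 20),
                "merge_distance": self.coverage.get("merge_distance", 100_000),
            },
        }


def _sim_config(cfg: PipelineConfig) -> sim.SimConfig:
    fields = {f.name for f in dataclasses.fields(sim.SimConfig)}
    kwargs = {k: v for k, v in cfg.simulate.items() if k in fields}
    kwargs.setdefault("seed", cfg.seed)
    return sim.SimConfig(**kwargs)


def _sim_dir(workdir: str) -> str:
    return os.path.join(workdir, "sim")


def _read_fasta(path: str) -> dict[str, str]:
    fa = Fasta(path, as_raw=True)  # creates/uses the .fai faidx index
    return {name: str(fa[name][:]) for name in fa.keys()}


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def stage_simulate(cfg: PipelineConfig) -> dict:
    workdir = cfg.outdir
    config = _sim_config(cfg)
    donor = sim.build_donor(config)
    suite = sim.standard_event_suite(donor)
    pair = sim.derive_assembly_pair(donor, suite.events, suite.scaffolds)
    plant = sim.plant_candidate_sites(
        pair,
        n_sites=cfg.simulate.get("n_candidate_sites", 24),
        type_mix=cfg.simulate.get("type_mix", {"SNV": 0.6, "INS": 0.2, "DEL": 0.2}),
        genotype_mix=cfg.simulate.get(
            "genotype_mix", {"HOM_REF": 0.25, "HET": 0.5, "HOM_ALT": 0.25}
        ),
    )
    sources = sim.build_sample(
        pair, plant.hap_edits, novel_length=cfg.simulate.get("novel_length", 0)
    )
    reads = sim.simulate_reads(pair, sources, config)
    transition_sites, _truth = sim.plant_transition_sites(pair)
    outdir = _sim_dir(workdir)
    paths = sim.write_reads(reads, outdir)
    paths.update(sim.write_sites(plant, pair, outdir))
    write_vcf_sites(
        transition_sites,
        {s: len(q) for s, q in pair.A.sequences.items()},
        os.path.join(outdir, "transition_sites.vcf"),
    )
    # manifest is written last so reads, genotypes and probes are attached
    paths.update(sim.write_pair(pair, outdir))
    return {
        "n_pairs": reads.n_pairs(),
        "n_sites": len(plant.sites),
        "n_transition_probes": len(transition_sites),
    }


def stage_collapse_expand(workdir: str, params: ce.RegionFilterParams | None = None) -> dict:
    d = _sim_dir(workdir)
    params = params or ce.RegionFilterParams()
    blocks = parse_alignment_table(open(os.path.join(d, "truth_alignments.paf")))
    out = {}
    for side, fasta, agp_name, focal_blocks in (
        ("A", "assemblyA.fa", "assemblyA.agp", blocks),
        ("B", "assemblyB.fa", "assemblyB.agp", [invert_block(b) for b in blocks]),
    ):
        seqs = _read_fasta(os.path.join(d, fasta))
        agp = parse_agp(open(os.path.join(d, agp_name)))
        regions = {
            sid: ce.ungapped_regions(
                seqs[sid],
                [r for r in agp if r.object_id == sid],
                params,
                seq_id=sid,
            )
            for sid in seqs
        }
        tracks = ce.label_bases(focal_blocks, {s: len(q) for s, q in seqs.items()})
        table, top = ce.summarize(tracks, regions)
        stage_dir = os.path.join(workdir, "collapse_expand")
        os.makedirs(stage_dir, exist_ok=True)
        table.to_csv(os.path.join(stage_dir, f"labels.{side}.tsv"), sep="\t", index=False)
        with open(os.path.join(stage_dir, f"intervals.{side}.bed"), "w") as fh:
            for sid in sorted(tracks):
                for s, e, lab in tracks[sid].runs:
                    fh.write(f"{sid}\t{s}\t{e}\t{lab}\n")
        out[side] = ce.label_lengths(table)
    return out


def stage_read_movement(workdir: str, movement_cfg: dict | None = None) -> dict:
    d = _sim_dir(workdir)
    movement_cfg = movement_cfg or {}
    config = rm.MovementConfig(
        min_mapq=movement_cfg.get("min_mapq", 20),
        primary_only=movement_cfg.get("primary_only", True),
        centromere_bed=read_bed(os.path.join(d, "centromere.B.bed")),
        roles=read_role_table(os.path.join(d, "roles.tsv")),
    )
    agp_a = parse_agp(open(os.path.join(d, "assemblyA.agp")))
    agp_b = parse_agp(open(os.path.join(d, "assemblyB.agp")))
    pl_a = load_primary_placements(os.path.join(d, "reads.A.sam"))
    pl_b = load_primary_placements(os.path.join(d, "reads.B.sam"))
    pl_bf = load_primary_placements(os.path.join(d, "reads.B_full.sam"))
    regions = rm.unchanged_regions(agp_a, agp_b)
    eligible = rm.select_unique_pairs(pl_a, config, regions)
    records, stats = rm.detect_moved_pairs(eligible, pl_a, pl_b, agp_a, agp_b, config)
    for rec in records:
        rm.classify_movement(rec, config)
    rescue = rm.rescue_stats(
        pl_a, pl_b, pl_bf, read_bed(os.path.join(d, "new_sequence.B.bed"))
    )
    pairings = rm.component_pairings(records)

    stage_dir = os.path.join(workdir, "read_movement")
    os.makedirs(stage_dir, exist_ok=True)
    with open(os.path.join(stage_dir, "movement.tsv"), "w") as fh:
        fh.write("read_id\tmate\tseq_a\tpos_a\tseq_b\tpos_b\tcomponent_a\tcomponent_b\tcategory\n")
        for r in sorted(records, key=lambda r: (r.read_id, r.mate)):
            fh.write(
                f"{r.read_id}\t{r.mate}\t{r.placement_a.seq_id}\t{r.placement_a.pos}\t"
                f"{r.placement_b.seq_id}\t{r.placement_b.pos}\t"
                f"{r.component_a}\t{r.component_b}\t{r.category}\n"
            )
    counts = {c: 0 for c in rm.CATEGORIES}
    for r in records:
        counts[r.category] += 1
    with open(os.path.join(stage_dir, "category_summary.tsv"), "w") as fh:
        fh.write("category\treads\n")
        for c in rm.CATEGORIES:
            fh.write(f"{c}\t{counts[c]}\n")
    with open(os.path.join(stage_dir, "pairings.tsv"), "w") as fh:
        fh.write("component_a\tcomponent_b\treads\n")
        for a, b, n in pairings:
            fh.write(f"{a}\t{b}\t{n}\n")
    return {
        "n_eligible": stats.n_eligible,
        "n_moved": stats.n_moved,
        "fraction_moved": stats.fraction_moved,
        "fraction_moved_also_unique_in_b": stats.fraction_moved_also_unique_in_b,
        "categories": counts,
        "rescue": {
            "fraction_a_unmapped_rescued": rescue.fraction_a_unmapped_rescued,
            "fraction_rescued_in_new_sequence": rescue.fraction_rescued_in_new_sequence,
            "fraction_b_unmapped_rescued_full": rescue.fraction_b_unmapped_rescued_full,
        },
        "records": [
            {"read_id": r.read_id, "mate": r.mate, "category": r.category}
            for r in records
        ],
    }


def _read_site_flags(vcf_path: str) -> dict[str, bool]:
    flags: dict[str, bool] = {}
    with pysam.VariantFile(vcf_path) as vf:
        for rec in vf:
            sid = rec.id or f"{rec.chrom}_{rec.pos}"
            flags[sid] = str(rec.info.get("SRC", "0")) == "1"
    return flags


def stage_base_validation(workdir: str, params: bv.ClassifierParams | None = None) -> dict:
    d = _sim_dir(workdir)
    params = params or bv.ClassifierParams()
    sites = parse_vcf_sites(os.path.join(d, "candidate_sites.vcf"))
    in_source = _read_site_flags(os.path.join(d, "candidate_sites.vcf"))
    reference = _read_fasta(os.path.join(d, "assemblyA.fa"))
    tallies = bv.pileup_tally(
        os.path.join(d, "reads.A.sam"), sites, params, reference
    )
    contigs = _read_fasta(os.path.join(d, "minicontigs.fa"))
    windows = {}
    with open(os.path.join(d, "minicontig_windows.bed")) as fh:
        for line in fh:
            f = line.split("\t")
            windows[f[3].strip()] = GenomicInterval(f[0], int(f[1]), int(f[2]))

    stage_dir = os.path.join(workdir, "base_validation")
    os.makedirs(stage_dir, exist_ok=True)
    rows = []
    updates: list[VariantSite] = []
    decisions: dict[str, str] = {}
    minicontig_pass: dict[str, bool] = {}
    for t in tallies:
        cls = bv.classify_site(t, params)
        dec = bv.decide_update(t.site, cls, in_source.get(t.site.site_id, False))
        decisions[t.site.site_id] = dec.decision
        if dec.decision == bv.APPLY_UPDATE:
            updates.append(t.site)
        mc_ok = None
        if t.site.site_id in contigs and t.site.site_id in windows:
            w = windows[t.site.site_id]
            result = bv.validate_minicontig(
                contigs[t.site.site_id],
                reference[w.seq_id][w.start : w.end],
                t.site,
                w.start,
            )
            mc_ok = result.passed
            minicontig_pass[t.site.site_id] = result.passed
        counts = ",".join(f"{a}:{n}" for a, n in sorted(t.counts.items()))
        rows.append(
            (t.site.site_id, t.site.seq_id, t.site.pos, t.site.site_type,
             t.depth, counts, cls.call,
             "" if cls.majority_fraction is None else f"{cls.majority_fraction:.4f}",
             dec.decision, dec.reason, mc_ok)
        )
    with open(os.path.join(stage_dir, "sites.tsv"), "w") as fh:
        fh.write(
            "site_id\tseq_id\tpos\ttype\tdepth\tcounts\tclassification\t"
            "majority_fraction\tdecision\treason\tminicontig_pass\n"
        )
        for row in rows:
            fh.write("\t".join("" if v is None else str(v) for v in row) + "\n")
    write_vcf_sites(
        updates,
        {s: len(q) for s, q in reference.items()},
        os.path.join(stage_dir, "updates.vcf"),
    )
    calls = {r[0]: r[6] for r in rows}
    return {
        "n_sites": len(sites),
        "calls": calls,
        "decisions": decisions,
        "minicontig_pass": minicontig_pass,
        "n_updates": len(updates),
    }


def stage_variant_transition(workdir: str, coverage_cfg: dict | None = None) -> dict:
    d = _sim_dir(workdir)
    coverage_cfg = coverage_cfg or {}
    min_mapq = coverage_cfg.get("min_mapq", 20)
    merge_distance = coverage_cfg.get("merge_distance", 100_000)
    sites_path = os.path.join(d, "transition_sites.vcf")
    if not os.path.exists(sites_path):
        sites_path = os.path.join(d, "candidate_sites.vcf")
    sites = parse_vcf_sites(sites_path)
    blocks = parse_alignment_table(open(os.path.join(d, "truth_alignments.paf")))
    roles = read_role_table(os.path.join(d, "roles.tsv"))
    pl_a = load_primary_placements(os.path.join(d, "reads.A.sam"))
    pl_b = load_primary_placements(os.path.join(d, "reads.B.sam"))
    status_a = vr.site_coverage(pl_a, sites, min_mapq)
    remaps = vr.remap_sites(sites, blocks, roles)
    b_probe_sites = []
    for r in remaps:
        if r.best_status != "unique":
            continue
        seq_b, pos_b = r.best[0], r.best[1]
        b_probe_sites.append(
            VariantSite(seq_b, pos_b, "N", "N", f"probe_{r.site.site_id}", "SNV")
        )
    status_b = vr.site_coverage(pl_b, b_probe_sites, min_mapq)
    report = vr.coverage_transition(status_a, remaps, status_b, merge_distance)

    stage_dir = os.path.join(workdir, "variant_transition")
    os.makedirs(stage_dir, exist_ok=True)
    cov_a = {c.site.site_id: c for c in status_a}
    cov_b = {(c.site.seq_id, c.site.pos): c for c in status_b}
    gained_ids = {s.site_id for s in report.gained}
    lost_ids = {s.site_id for s in report.lost}
    group_of: dict[str, int] = {}
    for gi, group in enumerate(report.gained_groups):
        for s in group:
            group_of[s.site_id] = gi
    for gi, group in enumerate(report.lost_groups):
        for s in group:
            group_of[s.site_id] = gi
    with open(os.path.join(stage_dir, "transition.tsv"), "w") as fh:
        fh.write("site_id\tseq_a\tpos_a\tstatus_a\tstatus_b\tambiguous\ttransition\tregion_group\n")
        for r in remaps:
            sid = r.site.site_id
            sa = cov_a[sid].status
            if r.best_status != "unique":
                sb = "NA"
            else:
                sb = cov_b[(r.best[0], r.best[1])].status
            trans = "GAINED" if sid in gained_ids else ("LOST" if sid in lost_ids else ".")
            fh.write(
                f"{sid}\t{r.site.seq_id}\t{r.site.pos}\t{sa}\t{sb}\t"
                f"{int(r.ambiguous)}\t{trans}\t{group_of.get(sid, '.')}\n"
            )
    return {
        "n_sites": len(sites),
        "gained": sorted(gained_ids),
        "lost": sorted(lost_ids),
        "n_gained_groups": len(report.gained_groups),
        "n_lost_groups": len(report.lost_groups),
        "n_ambiguous": report.n_ambiguous_skipped,
        "n_unmapped": report.n_unmapped_skipped,
    }


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

_STAGES = (
    "simulate",
    "collapse_expand",
    "read_movement",
    "base_validation",
    "variant_transition",
)


def run(cfg: PipelineConfig) -> dict:
    """Run all stages in dependency order and write the summary JSON."""
    os.makedirs(cfg.outdir, exist_ok=True)
    summary: dict = {"parameters": cfg.resolved(), "stages": {}, "incomplete": True}
    try:
        for stage in _STAGES:
            try:
                if stage == "simulate":
                    result = stage_simulate(cfg)
                elif stage == "collapse_expand":
                    result = stage_collapse_expand(
                        cfg.outdir, ce.RegionFilterParams(**cfg.region_filter)
                    )
                elif stage == "read_movement":
                    result = stage_read_movement(cfg.outdir, cfg.movement)
                elif stage == "base_validation":
                    result = stage_base_validation(
                        cfg.outdir, bv.ClassifierParams(**cfg.classifier)
                    )
                else:
                    result = stage_variant_transition(cfg.outdir, cfg.coverage)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - stage boundary
                raise StageError(stage, str(exc)) from exc
            summary["stages"][stage] = result
        summary["concordance"] = _concordance(cfg.outdir, summary)
        summary["incomplete"] = False
    finally:
        with open(os.path.join(cfg.outdir, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
            fh.write("\n")
    return summary


def _concordance(workdir: str, summary: dict) -> dict:
    """Truth-versus-called agreement, computed from the simulator manifest."""
    with open(os.path.join(_sim_dir(workdir), "truth_manifest.json")) as fh:
        manifest = json.load(fh)
    out: dict = {}

    truth_lengths = manifest["truth_label_lengths"]
    called = summary["stages"]["collapse_expand"]
    out["label_lengths_exact"] = {
        side: {
            lab: int(called[side].get(lab, 0)) == int(truth_lengths[side][lab])
            for lab in ("COLLAPSED", "EXPANDED")
        }
        for side in ("A", "B")
    }

    truth_cats = manifest["moved_read_categories"]
    records = summary["stages"]["read_movement"]["records"]
    n_match = sum(
        1
        for r in records
        if truth_cats.get(f"{r['read_id']}/{r['mate']}") == r["category"]
    )
    out["movement_category_agreement"] = (
        n_match / len(records) if records else None
    )
    out["movement_truth_reads"] = len(truth_cats)
    out["movement_called_reads"] = len(records)

    truth_geno = manifest.get("genotypes", {})
    calls = summary["stages"]["base_validation"]["calls"]
    both = [sid for sid in calls if sid in truth_geno]
    n_geno = sum(1 for sid in both if calls[sid] == truth_geno[sid])
    out["genotype_agreement"] = n_geno / len(both) if both else None

    truth_trans = manifest.get("truth_transitions", {})
    vt = summary["stages"]["variant_transition"]
    called_trans = {sid: "GAINED" for sid in vt["gained"]}
    called_trans.update({sid: "LOST" for sid in vt["lost"]})
    out["transition_agreement"] = {
        "gained_exact": sorted(vt["gained"])
        == sorted(s for s, t in truth_trans.items() if t == "GAINED"),
        "lost_exact": sorted(vt["lost"])
        == sorted(s for s, t in truth_trans.items() if t == "LOST"),
    }
    # drop the verbose per-read list from the persisted summary
    summary["stages"]["read_movement"]["records"] = len(records)
    return out
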