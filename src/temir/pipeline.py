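"""End-to-end orchestration: simulate -> homology -> profile -> annotate ->
predict -> degradome, from a single config, with figure-shaped report tables.

Every numeric threshold of the analysis lives in :class:`Thresholds` with
the printed defaults (TE-MIR call at E <= 0.005, target HSPs at E <= 0.05
and genes at E <= 0.01, genome hit <= 20, pairing score <= 4 with MFE
ratio >= 73%, usable sequencing total >= 10) and is echoed into every
table header.  Outputs are deterministic for a fixed seed; reruns are
byte-identical, so report files carry no timestamps.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, fields, replace as dc_replace
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import call_duplex, detect_inverted_te_pair, screen_typical
from .degradome import profile_from_counts, score_targets, scores_to_table
from .fold import fold_hairpin
from .homology import classify_gene_annotation, find_initial_targets, find_te_mirs
from .io import (
    write_annotation_table,
    write_degradome_table,
    write_fasta,
    write_gff3,
    write_json,
    write_srna_table,
)
from .profiling import aggregate_length_spectrum, build_profile, reads_from_table
from .sequtil import random_seq
from .synthetic import (
    GenomeTruth,
    SrnaProfileSpec,
    add_hairpin_locus,
    embed_te_in_cds,
    generate_te_family,
    make_genes,
    plant_duplex_mismatches,
    plant_insertions,
    simulate_degradome,
    simulate_srna_reads,
    speciate_hairpin_copy,
)
from .targets import (
    SrnaRecord,
    TargetPrediction,
    build_interaction_matrix,
    predict_targets,
    predictions_to_table,
)

log = logging.getLogger("temir")

GENE_DESCRIPTIONS = [
    "MYB family transcription factor, putative",
    "retrotransposon protein, putative, unclassified",
    "expressed protein",
    "serine/threonine protein kinase, putative",
    "transposon protein, putative, CACTA, En/Spm sub-class",
    "expressed protein, unknown function",
    "hypothetical protein",
    "pentatricopeptide repeat protein, putative",
]


@dataclass
class Thresholds:
    """All printed analysis thresholds (config-overridable)."""

    e_temir: float = 0.005
    e_hsp: float = 0.05
    e_gene: float = 0.01
    hit_max: float = 20.0
    score_max: float = 4.0
    ratio_min: float = 73.0
    usable_min: float = 10.0
    minor_fraction: float = 0.10
    dominance_min: float = 5.0
    window_concentration_min: float = 0.75

    def __post_init__(self):
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"threshold {f.name} must be positive")


@dataclass
class SimConfig:
    """The stated synthetic world behind a default pipeline run."""

    chrom_len: int = 60_000
    te_len: int = 200
    tir_len: int = 80
    mir_window: tuple[int, int] = (10, 31)
    n_datasets: int = 3
    depth: int = 1500
    degradome_datasets: int = 2
    n_decoy_hairpins: int = 2
    n_typical_palindrome: int = 2
    n_typical_inverted_pair: int = 1
    n_smeared: int = 3
    n_high_copy: int = 2
    n_both_strand: int = 2
    n_genes: int = 8
    n_target_genes: int = 3
    gene_len: int = 400
    cds_margin: int = 50
    background_copies: int = 2
    high_copy_number: int = 30
    degradome_signal: int = 40
    degradome_noise_positions: int = 12
    degradome_noise_reads: int = 5


@dataclass
class RunConfig:
    seed: int = 1
    out_dir: str = "temir_run"
    thresholds: Thresholds = field(default_factory=Thresholds)
    sim: SimConfig = field(default_factory=SimConfig)
    stages: dict[str, bool] = field(
        default_factory=lambda: {
            "simulate": True, "homology": True, "profile": True,
            "annotate": True, "predict": True, "degradome": True,
        }
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        cfg = cls()
        if "seed" in raw:
            cfg.seed = int(raw["seed"])
        if "out_dir" in raw:
            cfg.out_dir = str(raw["out_dir"])
        for key, value in (raw.get("thresholds") or {}).items():
            if not hasattr(cfg.thresholds, key):
                raise ValueError(f"unknown threshold {key!r}")
            setattr(cfg.thresholds, key, float(value))
        for key, value in (raw.get("simulation") or {}).items():
            if not hasattr(cfg.sim, key):
                raise ValueError(f"unknown simulation key {key!r}")
            current = getattr(cfg.sim, key)
            setattr(cfg.sim, key, tuple(value) if isinstance(current, tuple) else type(current)(value))
        for key, value in (raw.get("stages") or {}).items():
            if key not in cfg.stages:
                raise ValueError(f"unknown stage {key!r}")
            cfg.stages[key] = bool(value)
        return cfg


@dataclass
class World:
    """Everything the simulate stage hands to the analysis stages."""

    truth: GenomeTruth
    families: list
    hairpins: dict[str, str]
    srna_table: pd.DataFrame
    cds_set: dict[str, str]
    cdna_set: dict[str, str]
    annotations: dict[str, str]
    degradome_table: pd.DataFrame
    archetypes: dict[str, str]
    locus_mir_windows: dict[str, tuple[int, int]]


@dataclass
class RunReport:
    version: str
    seed: int
    thresholds: dict[str, float]
    counts: dict[str, int] = field(default_factory=dict)
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    world: "World | None" = None


def _derive_seed(seed: int, k: int) -> int:
    return int((seed * 100_003 + k) % (2**31 - 1))


def simulate_world(sim: SimConfig, seed: int) -> World:
    """Generate the full synthetic world with ground truth."""
    rng_seed = lambda k: _derive_seed(seed, k)
    families = []
    loci_plan: list[tuple[str, str, str]] = []  # (family idx tag, architecture, archetype)
    k = 0
    for _ in range(sim.n_typical_palindrome):
        families.append(generate_te_family("MITE", sim.te_len, sim.tir_len,
                                           sim.background_copies, 0.05, rng_seed(k),
                                           family_id=f"MITE_t{k}"))
        loci_plan.append((families[-1].family_id, "single_palindrome", "typical"))
        k += 1
    for _ in range(sim.n_typical_inverted_pair):
        # short non-autonomous retrotransposons: no terminal inverted repeat;
        # the hairpin arises from juxtaposition of two inverted copies
        families.append(generate_te_family("retrotransposon", sim.te_len // 2, 0,
                                           sim.background_copies, 0.05, rng_seed(k),
                                           family_id=f"RETRO_t{k}"))
        loci_plan.append((families[-1].family_id, "inverted_pair", "typical"))
        k += 1
    for _ in range(sim.n_smeared):
        families.append(generate_te_family("MITE", sim.te_len, sim.tir_len,
                                           sim.background_copies, 0.05, rng_seed(k),
                                           family_id=f"MITE_s{k}"))
        loci_plan.append((families[-1].family_id, "single_palindrome", "smeared"))
        k += 1
    for _ in range(sim.n_high_copy):
        families.append(generate_te_family("MITE", sim.te_len, sim.tir_len,
                                           sim.high_copy_number, 0.0, rng_seed(k),
                                           family_id=f"MITE_h{k}"))
        loci_plan.append((families[-1].family_id, "single_palindrome", "high_copy"))
        k += 1
    for _ in range(sim.n_both_strand):
        families.append(generate_te_family("other_DNA", sim.te_len, sim.tir_len,
                                           sim.background_copies, 0.05, rng_seed(k),
                                           family_id=f"DNA_b{k}"))
        loci_plan.append((families[-1].family_id, "single_palindrome", "both_strand"))
        k += 1

    fam_by_id = {f.family_id: f for f in families}
    copy_numbers = {
        f.family_id: (sim.high_copy_number if f.family_id.startswith("MITE_h")
                      else sim.background_copies)
        for f in families
    }
    truth = plant_insertions(families, {"chr1": sim.chrom_len}, copy_numbers,
                             seed=rng_seed(900))
    truth.hairpin_loci.clear()  # designated loci below carry the planted profiles

    make_genes(truth, sim.n_genes, sim.gene_len, sim.cds_margin,
               GENE_DESCRIPTIONS, seed=rng_seed(901), clearance=sim.te_len)

    s, e = sim.mir_window
    hairpins: dict[str, str] = {}
    archetypes: dict[str, str] = {}
    locus_mir_windows: dict[str, tuple[int, int]] = {}
    locus_copies: dict[str, str] = {}
    for idx, (fid, arch, archetype) in enumerate(loci_plan):
        fam = fam_by_id[fid]
        if archetype == "high_copy":
            copies = [fam.consensus]
        elif arch == "inverted_pair":
            # two cognate copies whose juxtaposition forms the stem; the
            # second carries a few non-cognate substitutions so the duplex
            # holds internal mismatches like a real miRNA/miRNA* pair
            c1 = fam.copies[0][0]
            c2 = plant_duplex_mismatches(c1, (s, e), rng_seed(1000 + idx))
            copies = [c1, c2]
        else:
            copies = [speciate_hairpin_copy(fam, (s, e), rng_seed(1000 + idx))]
        locus = add_hairpin_locus(truth, fam, copies, arch, rng_seed(1100 + idx),
                                  locus_id=f"temir{idx}", clearance=sim.te_len)
        lseq = truth.locus_sequence(locus)
        hairpins[locus.locus_id] = lseq
        archetypes[locus.locus_id] = archetype
        locus_mir_windows[locus.locus_id] = (s, e)
        locus_copies[locus.locus_id] = lseq

    # decoy hairpins: random foldback-free sequences, not TE derived
    rng = np.random.default_rng(rng_seed(902))
    for d in range(sim.n_decoy_hairpins):
        hairpins[f"decoy{d}"] = random_seq(sim.te_len, rng)
        archetypes[f"decoy{d}"] = "decoy"

    # cognate TE fragments into CDS of target genes
    target_locus_ids = [lid for lid, a in archetypes.items() if a == "typical"]
    eligible_genes = [g for g in truth.genes if "hypothetical" not in g.description]
    planted_sites: list[tuple[str, str, int]] = []  # (gene, locus, cleavage pos on cdna)
    for j in range(min(sim.n_target_genes, len(eligible_genes))):
        gene = eligible_genes[j]
        lid = target_locus_ids[j % len(target_locus_ids)]
        te_copy = locus_copies[lid][:sim.te_len]
        fam_id = next(h.family_id for h in truth.hairpin_loci if h.locus_id == lid)
        inside = min(e + 20, len(te_copy) - 1, (gene.cds[1] - gene.cds[0]) - 1)
        embed_te_in_cds(truth, gene.gene_id, te_copy, fam_id,
                        "boundary_spanning", orientation="-", inside_len=inside)
        ins = truth.insertions[-1]
        # site of the miR read on the transcript: rc coordinates of the window
        L = len(te_copy)
        site_start_g = ins.start + (L - e)
        site_end_g = ins.start + (L - s)
        cleavage_g = site_end_g - 10  # position opposite sRNA nt 10
        planted_sites.append((gene.gene_id, lid, cleavage_g - gene.start))

    # small RNA reads per locus
    srna_frames = []
    for idx, (lid, archetype) in enumerate(archetypes.items()):
        if archetype == "decoy":
            continue
        lseq = hairpins[lid]
        if archetype == "typical":
            spec = SrnaProfileSpec(
                strand_category="plus_only" if idx % 2 == 0 else "plus_major",
                excision="precise", mir_window=(s, e))
        elif archetype == "both_strand":
            spec = SrnaProfileSpec(strand_category="both", excision="precise",
                                   mir_window=(s, e))
        elif archetype == "high_copy":
            spec = SrnaProfileSpec(strand_category="both", excision="smeared",
                                   length_weights={24: 0.7, 21: 0.15, 22: 0.1, 20: 0.05})
        else:  # smeared
            spec = SrnaProfileSpec(strand_category="plus_major", excision="smeared",
                                   length_weights={24: 0.6, 21: 0.25, 23: 0.1, 22: 0.05})
        df = simulate_srna_reads(lseq, spec, sim.depth, sim.n_datasets,
                                 seed=_derive_seed(seed, 2000 + idx))
        srna_frames.append(df)
    srna_table = (
        pd.concat(srna_frames, ignore_index=True)
        .groupby(["sequence", "dataset_id"], as_index=False)["count"].sum()
        .sort_values(["sequence", "dataset_id"], ignore_index=True)
    )

    cds_set = {g.gene_id: truth.genome[g.chrom][g.cds[0]:g.cds[1]] for g in truth.genes}
    cdna_set = {g.gene_id: truth.genome[g.chrom][g.start:g.end] for g in truth.genes}
    annotations = {g.gene_id: g.description for g in truth.genes}

    # degradome tags: planted peak at the predicted slicing position of each
    # planted site, uniform low noise elsewhere; independent per dataset
    deg_rows = []
    for d in range(sim.degradome_datasets):
        ds = f"deg{d}"
        for j, (gene_id, _lid, pos) in enumerate(planted_sites):
            counts = simulate_degradome(
                cdna_set[gene_id], pos, sim.degradome_signal,
                sim.degradome_noise_positions, sim.degradome_noise_reads,
                seed=_derive_seed(seed, 3000 + 10 * d + j))
            for p, c in sorted(counts.items()):
                deg_rows.append({"cdna_id": gene_id, "dataset_id": ds,
                                 "position": p, "count": c})
    degradome_table = pd.DataFrame(deg_rows, columns=["cdna_id", "dataset_id", "position", "count"])

    return World(
        truth=truth, families=families, hairpins=hairpins, srna_table=srna_table,
        cds_set=cds_set, cdna_set=cdna_set, annotations=annotations,
        degradome_table=degradome_table, archetypes=archetypes,
        locus_mir_windows=locus_mir_windows,
    )


def write_world(world: World, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_fasta(world.truth.genome, out_dir / "genome.fa")
    write_fasta(
        [(f.family_id, f"te_class={f.te_class} tir_len={f.tir_len}", f.consensus)
         for f in world.families],
        out_dir / "repeats.fa")
    write_fasta(world.hairpins, out_dir / "hairpins.fa")
    write_fasta(world.cds_set, out_dir / "cds.fa")
    write_fasta(world.cdna_set, out_dir / "cdna.fa")
    write_srna_table(world.srna_table, out_dir / "srna.tsv")
    write_degradome_table(world.degradome_table, out_dir / "degradome.tsv")
    write_annotation_table(world.annotations, out_dir / "gene_annotations.tsv")
    features = []
    for g in world.truth.genes:
        features.append({"chrom": g.chrom, "type": "gene", "start": g.start,
                         "end": g.end, "strand": g.strand,
                         "attributes": {"ID": g.gene_id, "description": g.description.replace(";", ",")}})
        features.append({"chrom": g.chrom, "type": "CDS", "start": g.cds[0],
                         "end": g.cds[1], "strand": g.strand,
                         "attributes": {"Parent": g.gene_id,
                                        "te_overlaps_cds_boundary": str(g.te_overlaps_cds_boundary).lower()}})
    for i, ins in enumerate(world.truth.insertions):
        features.append({"chrom": ins.chrom, "type": "repeat_region", "start": ins.start,
                         "end": ins.end, "strand": ins.strand,
                         "attributes": {"ID": f"ins{i}", "family_id": ins.family_id}})
    for locus in world.truth.hairpin_loci:
        features.append({"chrom": locus.chrom, "type": "hairpin_locus", "start": locus.start,
                         "end": locus.end, "strand": "+",
                         "attributes": {"ID": locus.locus_id, "architecture": locus.architecture,
                                        "family_id": locus.family_id}})
    write_gff3(features, out_dir / "annotation.gff3")
    write_json(
        {
            "insertions": [asdict(i) for i in world.truth.insertions],
            "hairpin_loci": [asdict(h) for h in world.truth.hairpin_loci],
            "genes": [asdict(g) for g in world.truth.genes],
            "archetypes": world.archetypes,
        },
        out_dir / "truth.json")


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute enabled stages in dependency order and build the report."""
    th = config.thresholds
    report = RunReport(
        version=__version__, seed=config.seed,
        thresholds={f.name: getattr(th, f.name) for f in fields(th)},
    )
    if not config.stages.get("simulate", True):
        raise ValueError("the self-contained pipeline requires the simulate stage")
    log.info("stage simulate: seed=%d", config.seed)
    world = simulate_world(config.sim, config.seed)
    report.counts["n_hairpins"] = len(world.hairpins)
    report.counts["n_genes"] = len(world.truth.genes)
    report.counts["n_insertions"] = len(world.truth.insertions)
    log.info("simulated %d hairpins, %d genes", len(world.hairpins), len(world.truth.genes))

    repeat_lib = {f.family_id: (f.consensus, f.te_class) for f in world.families}
    te_mir_calls: dict = {}
    class_freq = pd.Series(dtype=object)
    if config.stages.get("homology", True):
        te_mir_calls, class_freq = find_te_mirs(world.hairpins, repeat_lib, e_max=th.e_temir)
        report.counts["n_te_mirs"] = len(te_mir_calls)
        report.tables["te_class_freq"] = class_freq.rename_axis("te_class").reset_index()
        log.info("stage homology: %d/%d hairpins are TE-MIRs at E<=%g",
                 len(te_mir_calls), len(world.hairpins), th.e_temir)

    profiles: dict = {}
    if config.stages.get("profile", True):
        reads = reads_from_table(world.srna_table)
        target_ids = te_mir_calls or world.hairpins
        for hid in target_ids:
            try:
                profiles[hid] = build_profile(
                    hid, reads, world.hairpins[hid], world.truth.genome,
                    minor_fraction=th.minor_fraction, usable_min=th.usable_min)
            except ValueError:
                continue  # no reads on this hairpin
        report.counts["n_profiled"] = len(profiles)
        strand_freq = pd.Series([p.strand_category for p in profiles.values()]).value_counts()
        report.tables["strand_freq"] = strand_freq.rename_axis("strand_category").reset_index(name="n")
        bins = [0, 1, 5, 20, 100, float("inf")]
        labels = ["1", "2-5", "6-20", "21-100", ">100"]
        hits = pd.Series([p.mean_genome_hits for p in profiles.values()])
        report.tables["hit_histogram"] = (
            pd.cut(hits, bins=bins, labels=labels).value_counts()
            .reindex(labels).rename_axis("mean_genome_hits").reset_index(name="n")
        )
        report.tables["length_spectra"] = (
            aggregate_length_spectrum(list(profiles.values()))
            .rename_axis("dataset_id").reset_index()
        )
        log.info("stage profile: %d hairpins profiled", len(profiles))

    screen_rows = []
    if config.stages.get("annotate", True):
        for hid, prof in profiles.items():
            structure = fold_hairpin(world.hairpins[hid])
            try:
                duplex = call_duplex(structure, prof.placements, hid,
                                     dominance_min=th.dominance_min,
                                     window_concentration_min=th.window_concentration_min)
            except ValueError:
                continue
            res = screen_typical(prof, duplex, hit_max=th.hit_max)
            arch, _ = detect_inverted_te_pair(world.hairpins[hid], world.families)
            screen_rows.append(
                {
                    "hairpin_id": hid,
                    "strand_category": prof.strand_category,
                    "mean_genome_hits": round(prof.mean_genome_hits, 2),
                    "length_type": prof.length_type,
                    "passes_hit": res.passes_hit,
                    "passes_strand": res.passes_strand,
                    "passes_excision": res.passes_excision,
                    "verdict": res.verdict,
                    "mir_seq": duplex.mir_read,
                    "star_seq": duplex.star_read or "",
                    "architecture": arch,
                }
            )
        typical_table = pd.DataFrame(
            screen_rows,
            columns=["hairpin_id", "strand_category", "mean_genome_hits", "length_type",
                     "passes_hit", "passes_strand", "passes_excision", "verdict",
                     "mir_seq", "star_seq", "architecture"])
        report.tables["typical_table"] = typical_table
        report.counts["n_typical"] = int((typical_table["verdict"] == "typical").sum())
        log.info("stage annotate: %d typical TE-MIRs", report.counts["n_typical"])

    predictions = []
    hsp_table = pd.DataFrame()
    if config.stages.get("predict", True):
        te_mir_seqs = {hid: world.hairpins[hid] for hid in (te_mir_calls or world.hairpins)}
        hsp_table, initial_targets = find_initial_targets(
            te_mir_seqs, world.cds_set, world.annotations,
            e_hsp=th.e_hsp, e_gene=th.e_gene)
        report.counts["n_hsps"] = len(hsp_table)
        report.counts["n_initial_targets"] = len(initial_targets)
        srna_records = []
        for hid, prof in profiles.items():
            seen = set()
            for p in prof.placements:
                if p.read.sequence in seen or p.read.total < 2:
                    continue
                seen.add(p.read.sequence)
                srna_records.append(SrnaRecord(p.read.sequence, hid, p.strand, p.read.total))
        target_cds = {r["gene_id"]: world.cds_set[r["gene_id"]]
                      for _, r in initial_targets.iterrows()}
        predictions = predict_targets(srna_records, target_cds,
                                      score_max=th.score_max, ratio_min=th.ratio_min)
        gene_classes = {g: classify_gene_annotation(world.annotations[g]) for g in world.cds_set}
        cells, class_summary = build_interaction_matrix(hsp_table, predictions, gene_classes)
        report.tables["interaction_matrix"] = cells
        report.tables["mtph_class_summary"] = class_summary
        report.tables["predictions"] = predictions_to_table(predictions)
        report.counts["n_predictions"] = len(predictions)
        report.counts["n_mtph"] = int(cells["mtph"].sum()) if len(cells) else 0
        log.info("stage predict: %d predictions, %d MTPH pairs",
                 len(predictions), report.counts["n_mtph"])

    if config.stages.get("degradome", True) and config.stages.get("predict", True):
        # predictions carry sites on the CDS; lift to cDNA coordinates
        lifted = []
        for p in predictions:
            gene = world.truth.gene(p.gene_id)
            offset = gene.cds[0] - gene.start
            aln = dc_replace(p.alignment, site_start=p.alignment.site_start + offset)
            lifted.append(TargetPrediction(p.srna, p.gene_id, p.site_start + offset,
                                           p.site_end + offset, aln))
        degradome_sets: dict[str, dict] = {}
        for ds, sub in world.degradome_table.groupby("dataset_id"):
            degradome_sets[str(ds)] = {
                str(gid): profile_from_counts(str(gid), dict(zip(g2["position"], g2["count"])))
                for gid, g2 in sub.groupby("cdna_id")
            }
        scores = score_targets(lifted, degradome_sets, score_max=th.score_max)
        report.tables["cleavage_scores"] = scores_to_table(scores)
        report.counts["n_scored_targets"] = len({s.gene_id for s in scores})
        log.info("stage degradome: %d target/dataset scores", len(scores))

    report.counts["n_world_reads"] = int(world.srna_table["count"].sum())
    report.world = world
    return report


def write_report(report: RunReport, out_dir: str | Path) -> list[Path]:
    """TSV per table plus one JSON summary; headers echo the thresholds."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = "# temir report; " + "; ".join(
        f"{k}={v:g}" for k, v in sorted(report.thresholds.items()))
    written = []
    for name, table in report.tables.items():
        path = out_dir / f"{name}.tsv"
        with open(path, "w") as fh:
            fh.write(header + "\n")
            table.to_csv(fh, sep="\t", index=False)
        written.append(path)
    summary_path = out_dir / "summary.json"
    write_json(
        {
            "version": report.version,
            "seed": report.seed,
            "thresholds": report.thresholds,
            "counts": report.counts,
            "tables": sorted(report.tables),
        },
        summary_path)
    written.append(summary_path)
    return written
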