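"""End-to-end orchestration: screen -> merge -> filter -> derep ->
chimera -> trim -> cluster -> floor -> clones -> taxonomy -> overlap ->
stats, from a single validated config, with stage logging and a hashed
output manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from ._seq import derive_seed
from .clustering import (
    OTU,
    cluster_otus,
    cocluster_clones,
    extract_its2,
    filter_low_abundance,
)
from .reads import (
    DerepSeq,
    ReadPair,
    dereplicate,
    detect_chimeras_denovo,
    filter_pool,
    merge_pool,
    screen_and_split,
)
from .stats import (
    alpha_diversity_table,
    class_composition,
    genus_nb_boxstats,
    rarefaction_curve,
    top_n_matrix,
)
from .synthetic import (
    MOTIF_3P,
    MOTIF_5P,
    PRIMERS,
    DivergenceSpec,
    build_reference_db,
    simulate_communities,
    simulate_reads,
)
from .taxonomy import (
    TaxonomyCall,
    build_hit_table,
    classify_overlap,
    consensus_assign,
    identity_class_percentages,
    overlap_percentages,
    percent,
    read_blast_tabular,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage-named pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All pipeline inputs and stage parameters, validated up front."""

    seed: int = 0
    # --- input: either a synthetic block or FASTQ/hit-table files
    simulate: dict | None = None
    fastq_fwd: str | None = None
    fastq_rev: str | None = None
    clone_fasta: str | None = None
    hit_table: str | None = None
    lineage_table: str | None = None
    sample_groups: dict[str, str] = field(default_factory=dict)
    # --- stage parameters
    max_primer_mismatch: int = 1
    min_overlap: int = 10
    max_overlap_mismatch_frac: float = 0.1
    min_len: int = 200
    max_ee: float = 1.0
    min_parent_fold: float = 2.0
    min_improvement: float = 0.02
    k_top_parents: int = 20
    min_chimera_identity: float = 0.99
    motif_5p: str = MOTIF_5P
    motif_3p: str = MOTIF_3P
    max_motif_mismatch: int = 1
    identity_threshold: float = 0.97
    floor_fraction: float = 0.00005
    n_consensus: int = 10
    n_recorded: int = 50

    def validate(self) -> None:
        checks = [
            (self.max_primer_mismatch >= 0, "max_primer_mismatch >= 0"),
            (self.min_overlap >= 10, "min_overlap >= 10"),
            (0 <= self.max_overlap_mismatch_frac <= 1, "overlap mismatch frac in [0,1]"),
            (self.min_len >= 0, "min_len >= 0"),
            (self.max_ee > 0, "max_ee > 0"),
            (self.min_parent_fold >= 1, "min_parent_fold >= 1"),
            (0 < self.identity_threshold <= 1, "identity threshold in (0,1]"),
            (0 <= self.floor_fraction <= 1, "floor_fraction in [0,1]"),
            (1 <= self.n_consensus <= self.n_recorded, "n_consensus <= n_recorded"),
        ]
        for ok, rule in checks:
            if not ok:
                raise PipelineError("config", f"violated: {rule}")
        if self.simulate is None and self.fastq_fwd is None:
            raise PipelineError("config", "need either a simulate block or FASTQ inputs")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError("config", f"unknown keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class RunResult:
    """All intermediates of one pipeline run, for in-memory inspection."""

    config: PipelineConfig
    stage_log: list[dict]
    otus: list[OTU]
    removed_otus: list[OTU]
    otu_table: pd.DataFrame
    calls: dict[str, TaxonomyCall]
    overlap_calls: list
    overlap_summary: dict
    composition: list
    alpha: pd.DataFrame
    clone_assignments: list[str] = field(default_factory=list)
    clone_only_clusters: dict = field(default_factory=dict)
    truth: list = field(default_factory=list)
    group_map: dict[str, str] = field(default_factory=dict)


def _log_stage(log: list[dict], stage: str, n_in: int, kept: int, discarded: int) -> None:
    if n_in != kept + discarded:
        raise PipelineError(stage, f"read conservation violated: {n_in} != {kept}+{discarded}")
    log.append({"stage": stage, "in": n_in, "kept": kept, "discarded": discarded})
    logger.info("stage %-10s in=%d kept=%d discarded=%d", stage, n_in, kept, discarded)


def _read_fastq_pairs(fwd_path: str, rev_path: str) -> list[ReadPair]:
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    pairs = []
    with open(fwd_path) as f1, open(rev_path) as f2:
        for (t1, s1, q1), (t2, s2, q2) in zip(
            FastqGeneralIterator(f1), FastqGeneralIterator(f2), strict=True
        ):
            rid = t1.split()[0]
            sample = "sample1"
            for token in t1.split():
                if token.startswith("sample="):
                    sample = token.removeprefix("sample=")
            pairs.append(ReadPair(rid, s1, s2, q1, q2, sample))
    return pairs


def _read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def run_pipeline_objects(
    config: PipelineConfig,
    pairs: list[ReadPair],
    references: list | None = None,
    clone_seqs: dict[str, str] | None = None,
    hit_tables: dict | None = None,
    group_map: dict[str, str] | None = None,
    truth: list | None = None,
) -> RunResult:
    """Run every stage on in-memory inputs.

    ``references`` is a list of synthetic ReferenceRecord used to build
    hit tables when no precomputed ``hit_tables`` are given.
    """
    config.validate()
    stage_log: list[dict] = []

    # --- screen & split ---------------------------------------------------
    buckets = screen_and_split(pairs, PRIMERS, config.max_primer_mismatch)
    n_discarded = len(buckets["discarded"])
    _log_stage(stage_log, "screen", len(pairs), len(pairs) - n_discarded, n_discarded)
    initial_per_group = {g: len(buckets[g]) for g in PRIMERS}

    # --- merge / filter / derep per amplicon pool -------------------------
    dereps_per_group: dict[str, list[DerepSeq]] = {}
    for group in PRIMERS:
        pool = buckets[group]
        merged, rejected = merge_pool(
            pool, group, config.min_overlap, config.max_overlap_mismatch_frac
        )
        _log_stage(stage_log, f"merge:{group}", len(pool), len(merged), len(rejected))
        kept, dropped = filter_pool(merged, config.min_len, config.max_ee)
        _log_stage(stage_log, f"filter:{group}", len(merged), len(kept), len(dropped))
        dereps = dereplicate(kept)
        flags = detect_chimeras_denovo(
            dereps, config.min_parent_fold, config.min_improvement,
            config.k_top_parents, config.min_chimera_identity
        )
        clean = [d for d, f in zip(dereps, flags) if not f]
        chim = [d for d, f in zip(dereps, flags) if f]
        _log_stage(
            stage_log,
            f"chimera:{group}",
            sum(d.abundance for d in dereps),
            sum(d.abundance for d in clean),
            sum(d.abundance for d in chim),
        )
        dereps_per_group[group] = clean

    # --- ITS2 trim, pool, re-dereplicate ----------------------------------
    trimmed: dict[str, DerepSeq] = {}
    n_in = n_rejected = 0
    for group, dereps in dereps_per_group.items():
        for derep in dereps:
            n_in += derep.abundance
            core, reason = extract_its2(
                derep.sequence, config.motif_5p, config.motif_3p, config.max_motif_mismatch
            )
            if core is None or not core:
                n_rejected += derep.abundance
                continue
            if core in trimmed:
                tgt = trimmed[core]
                tgt.abundance += derep.abundance
                tgt.member_ids.extend(derep.member_ids)
                for s, c in derep.sample_counts.items():
                    tgt.sample_counts[s] = tgt.sample_counts.get(s, 0) + c
            else:
                trimmed[core] = DerepSeq(
                    sequence=core,
                    abundance=derep.abundance,
                    member_ids=list(derep.member_ids),
                    sample_counts=dict(derep.sample_counts),
                    amplicon_group=group,
                )
    _log_stage(stage_log, "trim", n_in, n_in - n_rejected, n_rejected)
    pooled = sorted(trimmed.values(), key=lambda d: (-d.abundance, d.sequence))

    # --- cluster + abundance floor ----------------------------------------
    otus = cluster_otus(pooled, config.identity_threshold)
    reads_in_otus = sum(o.total_reads for o in otus)
    if reads_in_otus != n_in - n_rejected:
        raise PipelineError("cluster", "read conservation violated")
    kept_otus: list[OTU] = []
    removed_otus: list[OTU] = []
    for otu in otus:
        initial = initial_per_group.get(otu.amplicon_group, len(pairs))
        keep, drop = filter_low_abundance([otu], initial, config.floor_fraction)
        kept_otus.extend(keep)
        removed_otus.extend(drop)
    _log_stage(
        stage_log, "floor",
        reads_in_otus,
        sum(o.total_reads for o in kept_otus),
        sum(o.total_reads for o in removed_otus),
    )

    # --- clone co-clustering ----------------------------------------------
    clone_assignments: list[str] = []
    clone_only: dict = {}
    if clone_seqs:
        clone_assignments, clone_only = cocluster_clones(
            kept_otus, clone_seqs, config.identity_threshold
        )

    # --- OTU table ---------------------------------------------------------
    samples = sorted({s for o in kept_otus for s in o.sample_counts})
    otu_table = pd.DataFrame(
        [[o.sample_counts.get(s, 0) for s in samples] for o in kept_otus],
        index=[o.id for o in kept_otus],
        columns=samples,
        dtype=int,
    )

    # --- taxonomy ----------------------------------------------------------
    ref_tuples = None
    if hit_tables is None:
        if references is None:
            raise PipelineError("taxonomy", "need references or a precomputed hit table")
        ref_tuples = [
            (
                rec.id,
                rec.core,
                () if rec.mislabeled_as else rec.lineage,
                rec.mislabeled_as or rec.taxon.name,
            )
            for rec in references
        ]
    calls: dict[str, TaxonomyCall] = {}
    for otu in kept_otus:
        if hit_tables is not None:
            hits = hit_tables.get(otu.id, [])
        else:
            hits = build_hit_table(
                otu.id, otu.centroid, ref_tuples, n_recorded=config.n_recorded
            )
        calls[otu.id] = consensus_assign(
            hits, otu_id=otu.id,
            n_consensus=config.n_consensus, n_recorded=config.n_recorded,
        )

    # --- overlap + stats ----------------------------------------------------
    group_map = dict(group_map or config.sample_groups)
    if not group_map:
        group_map = {s: "groupA_north" for s in samples}
    overlap_calls, overlap_summary = classify_overlap(otu_table, calls, group_map)
    composition = class_composition(calls, otu_table)
    alpha = alpha_diversity_table(otu_table)

    return RunResult(
        config=config,
        stage_log=stage_log,
        otus=kept_otus,
        removed_otus=removed_otus,
        otu_table=otu_table,
        calls=calls,
        overlap_calls=overlap_calls,
        overlap_summary=overlap_summary,
        composition=composition,
        alpha=alpha,
        clone_assignments=clone_assignments,
        clone_only_clusters=clone_only,
        truth=truth or [],
        group_map=group_map,
    )


def _simulate_inputs(config: PipelineConfig):
    params = dict(config.simulate or {})
    db_keys = {
        "n_genera_per_class", "n_species_per_genus", "n_genotypes_per_species",
        "classes", "core_length_range", "core_length_mean", "core_length_sd",
        "mislabeled_fraction",
    }
    community_keys = {
        "n_sites_per_group", "shared_fraction", "reads_per_site",
        "lognormal_sigma", "group_b_pool_fraction",
    }
    read_keys = {
        "error_rate", "chimera_rate", "offtarget_fraction", "read_len",
        "min_merge_span",
    }
    divergence = params.pop("divergence", None)
    spec = DivergenceSpec(**divergence) if divergence else DivergenceSpec()
    unknown = set(params) - db_keys - community_keys - read_keys
    if unknown:
        raise PipelineError("config", f"unknown simulate keys: {sorted(unknown)}")
    refdb = build_reference_db(
        divergence_spec=spec,
        seed=derive_seed(config.seed, "refdb"),
        **{k: v for k, v in params.items() if k in db_keys},
    )
    profiles = simulate_communities(
        refdb,
        seed=derive_seed(config.seed, "communities"),
        **{k: v for k, v in params.items() if k in community_keys},
    )
    run = simulate_reads(
        profiles,
        refdb,
        seed=derive_seed(config.seed, "reads"),
        **{k: v for k, v in params.items() if k in read_keys},
    )
    group_map = {p.site: p.group for p in profiles}
    return refdb, profiles, run, group_map


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run from a config, write all outputs, and return the manifest."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    truth = None
    references = None
    if config.simulate is not None:
        references, _, run, group_map = _simulate_inputs(config)
        pairs = run.pairs
        truth = run.truth
    else:
        pairs = _read_fastq_pairs(config.fastq_fwd, config.fastq_rev)
        group_map = dict(config.sample_groups)

    clone_seqs = _read_fasta(config.clone_fasta) if config.clone_fasta else None
    hit_tables = None
    if config.hit_table:
        lineage_map = None
        if config.lineage_table:
            df = pd.read_csv(config.lineage_table, sep="\t", dtype=str)
            lineage_map = {
                r["id"]: tuple(r[c] for c in ("class", "order", "genus", "species", "genotype"))
                for _, r in df.iterrows()
            }
        hit_tables = read_blast_tabular(config.hit_table, lineage_map)

    result = run_pipeline_objects(
        config, pairs,
        references=references, clone_seqs=clone_seqs,
        hit_tables=hit_tables, group_map=group_map, truth=truth,
    )
    manifest = write_outputs(result, out)
    return manifest


def write_outputs(result: RunResult, out: Path) -> dict:
    out.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(result.stage_log).to_csv(out / "processing_log.tsv", sep="\t", index=False)

    with open(out / "centroids.fasta", "w") as fh:
        for otu in result.otus:
            fh.write(f">{otu.id};size={otu.total_reads}\n{otu.centroid}\n")

    result.otu_table.rename_axis("otu_id").to_csv(out / "otu_table.tsv", sep="\t")

    with open(out / "membership.tsv", "w") as fh:
        fh.write("otu_id\tmember_abundance\tidentity\n")
        for otu in result.otus:
            for derep, identity in otu.members:
                fh.write(f"{otu.id}\t{derep.abundance}\t{identity:.4f}\n")

    with open(out / "taxonomy.tsv", "w") as fh:
        fh.write("otu_id\tlabel\tassigned_rank\tbest_nb\tidentity_class\tis_target\tclass\thas_clone_member\n")
        mixed = {o.id for o in result.otus if o.has_clone_member}
        for otu_id in result.otu_table.index:
            c = result.calls[otu_id]
            fh.write(
                f"{otu_id}\t{c.label}\t{c.assigned_rank or ''}\t{c.best_nb:.4f}"
                f"\t{c.identity_class}\t{int(c.is_target)}\t{c.lineage_class or ''}"
                f"\t{int(otu_id in mixed)}\n"
            )

    with open(out / "overlap.tsv", "w") as fh:
        fh.write("otu_id\tpresence\tshared_breakdown\n")
        for oc in result.overlap_calls:
            fh.write(f"{oc.otu_id}\t{oc.presence}\t{oc.shared_breakdown}\n")

    if result.clone_assignments:
        with open(out / "clone_assignments.tsv", "w") as fh:
            fh.write("clone_id\totu_id\tidentity\n")
            for line in result.clone_assignments:
                fh.write(line + "\n")

    comp_rows = []
    for row in result.composition:
        comp_rows.append(
            {
                "sample": row.sample,
                "algal_total": row.algal_total,
                "nonalgal_total": row.nonalgal_total,
                **{f"n_{k}": v for k, v in row.class_counts.items()},
                **{f"pct_{k}": v for k, v in row.percentages.items()},
            }
        )
    pd.DataFrame(comp_rows).to_csv(out / "composition.tsv", sep="\t", index=False)

    result.alpha.rename_axis("sample").to_csv(out / "alpha.tsv", sep="\t")

    rare_rows = []
    rare_seed = derive_seed(result.config.seed, "rarefaction")
    for sample in result.otu_table.columns:
        counts = result.otu_table[sample].to_numpy()
        total = int(counts.sum())
        if total == 0:
            continue
        depths = sorted({max(1, total // 10), total // 4, total // 2, total})
        curve = rarefaction_curve(counts, depths, n_reps=10, seed=rare_seed)
        curve.insert(0, "sample", sample)
        rare_rows.append(curve)
    if rare_rows:
        pd.concat(rare_rows).to_csv(out / "rarefaction.tsv", sep="\t", index=False)

    mixed_ids = {o.id for o in result.otus if o.has_clone_member}
    box = genus_nb_boxstats(list(result.calls.values()), mixed_ids)
    pd.DataFrame([dataclasses.asdict(b) for b in box]).to_csv(
        out / "nb_boxstats.tsv", sep="\t", index=False
    )

    top = top_n_matrix(result.otu_table, result.calls, group_map=result.group_map)
    frames = []
    for cls, matrix in top.items():
        m = matrix.copy()
        m.insert(0, "class", cls)
        frames.append(m.rename_axis("otu_id").reset_index())
    if frames:
        pd.concat(frames).to_csv(out / "top_otus.tsv", sep="\t", index=False)

    with open(out / "venn.json", "w") as fh:
        json.dump(
            {
                k: v
                for k, v in result.overlap_summary.items()
                if k != "per_class_overlap"
            }
            | {"per_class_overlap": result.overlap_summary["per_class_overlap"]},
            fh, indent=2, sort_keys=True,
        )

    summary = summarize_result(result)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(result.config), fh, sort_keys=True)

    manifest = {
        "version": __version__,
        "seed": result.config.seed,
        "stage_log": result.stage_log,
        "outputs": {},
    }
    for path in sorted(out.glob("*")):
        if path.name == "manifest.json":
            continue
        manifest["outputs"][path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def summarize_result(result: RunResult) -> dict:
    """Headline numbers, all recomputable from the written TSVs."""
    calls = list(result.calls.values())
    n_total = len(calls)
    algal = [c for c in calls if c.is_target]
    class_counts = Counter(c.lineage_class for c in algal)
    mixed = sum(1 for o in result.otus if o.has_clone_member)
    summary = {
        "n_otus_total": n_total,
        "n_otus_algal": len(algal),
        "algal_pct": percent(len(algal), n_total),
        "class_counts": dict(sorted(class_counts.items())),
        "class_pct": {
            k: percent(v, len(algal)) for k, v in sorted(class_counts.items())
        },
        "identity_classes": identity_class_percentages(calls),
        "overlap": {
            k: v for k, v in result.overlap_summary.items() if k != "per_class_overlap"
        },
        "overlap_pct": overlap_percentages(result.overlap_summary),
        "n_mixed_otus": mixed,
        "mixed_pct": percent(mixed, len(algal)),
    }
    return summary


def summarize_run(out_dir) -> dict:
    """Recompute the headline JSON from the TSVs of a finished run."""
    out = Path(out_dir)
    required = ["taxonomy.tsv", "otu_table.tsv", "overlap.tsv"]
    for name in required:
        if not (out / name).exists():
            raise PipelineError("summarize", f"incomplete manifest: missing {name}")
    tax = pd.read_csv(out / "taxonomy.tsv", sep="\t")
    overlap = pd.read_csv(out / "overlap.tsv", sep="\t")
    n_total = len(tax)
    algal = tax[tax["is_target"] == 1]
    class_counts = algal["class"].value_counts().to_dict()
    shared = overlap[overlap["presence"] == "shared"]
    n_genotype = int((algal["identity_class"] == "genotype").sum())
    n_species = int((algal["identity_class"] == "species").sum())
    mixed = int(tax["has_clone_member"].sum())
    return {
        "n_otus_total": n_total,
        "n_otus_algal": len(algal),
        "algal_pct": percent(len(algal), n_total),
        "class_counts": dict(sorted(class_counts.items())),
        "class_pct": {
            k: percent(v, len(algal)) for k, v in sorted(class_counts.items())
        },
        "identity_classes": {
            "n_algal": len(algal),
            "genotype_pct": percent(n_genotype, len(algal)),
            "species_pct": percent(n_species, len(algal)),
            "unambiguous_pct": percent(n_genotype + n_species, len(algal)),
        },
        "overlap": {
            "shared": len(shared),
            "groupA_total": int((overlap["presence"] != "groupB_only").sum()),
            "groupB_total": int((overlap["presence"] != "groupA_only").sum()),
        },
        "n_mixed_otus": mixed,
        "mixed_pct": percent(mixed, len(algal)),
    }
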