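"""End-to-end pipeline: reference -> catalog -> quantify -> cohort -> enrich -> targets.

``run_pipeline`` executes the stages in order into a run directory and
writes a manifest (parameters, seeds, per-stage timing and record counts,
sha256 checksum of every output).  Re-running the same configuration
reproduces byte-identical tables.  A stage failure halts the run with the
stage name and an error code; earlier outputs stay on disk next to a
``FAILED`` marker.

``demo_config`` materializes a fully synthetic input bundle (genome,
annotation, fragment table, FASTQ per sample, cohort annotation, mRNA
matrix, GMT, UTR FASTA) and is what the bundled examples and the CLI's
``simulate`` command use.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import catalog as cat
from . import cohort as coh
from . import enrichment as enr
from . import quantify as qnt
from . import reference as ref
from . import simulate as sim
from . import targets as tgt

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "StageError", "run_pipeline", "demo_config", "write_demo_inputs"]

STAGES = ("reference", "catalog", "quantify", "cohort", "enrich", "targets")


class StageError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    annotation_path: str
    genome_path: str
    fragment_table_path: str
    fastq_paths: dict[str, str]  # sample_id -> path
    cohort_annotation_path: str
    mrna_path: str
    gmt_path: str
    utr_path: str
    out_dir: str
    seed: int = 0
    threshold_log2: float = 1.0
    leader_len: int = 20
    trailer_len: int = 30
    top_n_targets: int = 50
    n_perm: int = 500
    landmark_table_path: str | None = None
    index_fragment: str | None = None  # fragment for median-split survival
    stages: tuple[str, ...] = STAGES

    def validate(self) -> None:
        if not (0 <= self.threshold_log2 <= 20):
            raise ValueError("threshold_log2 outside [0, 20]")
        if self.trailer_len < 1 or self.leader_len < 0:
            raise ValueError("invalid flank lengths")
        paths = [self.annotation_path, self.genome_path, self.fragment_table_path,
                 self.cohort_annotation_path, self.mrna_path, self.gmt_path,
                 self.utr_path, *self.fastq_paths.values()]
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all configured stages; returns the manifest dict."""
    try:
        config.validate()
    except FileNotFoundError as e:
        raise StageError("config", "missing_input", str(e)) from e
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": {k: v for k, v in asdict(config).items()},
        "stages": {},
        "outputs": {},
    }
    state: dict = {}

    def record(stage: str, t0: float, counts: dict, files: list[Path]) -> None:
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 3), "counts": counts,
        }
        for f in files:
            manifest["outputs"][f.name] = _sha256(f)

    try:
        for stage in config.stages:
            t0 = time.time()
            if stage == "reference":
                genes = ref.load_trna_annotation(config.annotation_path, config.genome_path)
                landmarks = (ref.load_landmark_table(config.landmark_table_path)
                             if config.landmark_table_path else None)
                state["models"] = cat.build_reference_models(
                    genes, config.genome_path,
                    leader_len=config.leader_len, trailer_len=config.trailer_len,
                    landmark_table=landmarks,
                )
                record(stage, t0, {"genes": len(genes)}, [])
            elif stage == "catalog":
                records = cat.load_fragment_table(config.fragment_table_path)
                cat.classify_catalog(records, state["models"])
                state["catalog"] = records
                path = out / "catalog.tsv"
                cat.write_catalog(records, path)
                summary = cat.summarize_catalog(records)
                spath = out / "catalog_summary.tsv"
                pd.concat(
                    {k: v for k, v in summary.items()}, names=["partition", "key"]
                ).rename("proportion").to_frame().to_csv(spath, sep="\t")
                record(stage, t0, {"fragments": len(records)}, [path, spath])
            elif stage == "quantify":
                assignments = {}
                stats = {}
                for sample, fq in sorted(config.fastq_paths.items()):
                    if not Path(fq).exists():
                        raise StageError("quantify", "missing_fastq", fq)
                    a, skipped = qnt.assign_reads(fq, state["catalog"])
                    assignments[sample] = a
                    stats[sample] = {
                        "reads": len(a), "skipped": skipped,
                        "unique": sum(x.status == "unique" for x in a),
                        "ambiguous": sum(x.status == "ambiguous" for x in a),
                        "unmapped": sum(x.status == "unmapped" for x in a),
                    }
                counts = qnt.count_fragments(assignments, state["catalog"])
                rpm = qnt.rpm_normalize(counts)
                filtered = qnt.abundance_filter(rpm, config.threshold_log2)
                state["rpm"] = filtered
                cpath = out / "counts.tsv"
                rpath = out / "rpm_filtered.tsv"
                counts.data.to_csv(cpath, sep="\t")
                filtered.data.to_csv(rpath, sep="\t")
                report = {
                    "per_sample": stats,
                    "rpm_denominator": "uniquely assigned reads",
                    "filter_threshold_log2": config.threshold_log2,
                    "fragments_removed": filtered.removed_fragments,
                }
                jpath = out / "quantify_report.json"
                jpath.write_text(json.dumps(report, indent=2, sort_keys=True))
                record(stage, t0,
                       {"fragments_kept": filtered.data.shape[0],
                        "fragments_removed": len(filtered.removed_fragments)},
                       [cpath, rpath, jpath])
            elif stage == "cohort":
                ann = coh.load_cohort_annotation(config.cohort_annotation_path)
                rpm = state["rpm"]
                de = coh.differential_expression(rpm, ann)
                de_path = out / "differential_expression.tsv"
                de.to_csv(de_path, sep="\t")
                files = [de_path]
                idx_frag = config.index_fragment or (
                    de.sort_values("p_value").index[0] if len(de) else None)
                surv_info: dict = {}
                if idx_frag is not None and idx_frag in rpm.data.index and "survival_time" in ann.columns:
                    tumor = ann[ann["group"] == "tumor"].dropna(subset=["survival_time"])
                    expr = rpm.data.loc[idx_frag, [s for s in tumor.index if s in rpm.data.columns]]
                    labels = coh.median_split(expr)
                    res = coh.km_logrank(
                        tumor.loc[labels.index, "survival_time"],
                        tumor.loc[labels.index, "event"], labels)
                    km_rows = []
                    for gname, curve in res["curves"].items():
                        curve = curve.assign(group=gname)
                        km_rows.append(curve)
                    km_path = out / "km_curves.tsv"
                    pd.concat(km_rows).to_csv(km_path, sep="\t", index=False)
                    files.append(km_path)
                    surv_info = {"fragment": idx_frag,
                                 "logrank_statistic": res["statistic"],
                                 "logrank_p": res["p_value"]}
                    chi_rows = []
                    for feat in ann.columns:
                        if feat in ("group", "survival_time", "event", "expr_group_truth"):
                            continue
                        try:
                            c = coh.chisq_association(labels, tumor.loc[labels.index, feat])
                        except ValueError:
                            continue
                        chi_rows.append({"feature": feat, "statistic": c["statistic"],
                                         "df": c["df"], "p_value": c["p_value"]})
                    if chi_rows:
                        chi_path = out / "feature_association.tsv"
                        pd.DataFrame(chi_rows).to_csv(chi_path, sep="\t", index=False)
                        files.append(chi_path)
                    state["index_fragment"] = idx_frag
                    state["annotation"] = ann
                spath = out / "survival_summary.json"
                spath.write_text(json.dumps(surv_info, indent=2, default=float))
                files.append(spath)
                cluster = coh.hierarchical_cluster(np.log2(rpm.data + 1)) if len(rpm.data) > 1 else None
                if cluster:
                    cl_path = out / "cluster.json"
                    cl_path.write_text(json.dumps(
                        {"leaf_order": cluster["leaf_order"],
                         "merges": [[int(a), int(b), float(h), int(s)]
                                    for a, b, h, s in cluster["merges"]]}, indent=2))
                    files.append(cl_path)
                state["de"] = de
                record(stage, t0, {"fragments_tested": len(de)}, files)
            elif stage == "enrich":
                mrna = pd.read_csv(config.mrna_path, sep="\t", index_col=0)
                rpm = state["rpm"]
                idx_frag = state.get("index_fragment") or rpm.data.index[0]
                frag_log = np.log2(rpm.data.loc[idx_frag] + 1)
                corr = coh.correlate_with_mrna(frag_log, mrna, method="spearman")
                corr_path = out / "correlated_mrnas.tsv"
                corr.to_csv(corr_path, sep="\t")
                ranked = enr.as_ranked_list(corr["effect"].dropna())
                sets = enr.read_gmt(config.gmt_path)
                universe = list(mrna.index)
                hits = list(corr.index[(corr["q_value"] < 0.25) & corr["effect"].gt(0)])
                files = [corr_path]
                if hits:
                    ora = enr.ora_table(hits, sets, universe)
                    opath = out / "ora.tsv"
                    ora.to_csv(opath, sep="\t")
                    files.append(opath)
                gsea = enr.gsea_table(ranked, sets, n_perm=config.n_perm, seed=config.seed)
                gpath = out / "gsea.tsv"
                gsea.to_csv(gpath, sep="\t")
                files.append(gpath)
                record(stage, t0, {"gene_sets": len(sets), "hits": len(hits)}, files)
            elif stage == "targets":
                utrs = {r.id: str(r.seq) for r in SeqIO.parse(config.utr_path, "fasta")}
                frags = {r.fragment_id: r.sequence for r in state["catalog"]
                         if r.fragment_id in state["rpm"].data.index}
                edges = tgt.rank_targets(frags, utrs, top_n=config.top_n_targets)
                epath = out / "target_edges.tsv"
                edges.to_csv(epath, sep="\t", index=False)
                npath = out / "target_network.json"
                npath.write_text(json.dumps(tgt.edges_to_network_json(edges), indent=2))
                record(stage, t0, {"edges": len(edges)}, [epath, npath])
            else:
                raise StageError(stage, "unknown_stage", stage)
    except StageError:
        (out / "FAILED").write_text(stage)
        raise
    except Exception as e:
        (out / "FAILED").write_text(stage)
        raise StageError(stage, "internal", str(e)) from e

    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest


def write_demo_inputs(data_dir, config: sim.SimulationConfig | None = None) -> PipelineConfig:
    """Materialize a synthetic input bundle and return a ready PipelineConfig."""
    cfg = config or sim.SimulationConfig()
    data_dir = Path(data_dir)
    data_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    genes, genome, gene_truth = sim.simulate_trna_genes(cfg.n_genes, seed=cfg.seed)
    sim.write_genome_fasta(genome, data_dir / "genome.fa")
    sim.write_annotation_bed(genes, data_dir / "trna_genes.bed")
    models = cat.build_reference_models(
        genes, genome, leader_len=cfg.leader_len, trailer_len=cfg.trailer_len)
    records, frag_truth = sim.simulate_catalog(
        models, cfg.type_mixture, cfg.n_fragments, seed=cfg.seed)
    pd.DataFrame(
        {"fragment_id": [r.fragment_id for r in records],
         "sequence": [r.sequence for r in records]}
    ).to_csv(data_dir / "fragments.tsv", sep="\t", index=False)
    frag_truth.to_csv(data_dir / "fragments_truth.tsv", sep="\t")

    # planted fragments must be tRF-3 (mirrors the down-regulated tRF-3 pair)
    trf3_ids = list(frag_truth.index[frag_truth["true_type"] == "tRF-3"])
    planted = trf3_ids[: cfg.n_planted]
    ordered_ids = planted + [r.fragment_id for r in records if r.fragment_id not in planted]
    cohort = sim.simulate_cohort(
        ordered_ids, cfg,
        planted_correlations={"GENE0001": (planted[0], 0.6)} if planted else None,
    )
    fastq_paths = {}
    seq_of = {r.fragment_id: r.sequence for r in records}
    for sample in cohort["counts"].columns:
        abundances = cohort["counts"][sample].to_dict()
        reads, _ = sim.simulate_reads(
            records, abundances, cfg.reads_per_sample,
            seed=int(rng.integers(2**31)), decoy_fraction=cfg.decoy_fraction)
        fq = data_dir / f"{sample}.fastq"
        sim.write_fastq(reads, fq)
        fastq_paths[sample] = str(fq)
    cohort["annotation"].to_csv(data_dir / "cohort.tsv", sep="\t")
    cohort["mrna"].to_csv(data_dir / "mrna.tsv", sep="\t")
    with open(data_dir / "sets.gmt", "w") as fh:
        for gs in sim.simulate_gene_sets(list(cohort["mrna"].index), seed=cfg.seed):
            fh.write(f"{gs.name}\t{gs.description}\t" + "\t".join(sorted(gs.members)) + "\n")
    utrs, utr_truth = sim.simulate_utrs(
        {f: seq_of[f] for f in planted} if planted else
        {records[0].fragment_id: records[0].sequence},
        n_targets=60, planted_sites=10, seed=cfg.seed)
    with open(data_dir / "utrs.fa", "w") as fh:
        for tid, seq in utrs.items():
            fh.write(f">{tid}\n{seq}\n")
    utr_truth.to_csv(data_dir / "utrs_truth.tsv", sep="\t", index=False)
    with open(data_dir / "cohort_truth.json", "w") as fh:
        json.dump(cohort["truth"], fh, indent=2, default=str)

    return PipelineConfig(
        annotation_path=str(data_dir / "trna_genes.bed"),
        genome_path=str(data_dir / "genome.fa"),
        fragment_table_path=str(data_dir / "fragments.tsv"),
        fastq_paths=fastq_paths,
        cohort_annotation_path=str(data_dir / "cohort.tsv"),
        mrna_path=str(data_dir / "mrna.tsv"),
        gmt_path=str(data_dir / "sets.gmt"),
        utr_path=str(data_dir / "utrs.fa"),
        out_dir=str(data_dir / "run"),
        seed=cfg.seed,
        leader_len=cfg.leader_len,
        trailer_len=cfg.trailer_len,
        index_fragment=planted[0] if planted else None,
    )


def demo_config(base_dir, seed: int = 0, **overrides) -> PipelineConfig:
    """Synthetic demo inputs under ``base_dir`` with the default study structure."""
    cfg = sim.SimulationConfig(seed=seed, **overrides)
    return write_demo_inputs(Path(base_dir) / "data", cfg)
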