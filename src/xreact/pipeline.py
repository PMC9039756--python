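"""End-to-end orchestration: simulate -> classify -> features -> tads ->
methylation -> overlap, with a YAML-configurable parameter set and an output
manifest of content hashes."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as cls_mod
from . import features as feat_mod
from . import methylation as meth_mod
from . import overlap as ovl_mod
from . import tads as tad_mod
from .core import read_bedgraph, read_gene_table, read_tads, repeats_from_bed, read_bed
from .simulate import TRACK_NAMES, BODY_TRACK, SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every stage parameter with its default; a fully-defaulted run is valid."""

    out_dir: str = "xreact_out"
    seed: int = 1
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    # classification
    min_allelic_reads: float = 10.0
    escape_ratio_threshold: float = 0.10
    alpha: float = 0.05
    control_condition: str = "control"
    treated_condition: str = "tomato_high"
    test_method: str = "betabinom"

    # features
    cpg_window_bp: int = 2000
    repeat_window_bp: int = 100_000
    profile_flank_bp: int = 3000

    # methylation
    promoter_flank_bp: int = 1000
    meth_alpha: float = 0.05

    # overlap
    external_lists: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("simulation", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if sim_raw:
            sim_known = {f.name for f in dataclasses.fields(SimulationConfig)}
            bad = set(sim_raw) - sim_known
            if bad:
                raise ValueError(f"unknown simulation keys: {sorted(bad)}")
            for k in ("cast_fraction_escapee_range", "cast_fraction_reactivated_high",
                      "cast_fraction_reactivated_regular", "cast_fraction_strong",
                      "conditions"):
                if k in sim_raw and isinstance(sim_raw[k], list):
                    sim_raw[k] = tuple(sim_raw[k])
            cfg.simulation = SimulationConfig(**sim_raw)
        return cfg

    def validate(self) -> None:
        if self.alpha <= 0 or self.alpha >= 1:
            raise ValueError("alpha must lie in (0, 1)")
        for p in self.external_lists:
            if not Path(p).exists():
                raise FileNotFoundError(f"external list not found: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: PipelineConfig, dry_run: bool = False) -> dict:
    """Run every stage on a fresh synthetic bundle; returns the manifest.

    Deterministic for a fixed config + seed. On stage failure the partial
    manifest written so far is retained under out_dir/manifest.json.
    """
    config.validate()
    sim = dataclasses.replace(config.simulation, seed=config.seed)
    if dry_run:
        logger.info("dry run: configuration valid; no files written")
        return {"dry_run": True, "outputs": {}}

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"outputs": {}, "parameters": _params_dict(config)}
    manifest_path = out / "manifest.json"

    def record(*paths):
        for p in paths:
            manifest["outputs"][Path(p).name] = _sha256(Path(p))
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))

    try:
        logger.info("stage simulate (seed %d)", config.seed)
        bundle, truth = simulate_dataset(sim, out / "bundle")
        record(*bundle.values())

        logger.info("stage classify")
        genes = read_gene_table(bundle["genes"])
        table = cls_mod.load_count_table(bundle["counts"])
        classes = cls_mod.classify_genes(
            table,
            [g.gene_id for g in genes],
            min_allelic_reads=config.min_allelic_reads,
            escape_ratio_threshold=config.escape_ratio_threshold,
            treated_condition=config.treated_condition,
            control_condition=config.control_condition,
            alpha=config.alpha,
            method=config.test_method,
        )
        classes_path = out / "classifications.tsv"
        classes.to_csv(classes_path, sep="\t", index=False)
        gene_pos = pd.DataFrame(
            {"gene_id": [g.gene_id for g in genes], "tss": [g.tss for g in genes]}
        )
        informative = set(classes.loc[classes["status"] != "uninformative", "gene_id"])
        profile = cls_mod.delta_ratio_profile(
            table, gene_pos, informative,
            config.treated_condition, config.control_condition,
        )
        profile_path = out / "delta_ratio.tsv"
        profile.to_csv(profile_path, sep="\t", index=False)
        record(classes_path, profile_path)

        logger.info("stage features")
        cpg_starts = np.array(
            [r["interval"].start for r in read_bed(bundle["cpg"])], dtype=np.int64
        )
        repeats = repeats_from_bed(bundle["repeats"])
        name_by_id = {g.gene_id: g.name for g in genes}
        xist_tss = next((g.tss for g in genes if g.name == "Xist"), None)
        escapee_ids = set(classes.loc[classes["status"] == "escapee", "gene_id"])
        tracks = {
            name: read_bedgraph(bundle[f"track_{name}"])
            for name in (*TRACK_NAMES, BODY_TRACK)
            if f"track_{name}" in bundle
        }
        features = feat_mod.build_feature_table(
            genes, cpg_starts, repeats, escapee_ids, xist_tss, tracks,
            cpg_window_bp=config.cpg_window_bp,
            repeat_window_bp=config.repeat_window_bp,
            profile_flank_bp=config.profile_flank_bp,
        )
        features_path = out / "features.tsv"
        features.to_csv(features_path, sep="\t", index=False)
        comparisons = feat_mod.compare_classes(features, classes)
        comp_path = out / "feature_comparisons.tsv"
        feat_mod.comparisons_frame(comparisons).to_csv(comp_path, sep="\t", index=False)

        class_gene_lists = {
            st: [g for g in genes if classes.set_index("gene_id")["status"].get(g.gene_id) == st]
            for st in ("escapee", "reactivated", "non_reactivated")
        }
        prof_rows = []
        for name, track in tracks.items():
            mode = "scaled_body" if name == BODY_TRACK else "tss"
            for st, gl in class_gene_lists.items():
                gl = [g for g in gl if g.name != "Xist"] if st == "escapee" else gl
                if not gl:
                    continue
                vec = feat_mod.metagene_profile(
                    gl, track, mode=mode, flank_bp=config.profile_flank_bp
                )
                for i, v in enumerate(vec):
                    prof_rows.append((name, st, i, v))
        prof_path = out / "metagene_profiles.tsv"
        pd.DataFrame(
            prof_rows, columns=["track", "status", "bin", "mean_signal"]
        ).to_csv(prof_path, sep="\t", index=False)
        record(features_path, comp_path, prof_path)

        logger.info("stage tads")
        tadset = read_tads(bundle["tads"])
        tad_ids = [r.get("name", f"TAD{i+1:03d}") for i, r in
                   enumerate(read_bed(bundle["tads"]))]
        tad_records = tad_mod.run_tad_enrichment(
            classes, genes, tadset, alpha=config.alpha, tad_ids=tad_ids
        )
        tads_path = out / "tads.tsv"
        tad_records.to_csv(tads_path, sep="\t", index=False)
        tadbg_path = out / "tad_signed_p.bedgraph"
        tad_mod.write_signed_p_bedgraph(tad_records, tadbg_path)
        tad_summary, tad_comps = tad_mod.tad_feature_summary(
            tad_records, repeats, cpg_starts, tracks
        )
        tadsum_path = out / "tad_feature_summary.tsv"
        tad_summary.to_csv(tadsum_path, sep="\t", index=False)
        tadcomp_path = out / "tad_feature_comparisons.tsv"
        feat_mod.comparisons_frame(tad_comps).to_csv(tadcomp_path, sep="\t", index=False)
        record(tads_path, tadbg_path, tadsum_path, tadcomp_path)

        logger.info("stage methylation")
        meth = meth_mod.load_methylation(bundle["methylation"])
        diff = meth_mod.differential_methylation(
            meth, config.control_condition, config.treated_condition,
            alpha=config.meth_alpha,
        )
        diff_path = out / "differential_methylation.tsv"
        diff.to_csv(diff_path, sep="\t", index=False)

        prom = meth[meth["region_id"].str.startswith("prom_")].copy()
        prom["gene_id"] = prom["region_id"].str.removeprefix("prom_")
        female = prom[prom["condition"] != "male_xa"]
        rates = meth_mod.normalize_methylation(female)
        cluster = meth_mod.cluster_promoters(rates, classes, seed=config.seed)
        cluster_path = out / "promoter_cluster.json"
        cluster_path.write_text(
            json.dumps(
                {k: cluster[k] for k in ("purity", "permutation_p")}, indent=2
            )
        )
        # baseline samples only: flank methylation is a property of the
        # untreated landscape, independent of the induced promoter changes
        baseline = meth[meth["condition"] == config.control_condition]
        flank_comps = meth_mod.repeat_flank_methylation(
            repeats, baseline, classes, genes, flank_bp=config.promoter_flank_bp
        )
        flank_path = out / "repeat_flank_comparisons.tsv"
        feat_mod.comparisons_frame(flank_comps).to_csv(flank_path, sep="\t", index=False)
        record(diff_path, cluster_path, flank_path)

        logger.info("stage overlap")
        by_status = classes.groupby("status")["gene_id"].apply(list).to_dict()
        class_lists = {
            st: ovl_mod.GeneList.from_symbols(
                st, [name_by_id[g] for g in by_status.get(st, [])]
            )
            for st in ("escapee", "reactivated")
            if by_status.get(st)
        }
        if config.external_lists:
            ext = [ovl_mod.GeneList.from_file(p) for p in config.external_lists]
        else:
            # no external lists supplied: report the classes against each other
            ext = [v for v in class_lists.values()]
        report = ovl_mod.multi_overlap_report(class_lists, ext)
        ovl_path = out / "overlap_report.tsv"
        report.to_csv(ovl_path, sep="\t", index=False)
        record(ovl_path)
    except Exception:
        logger.exception("pipeline stage failed; partial manifest retained")
        raise
    logger.info("pipeline complete: %d outputs", len(manifest["outputs"]))
    return manifest


def _params_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    return json.loads(json.dumps(d, default=str))
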