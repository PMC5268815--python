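"""End-to-end orchestration: QC -> segmentation -> DM -> enrichment -> DM-DE.

A single declarative config (YAML or dict) names every input path and every
threshold; :func:`run_all` executes the stages in order, writes one table
per output, and stamps a machine-readable run manifest with the config
hash, input checksums and the thresholds actually used.  Deterministic
stages rerun bit-identically under the same config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import clone_bisulfite, data_io, dm_de, dm_testing, enrichment, qc_filter, qpcr, segmentation


@dataclass
class PipelineConfig:
    """Input paths and every numeric threshold of the workflow."""

    beta: str = ""
    detection_p: str | None = None
    samples: str = ""
    manifest: str = ""
    chromatin_beds: list = field(default_factory=list)
    expression: str | None = None
    clone_tables: list = field(default_factory=list)
    ct_table: str | None = None
    out_dir: str = "elementdm_out"

    detection_alpha: float = 0.05
    max_missing_frac: float = 0.20
    snp_maf_cut: float = 0.01
    window: int = 500
    flank: int = 100
    overlap: int = 100
    min_per_group: int = 3
    equal_var: bool = True
    corr_p: float = 0.005
    corr_rho: float = 0.7
    corr_method: str = "pearson"
    fpkm_min: float = 1.0
    upstream: int = 1500
    enrichment_method: str = "logistic"
    state_map: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.window <= self.overlap:
            raise data_io.DataValidationError(
                f"window ({self.window}) must exceed overlap ({self.overlap})"
            )
        for name in ("detection_alpha", "max_missing_frac", "snp_maf_cut", "corr_p", "corr_rho"):
            if getattr(self, name) <= 0:
                raise data_io.DataValidationError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise data_io.DataValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_all(config: PipelineConfig) -> dict:
    """Run every stage for which inputs are configured.

    Returns a dict of in-memory results; tables are also written under
    ``config.out_dir`` together with ``run_manifest.json``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    manifest_entry: dict = {
        "config_hash": config.config_hash(),
        "thresholds": {
            k: getattr(config, k)
            for k in (
                "detection_alpha", "max_missing_frac", "snp_maf_cut", "window",
                "flank", "overlap", "min_per_group", "corr_p", "corr_rho",
                "fpkm_min", "upstream",
            )
        },
        "inputs": {},
        "stages": [],
    }

    def _stage(name):
        manifest_entry["stages"].append(name)

    try:
        # ---- qc ----------------------------------------------------------
        _stage("qc")
        for key in ("beta", "samples", "manifest"):
            manifest_entry["inputs"][key] = _checksum(getattr(config, key))
        bm = data_io.read_beta_matrix(config.beta, config.samples, config.detection_p)
        man = data_io.read_manifest(config.manifest)
        bm = qc_filter.mask_low_detection(bm, config.detection_alpha)
        bm, report = qc_filter.filter_probes(
            bm, man,
            max_missing_frac=config.max_missing_frac,
            snp_maf_cut=config.snp_maf_cut,
            detection_alpha=config.detection_alpha,
        )
        report.as_frame().to_csv(out / "qc_report.tsv", sep="\t", index=False)
        results["beta"] = bm
        results["qc_report"] = report

        # ---- segmentation ------------------------------------------------
        _stage("segment")
        tracks = data_io.read_chromatin_bed(config.chromatin_beds, config.state_map)
        for p in config.chromatin_beds:
            manifest_entry["inputs"][str(p)] = _checksum(p)
        elements = segmentation.merge_states(tracks)
        segments = segmentation.build_segments(
            elements, man, set(bm.beta.index),
            window=config.window, flank=config.flank, overlap=config.overlap,
        )
        data_io.write_results(segmentation.segments_frame(segments), out / "segments.tsv")
        seg_meth = segmentation.summarize_segments(bm, segments)
        results["segments"] = segments
        results["segment_methylation"] = seg_meth

        # ---- DM testing, both levels ------------------------------------
        _stage("dm")
        cpg_recs = dm_testing.test_units(
            bm.beta, bm.groups, level="cpg",
            min_per_group=config.min_per_group, equal_var=config.equal_var,
        )
        cpg_recs = dm_testing.classify_stringent(dm_testing.adjust_bh(cpg_recs))
        seg_recs = dm_testing.test_units(
            seg_meth.means, bm.groups, level="segment",
            min_per_group=config.min_per_group, equal_var=config.equal_var,
            single_cpg_flags={s.segment_id: s.is_single_cpg for s in segments},
        )
        seg_recs = dm_testing.classify_stringent(dm_testing.adjust_bh(seg_recs))
        data_io.write_results(cpg_recs, out / "dm_cpg.tsv", sort_by=["unit_id"])
        data_io.write_results(seg_recs, out / "dm_segment.tsv", sort_by=["unit_id"])
        results["dm_cpg"] = cpg_recs
        results["dm_segment"] = seg_recs

        cpg_genes = {pid: man.loc[pid, "genes"] for pid in bm.beta.index}
        seg_genes = {
            s.segment_id: tuple(sorted({g for p in s.member_probe_ids for g in man.loc[p, "genes"]}))
            for s in segments
        }
        gene_calls_cpg = dm_testing.classify_lenient_genes(cpg_recs, cpg_genes)
        gene_calls_seg = dm_testing.classify_lenient_genes(seg_recs, seg_genes)
        data_io.write_results(gene_calls_cpg, out / "gene_dm_cpg.tsv", sort_by=["gene"])
        data_io.write_results(gene_calls_seg, out / "gene_dm_segment.tsv", sort_by=["gene"])
        results["gene_dm_cpg"] = gene_calls_cpg
        results["gene_dm_segment"] = gene_calls_seg

        # ---- enrichment --------------------------------------------------
        _stage("enrich")
        membership = enrichment.probe_state_membership(man.loc[bm.beta.index], tracks)
        dm_flags = cpg_recs.set_index("unit_id")["stringent"].reindex(membership.index).fillna(False)
        panel = enrichment.enrichment_panel(dm_flags, membership, method=config.enrichment_method)
        data_io.write_results(enrichment.enrichment_frame(panel), out / "enrichment.tsv")
        results["enrichment"] = panel

        # ---- DM-DE integration ------------------------------------------
        if config.expression:
            _stage("integrate")
            manifest_entry["inputs"]["expression"] = _checksum(config.expression)
            expr = data_io.read_expression(config.expression)
            expr_f = dm_de.filter_expressed(expr, bm.groups, fpkm_min=config.fpkm_min)
            unit_iv = dm_de.cpg_intervals(man.loc[bm.beta.index])
            gene_map = dm_de.map_units_to_genes(unit_iv, expr_f.gene_info, upstream=config.upstream)
            corrs = dm_de.correlate(
                expr_f, bm.beta, gene_map, level="cpg",
                method=config.corr_method, p_cut=config.corr_p, rho_cut=config.corr_rho,
            )
            data_io.write_results(corrs, out / "meth_expr_corr.tsv", sort_by=["gene", "unit_id"])
            arrayed = {g for gs in cpg_genes.values() for g in gs}
            universe = set(expr_f.fpkm.index) & arrayed
            dm_genes = set(gene_calls_cpg.loc[gene_calls_cpg["lenient"], "gene"])
            if universe:
                overlap, enr = dm_de.overlap_dm_correlated(
                    dm_genes, corrs, universe, level="cpg", method=config.enrichment_method
                )
                pd.DataFrame([dataclasses.asdict(overlap)]).to_csv(
                    out / "dm_de_overlap.tsv", sep="\t", index=False
                )
                results["dm_de_overlap"] = overlap
            results["meth_expr_corr"] = corrs

        # ---- clones ------------------------------------------------------
        if config.clone_tables:
            _stage("clones")
            sets = [data_io.read_clone_table(p) for p in config.clone_tables]
            by_key: dict = {}
            for cs in sets:
                by_key.setdefault((cs.amplicon_id, cs.sample_id), {})[cs.chemistry] = cs
            profiles = []
            for (amp, sample), chem in sorted(by_key.items()):
                if "BS" in chem and "oxBS" in chem:
                    profiles.append(clone_bisulfite.infer_5hmc(chem["BS"], chem["oxBS"]))
            if profiles:
                frames = []
                for pr in profiles:
                    f = pr.as_frame()
                    f.insert(0, "amplicon_id", pr.amplicon_id)
                    f.insert(1, "sample_id", pr.sample_id)
                    frames.append(f)
                pd.concat(frames).to_csv(out / "hydroxymethyl.tsv", sep="\t", index=False)
                results["hydroxymethyl"] = profiles

        # ---- qPCR --------------------------------------------------------
        if config.ct_table:
            _stage("qpcr")
            ct = data_io.read_ct_table(config.ct_table)
            records = qpcr.records_from_table(ct)
            dr = qpcr.dose_response(records)
            dr.to_csv(out / "qpcr_dose_response.tsv", sep="\t", index=False)
            results["qpcr_records"] = records
            results["qpcr_dose_response"] = dr
    except Exception as exc:
        stage = manifest_entry["stages"][-1] if manifest_entry["stages"] else "setup"
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest_entry, fh, indent=2, sort_keys=True)
    results["run_manifest"] = manifest_entry
    return results
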