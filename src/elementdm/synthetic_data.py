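"""Synthetic inputs with known ground truth for every pipeline stage.

The generator lays genes along one synthetic chromosome, places promoter,
enhancer and insulator elements around them (with some enhancers wide
enough to force segment tiling), drops CpG probes into the elements plus
intergenic background, and emits two partially overlapping cell-line
chromatin tracks.  Methylation baselines come from a bimodal low/high
mixture drawn once per element; within-group noise is additive normal on
the beta scale (truncated to the valid range), so the configured SD holds
exactly and the two-sample t-test keeps its nominal level.
Differential methylation is spiked at element granularity (all member
CpGs of a chosen element shift together in the cases), expression is
coupled to the realised methylation of one member CpG for a subset of DM
genes (negative sign at promoters, positive elsewhere), and clone-based
bisulfite and qPCR tables are simulated from their declared generative
models.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from . import dm_de
from .clone_bisulfite import CloneBisulfiteSet
from .data_io import BetaMatrix, ChromatinStateTrack, DataValidationError, ExpressionTable

_PROMOTER_SUBSTATES = ("promoter_active", "promoter_weak", "promoter_poised")
_ENHANCER_SUBSTATES = ("enhancer_active", "enhancer_poised")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror a 5 vs 5 array design."""

    seed: int = 0
    n_case: int = 5
    n_control: int = 5
    n_genes: int = 60
    gene_spacing: int = 8000
    gene_span: int = 3000
    p_large_enhancer: float = 0.4  # enhancers wide enough to force tiling
    insulator_every: int = 3
    background_cpgs_per_gene: float = 1.5
    snp_probe_rate: float = 0.02
    sex_chrom_probe_rate: float = 0.03
    detection_dropout: float = 0.01
    # methylation model
    low_mode_ab: tuple = (2.0, 18.0)  # Beta params, mean ~0.1
    high_mode_ab: tuple = (18.0, 2.0)  # mean ~0.9
    promoter_low_weight: float = 0.8
    other_low_weight: float = 0.5
    noise_sd: float = 0.05  # within-group SD on the beta scale
    dm_fraction: float = 0.2  # fraction of elements spiked
    dm_effect: float = 0.3  # |delta beta| in cases
    dm_element_classes: tuple = ("promoter", "enhancer", "insulator")
    dm_class_weights: dict | None = None  # class -> relative spike weight
    # expression model
    coupling_fraction: float = 0.5  # of DM genes coupled to methylation
    coupling_r: float = 0.95  # target |corr| on the log2(FPKM) scale
    coupling_log2_amplitude: float = 1.0  # log2-FPKM swing per methylation SD
    low_expression_fraction: float = 0.15
    fpkm_log2_mean: float = 4.0
    fpkm_log2_sd: float = 1.0
    fpkm_sample_log2_sd: float = 0.8
    # clones and qPCR
    n_amplicons: int = 2
    cpgs_per_amplicon: int = 8
    clones_per_set: int = 10
    qpcr_genes: tuple = ("g1", "g2", "g3")
    qpcr_doses: tuple = (0.0, 1.0, 1.5, 2.0)
    qpcr_dose_ddct: float = -1.0  # dCt shift per uM (fold 2 per uM)
    qpcr_replicates: int = 3
    qpcr_samples_per_group: int = 3
    qpcr_ct_sd: float = 0.15

    def __post_init__(self) -> None:
        for name in (
            "p_large_enhancer", "snp_probe_rate", "sex_chrom_probe_rate",
            "detection_dropout", "dm_fraction", "coupling_fraction",
            "low_expression_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise DataValidationError(f"{name} must be in [0,1], got {v}")
        if self.n_case < 2 or self.n_control < 2:
            raise DataValidationError("need at least 2 samples per group")
        if self.dm_effect > 1:
            raise DataValidationError("dm_effect cannot exceed 1")


@dataclass
class GroundTruth:
    """What the generator actually planted."""

    dm_element_ids: tuple = ()
    dm_cpg_ids: tuple = ()
    dm_gene_ids: tuple = ()
    dm_direction: dict = field(default_factory=dict)  # element_id -> +1/-1
    coupled_pairs: tuple = ()  # (gene, probe_id, sign)
    amplicon_truth: dict = field(default_factory=dict)  # amp -> {group: (mc, hmc)}
    qpcr_fold_per_uM: float = 2.0


@dataclass
class Annotation:
    """Synthetic genome annotation: probes, elements, tracks, genes."""

    manifest: pd.DataFrame
    tracks: list
    gene_info: pd.DataFrame
    elements: pd.DataFrame  # element_id, chrom, start, end, state_class, gene


@dataclass
class SyntheticDataset:
    annotation: Annotation
    beta: BetaMatrix
    expression: ExpressionTable
    clone_sets: list
    ct_table: pd.DataFrame
    truth: GroundTruth
    config: SimulationConfig


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def generate_annotation(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> Annotation:
    """Lay out genes, regulatory elements, CpG probes and cell-line tracks."""
    rng = rng or np.random.default_rng(cfg.seed)
    chrom = "chr1"
    genes, elements, probes = [], [], []
    for i in range(cfg.n_genes):
        gname = f"gene{i + 1:03d}"
        gstart = 2000 + i * cfg.gene_spacing
        gend = gstart + cfg.gene_span
        strand = "+" if rng.random() < 0.5 else "-"
        tss = gstart if strand == "+" else gend - 1
        genes.append((gname, chrom, tss, strand, gstart, gend))

        # promoter around the TSS
        p_start, p_end = tss - 600, tss + 400
        eid = f"el_prom_{gname}"
        elements.append((eid, chrom, p_start, p_end, "promoter", gname))
        n = int(rng.integers(3, 7))
        pos = tss - 400 + np.cumsum(np.concatenate(([0], rng.integers(30, 180, n - 1))))
        pos = pos[pos < p_end]
        for p in pos:
            probes.append((chrom, int(p), eid, "promoter", gname))

        # enhancer in the gene body; wide ones force tiling downstream
        large = rng.random() < cfg.p_large_enhancer
        if large:
            n = int(rng.integers(4, 8))
            gaps = rng.integers(180, 450, n - 1)
        else:
            n = int(rng.integers(2, 5))
            gaps = rng.integers(40, 150, n - 1)
        first = gstart + 1200
        cpg_pos = first + np.cumsum(np.concatenate(([0], gaps)))
        e_start, e_end = int(cpg_pos[0] - 50), int(cpg_pos[-1] + 50)
        eid = f"el_enh_{gname}"
        elements.append((eid, chrom, e_start, e_end, "enhancer", gname))
        for p in cpg_pos:
            probes.append((chrom, int(p), eid, "enhancer", gname))

        # occasional intergenic insulator (annotated to the nearest gene)
        if i % cfg.insulator_every == 0:
            i_start = gend + 2000
            eid = f"el_ins_{gname}"
            elements.append((eid, chrom, i_start, i_start + 300, "insulator", gname))
            n = int(rng.integers(1, 3))
            for k in range(n):
                probes.append((chrom, i_start + 60 + 120 * k, eid, "insulator", gname))

        # background CpGs outside any element
        n_bg = rng.poisson(cfg.background_cpgs_per_gene)
        for k in range(n_bg):
            probes.append((chrom, int(gend + 700 + rng.integers(0, 600)), None, None, None))

    # sex-chromosome probes (removed by QC)
    n_x = int(round(cfg.sex_chrom_probe_rate * len(probes)))
    for k in range(n_x):
        probes.append(("chrX", 1000 + 500 * k, None, None, None))

    man = pd.DataFrame(probes, columns=["chrom", "pos", "element_id", "state_class", "gene"])
    man = man.drop_duplicates(subset=["chrom", "pos"]).reset_index(drop=True)
    man.index = pd.Index([f"cg{i + 1:07d}" for i in range(len(man))], name="probe_id")

    # common-SNP flags on probes outside regulatory elements only, so that
    # planted DM elements are never silently truncated by the SNP filter
    man["snp_maf"] = np.nan
    bg = man.index[man["element_id"].isna() & (man["chrom"] == chrom)]
    n_snp = int(round(cfg.snp_probe_rate * len(man)))
    if n_snp and len(bg):
        flagged = rng.choice(bg, size=min(n_snp, len(bg)), replace=False)
        man.loc[flagged, "snp_maf"] = rng.uniform(0.05, 0.4, size=len(flagged))

    gene_info = pd.DataFrame(
        [g[1:] for g in genes],
        columns=["chrom", "tss", "strand", "start", "end"],
        index=pd.Index([g[0] for g in genes], name="gene"),
    )

    elements_df = pd.DataFrame(
        elements, columns=["element_id", "chrom", "start", "end", "state_class", "gene"]
    )

    tracks = _make_tracks(elements_df, rng)

    # gene annotation per probe: gene span plus 1.5 kb upstream of the TSS
    intervals = pd.DataFrame(
        {"chrom": man["chrom"], "start": man["pos"], "end": man["pos"] + 1}, index=man.index
    )
    gene_map = dm_de.map_units_to_genes(intervals, gene_info)
    man["genes"] = [gene_map.get(pid, ()) for pid in man.index]

    manifest = man[["chrom", "pos", "genes", "snp_maf", "element_id", "state_class", "gene"]]
    if len(manifest) == 0:
        raise DataValidationError("configuration produced zero CpGs")
    return Annotation(manifest=manifest, tracks=tracks, gene_info=gene_info, elements=elements_df)


def _make_tracks(elements: pd.DataFrame, rng: np.random.Generator) -> list:
    """Two cell-line tracks with partially overlapping, jittered states."""
    rows_a, rows_b = [], []
    for el in elements.itertuples(index=False):
        if el.state_class == "promoter":
            sub_a, sub_b = rng.choice(_PROMOTER_SUBSTATES, 2)
        elif el.state_class == "enhancer":
            sub_a, sub_b = rng.choice(_ENHANCER_SUBSTATES, 2)
        else:
            sub_a = sub_b = "insulator"
        which = rng.random()
        jit = int(rng.integers(0, 50))
        if which < 0.5:  # both lines
            rows_a.append((el.chrom, el.start, el.end, sub_a))
            rows_b.append((el.chrom, el.start - jit, el.end + jit, sub_b))
        elif which < 0.75:
            rows_a.append((el.chrom, el.start, el.end, sub_a))
        else:
            rows_b.append((el.chrom, el.start, el.end, sub_b))
    cols = ["chrom", "start", "end", "state"]
    return [
        ChromatinStateTrack("cellA", pd.DataFrame(rows_a, columns=cols)),
        ChromatinStateTrack("cellB", pd.DataFrame(rows_b, columns=cols)),
    ]


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------


def generate_methylation(
    cfg: SimulationConfig,
    annotation: Annotation,
    rng: np.random.Generator | None = None,
) -> tuple[BetaMatrix, GroundTruth]:
    """Bimodal per-element baselines, beta-scale noise, element-granular DM."""
    rng = rng or np.random.default_rng(cfg.seed + 1)
    man = annotation.manifest
    n_probes = len(man)
    samples = [f"case{i + 1}" for i in range(cfg.n_case)] + [
        f"ctrl{i + 1}" for i in range(cfg.n_control)
    ]
    groups = pd.Series(
        ["case"] * cfg.n_case + ["control"] * cfg.n_control, index=samples, name="group"
    )

    # the low/high mode is drawn once per element (contiguous CpGs of one
    # element share their methylation regime); background CpGs draw their
    # own mode
    low_w = np.where(man["state_class"] == "promoter", cfg.promoter_low_weight, cfg.other_low_weight)
    element_ids = man["element_id"].to_numpy()
    mode_draw = rng.random(n_probes)
    el_mode: dict = {}
    is_low = np.empty(n_probes, dtype=bool)
    for i, eid in enumerate(element_ids):
        if eid is None or (isinstance(eid, float) and np.isnan(eid)):
            is_low[i] = mode_draw[i] < low_w[i]
        else:
            if eid not in el_mode:
                el_mode[eid] = mode_draw[i] < low_w[i]
            is_low[i] = el_mode[eid]
    a_lo, b_lo = cfg.low_mode_ab
    a_hi, b_hi = cfg.high_mode_ab
    baseline = np.where(
        is_low, rng.beta(a_lo, b_lo, n_probes), rng.beta(a_hi, b_hi, n_probes)
    )

    # choose spiked elements; all member CpGs move together in the cases
    elig = annotation.elements[annotation.elements["state_class"].isin(cfg.dm_element_classes)]
    eligible = elig["element_id"].to_numpy()
    n_dm = int(round(cfg.dm_fraction * len(eligible)))
    if cfg.dm_class_weights:
        w = elig["state_class"].map(lambda c: cfg.dm_class_weights.get(c, 1.0)).to_numpy(float)
        probs = w / w.sum()
    else:
        probs = None
    dm_elements = (
        rng.choice(eligible, size=n_dm, replace=False, p=probs)
        if n_dm
        else np.array([], dtype=object)
    )
    dm_el_set = set(dm_elements)

    direction = {}
    effect = np.zeros(n_probes)
    member_of = man["element_id"].to_numpy()
    for eid in dm_elements:
        members = member_of == eid
        # the whole element shifts together, toward the valid range, so the
        # full |dm_effect| is realised without clipping
        sign = -1 if baseline[members].mean() > 0.5 else 1
        direction[eid] = sign
        effect[members] = sign * cfg.dm_effect

    mean_ctrl = np.clip(baseline, 0.02, 0.98)
    mean_case = np.clip(baseline + effect, 0.02, 0.98)

    beta = np.empty((n_probes, len(samples)))
    for j, s in enumerate(samples):
        m = mean_case if groups[s] == "case" else mean_ctrl
        # additive within-group noise on the beta scale (truncated at the
        # valid range) keeps the configured SD exact and the two-sample t
        # test at its nominal level
        beta[:, j] = m + rng.normal(0.0, cfg.noise_sd, n_probes)
    beta = np.clip(beta, 0.001, 0.999)

    detp = rng.uniform(0.0, 0.04, size=beta.shape)
    dropout = rng.random(beta.shape) < cfg.detection_dropout
    detp[dropout] = rng.uniform(0.06, 1.0, size=int(dropout.sum()))

    bm = BetaMatrix(
        pd.DataFrame(beta, index=man.index, columns=samples),
        pd.DataFrame(detp, index=man.index, columns=samples),
        groups,
    )
    dm_cpgs = tuple(man.index[np.isin(member_of, list(dm_el_set))]) if dm_el_set else ()
    dm_genes = tuple(
        sorted(set(annotation.elements.set_index("element_id").loc[list(dm_el_set), "gene"]))
    ) if dm_el_set else ()
    truth = GroundTruth(
        dm_element_ids=tuple(sorted(dm_el_set)),
        dm_cpg_ids=dm_cpgs,
        dm_gene_ids=dm_genes,
        dm_direction=direction,
    )
    return bm, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def generate_expression(
    cfg: SimulationConfig,
    annotation: Annotation,
    bm: BetaMatrix,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionTable, GroundTruth]:
    """FPKM coupled to realised methylation for a subset of DM genes.

    For a coupled gene, log2(FPKM) is linear in the realised beta of one
    member CpG of its spiked element, with the noise variance set from the
    target correlation; the sign is negative for promoter elements and
    positive otherwise.  A fraction of uncoupled genes is set to mean
    FPKM < 1 in both groups to exercise the expression filter.
    """
    rng = rng or np.random.default_rng(cfg.seed + 2)
    genes = annotation.gene_info.index.to_list()
    samples = list(bm.beta.columns)
    man = annotation.manifest
    el_by_id = annotation.elements.set_index("element_id")

    # only elements whose probes map to their gene by position (span plus
    # 1.5 kb upstream) can carry an observable methylation-expression link;
    # intergenic insulators fall outside that window
    linkable: dict[str, list[str]] = {}
    for eid in truth.dm_element_ids:
        g = el_by_id.loc[eid, "gene"]
        members = man.index[man["element_id"] == eid]
        if any(g in man.loc[p, "genes"] for p in members):
            linkable.setdefault(g, []).append(eid)
    candidates = sorted(linkable)
    n_couple = min(int(round(cfg.coupling_fraction * len(truth.dm_gene_ids))), len(candidates))
    coupled_genes = list(rng.choice(candidates, size=n_couple, replace=False)) if n_couple else []
    coupled_pairs = []

    uncoupled = [g for g in genes if g not in set(coupled_genes)]
    n_low = int(round(cfg.low_expression_fraction * len(genes)))
    low_genes = set(rng.choice(uncoupled, size=min(n_low, len(uncoupled)), replace=False)) if n_low else set()

    log2fpkm = pd.DataFrame(index=pd.Index(genes, name="gene"), columns=samples, dtype=float)
    for g in genes:
        if g in set(coupled_genes):
            eids = linkable[g]
            eid = eids[int(rng.integers(0, len(eids)))]
            members = [
                p for p in man.index[man["element_id"] == eid] if g in man.loc[p, "genes"]
            ]
            probe = members[len(members) // 2]
            m = bm.beta.loc[probe].to_numpy(dtype=float)
            sign = -1.0 if el_by_id.loc[eid, "state_class"] == "promoter" else 1.0
            s = m.std()
            # moderate log2 amplitude keeps the exp transform near-linear,
            # so the raw-FPKM Pearson correlation stays near coupling_r
            slope = sign * cfg.coupling_log2_amplitude / max(s, 1e-6)
            signal = slope * (m - m.mean())
            eps_sd = abs(slope) * s * np.sqrt(1.0 / cfg.coupling_r**2 - 1.0)
            mu = max(2.0, cfg.fpkm_log2_mean + rng.normal(0, cfg.fpkm_log2_sd))
            log2fpkm.loc[g] = mu + signal + rng.normal(0, eps_sd, len(samples))
            coupled_pairs.append((g, probe, "negative" if sign < 0 else "positive"))
        elif g in low_genes:
            log2fpkm.loc[g] = rng.normal(-2.5, 0.5, len(samples))  # FPKM ~ 0.2
        else:
            mu = cfg.fpkm_log2_mean + rng.normal(0, cfg.fpkm_log2_sd)
            log2fpkm.loc[g] = mu + rng.normal(0, cfg.fpkm_sample_log2_sd, len(samples))

    fpkm = (2.0 ** log2fpkm.astype(float)).clip(lower=0.0)
    expr = ExpressionTable(fpkm, annotation.gene_info.copy())
    truth.coupled_pairs = tuple(coupled_pairs)
    return expr, truth


# ---------------------------------------------------------------------------
# clones and qPCR
# ---------------------------------------------------------------------------


def generate_clones_and_qpcr(
    cfg: SimulationConfig,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> tuple[list, pd.DataFrame]:
    """Clone call tables (BS/oxBS, both groups) and a replicate Ct table."""
    rng = rng or np.random.default_rng(cfg.seed + 3)
    clone_sets = []
    for a in range(cfg.n_amplicons):
        amp = f"amp{a + 1}"
        positions = tuple(1000 * (a + 1) + 80 * j for j in range(cfg.cpgs_per_amplicon))
        mc_ctrl = rng.uniform(0.2, 0.5, cfg.cpgs_per_amplicon)
        hmc_ctrl = rng.uniform(0.0, 0.2, cfg.cpgs_per_amplicon)
        mc_case = np.clip(mc_ctrl + 0.3, 0, 0.75)
        hmc_case = hmc_ctrl
        truth.amplicon_truth[amp] = {
            "case": (mc_case, hmc_case),
            "control": (mc_ctrl, hmc_ctrl),
        }
        for group, (mc, hmc) in truth.amplicon_truth[amp].items():
            sample = f"{group}1"
            bs = rng.random((cfg.clones_per_set, cfg.cpgs_per_amplicon)) < (mc + hmc)
            ox = rng.random((cfg.clones_per_set, cfg.cpgs_per_amplicon)) < mc
            clone_sets.append(
                CloneBisulfiteSet(amp, "BS", sample, positions, bs.astype(float))
            )
            clone_sets.append(
                CloneBisulfiteSet(amp, "oxBS", sample, positions, ox.astype(float))
            )

    rows = []
    for gene in cfg.qpcr_genes:
        base_dct = {"control": rng.uniform(3, 6), "case": rng.uniform(3, 6)}
        for group in ("control", "case"):
            for dose in cfg.qpcr_doses:
                dct = base_dct[group] + cfg.qpcr_dose_ddct * dose
                for s in range(cfg.qpcr_samples_per_group):
                    hk = 20.0 + rng.normal(0, cfg.qpcr_ct_sd, cfg.qpcr_replicates)
                    tgt = 20.0 + dct + rng.normal(0, cfg.qpcr_ct_sd, cfg.qpcr_replicates)
                    rows.append(
                        {
                            "sample_id": f"{group}{s + 1}",
                            "group": group,
                            "dose_uM": dose,
                            "target_gene": gene,
                            "housekeeping_gene": "B2MG",
                            "ct_target": tuple(np.round(tgt, 3)),
                            "ct_housekeeping": tuple(np.round(hk, 3)),
                        }
                    )
    truth.qpcr_fold_per_uM = float(2.0 ** (-cfg.qpcr_dose_ddct))
    return clone_sets, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orchestration and evaluation helpers
# ---------------------------------------------------------------------------


def generate_all(cfg: SimulationConfig) -> SyntheticDataset:
    """Generate every input kind under one seed."""
    rng = np.random.default_rng(cfg.seed)
    ann = generate_annotation(cfg, rng)
    bm, truth = generate_methylation(cfg, ann, rng)
    expr, truth = generate_expression(cfg, ann, bm, truth, rng)
    clones, ct = generate_clones_and_qpcr(cfg, truth, rng)
    return SyntheticDataset(ann, bm, expr, clones, ct, truth, cfg)


def true_segment_flags(segments, truth: GroundTruth) -> pd.Series:
    """Truly-DM flag per segment (any member CpG was spiked)."""
    dm = set(truth.dm_cpg_ids)
    return pd.Series(
        [any(p in dm for p in s.member_probe_ids) for s in segments],
        index=pd.Index([s.segment_id for s in segments], name="segment_id"),
    )


def write_dataset(ds: SyntheticDataset, outdir) -> dict:
    """Write every input format to ``outdir``; returns the path map."""
    from pathlib import Path

    from . import data_io

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    beta = ds.beta.beta.reset_index()
    beta.to_csv(out / "beta.tsv", sep="\t", index=False)
    paths["beta"] = out / "beta.tsv"
    detp = ds.beta.detection_p.reset_index()
    detp.to_csv(out / "detection_p.tsv", sep="\t", index=False)
    paths["detection_p"] = out / "detection_p.tsv"
    pd.DataFrame({"sample_id": ds.beta.groups.index, "group": ds.beta.groups.values}).to_csv(
        out / "samples.tsv", sep="\t", index=False
    )
    paths["samples"] = out / "samples.tsv"
    data_io.write_manifest(ds.annotation.manifest, out / "manifest.tsv")
    paths["manifest"] = out / "manifest.tsv"
    for tr in ds.annotation.tracks:
        p = out / f"chromatin_{tr.cell_line}.bed"
        data_io.write_chromatin_bed(tr, p)
        paths[f"chromatin_{tr.cell_line}"] = p
    data_io.write_expression(ds.expression, out / "expression.tsv")
    paths["expression"] = out / "expression.tsv"
    for cs in ds.clone_sets:
        p = out / f"clones_{cs.amplicon_id}_{cs.sample_id}_{cs.chemistry}.tsv"
        data_io.write_clone_table(cs, p)
    data_io.write_ct_table(ds.ct_table, out / "qpcr_ct.tsv")
    paths["qpcr_ct"] = out / "qpcr_ct.tsv"
    truth_units = pd.DataFrame(
        {
            "kind": (["cpg"] * len(ds.truth.dm_cpg_ids))
            + (["gene"] * len(ds.truth.dm_gene_ids))
            + (["element"] * len(ds.truth.dm_element_ids)),
            "id": list(ds.truth.dm_cpg_ids)
            + list(ds.truth.dm_gene_ids)
            + list(ds.truth.dm_element_ids),
        }
    )
    truth_units.to_csv(out / "truth.tsv", sep="\t", index=False)
    paths["truth"] = out / "truth.tsv"
    return paths
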