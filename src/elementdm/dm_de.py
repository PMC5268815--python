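"""Integration of differential methylation with gene expression.

Expressed genes (mean FPKM >= 1 in at least one group) are paired with the
CpGs or segments lying within the gene span or within 1.5 kb upstream of
its TSS (strand-aware).  For each (gene, unit) pair the FPKM values are
correlated with fractional methylation across all samples pooled,
independent of case/control status; a pair is significant when p < 0.005
and |rho| > 0.7 (Pearson by default, so rho > 0.7 corresponds to
R^2 > 0.5).  Gene-level DM lists are then overlapped with the correlated
genes and the enrichment over random expectation is quantified with the
2x2 machinery of the enrichment module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import BetaMatrix, DataValidationError, ExpressionTable
from .enrichment import EnrichmentResult, enrichment_from_counts

P_SIG = 0.005
RHO_SIG = 0.7
FPKM_MIN = 1.0
UPSTREAM_BP = 1500

CORR_COLUMNS = ["gene", "unit_id", "level", "rho", "p", "n_samples", "sign", "significant"]


def filter_expressed(expr: ExpressionTable, groups: pd.Series, fpkm_min: float = FPKM_MIN) -> ExpressionTable:
    """Drop genes with mean FPKM below ``fpkm_min`` in both groups."""
    case_cols = [s for s in expr.fpkm.columns if groups.get(s) == "case"]
    ctrl_cols = [s for s in expr.fpkm.columns if groups.get(s) == "control"]
    if not case_cols or not ctrl_cols:
        raise DataValidationError("expression table must contain both groups")
    keep = (expr.fpkm[case_cols].mean(axis=1) >= fpkm_min) | (
        expr.fpkm[ctrl_cols].mean(axis=1) >= fpkm_min
    )
    return ExpressionTable(expr.fpkm.loc[keep].copy(), expr.gene_info.loc[keep].copy())


def map_units_to_genes(
    unit_intervals: pd.DataFrame,
    gene_info: pd.DataFrame,
    upstream: int = UPSTREAM_BP,
) -> dict[str, tuple[str, ...]]:
    """Map units to genes by position (gene span plus upstream window).

    ``unit_intervals`` is indexed by unit id with columns chrom, start, end
    (a CpG probe is the 1 bp interval at its position).  A unit maps to a
    gene when it overlaps the gene span extended ``upstream`` bp beyond the
    TSS on the 5' side (strand-aware).  Units may map to several genes.
    Genes lacking coordinates are skipped.
    """
    regions = []
    for gene, r in gene_info.iterrows():
        if pd.isna(r["tss"]) or pd.isna(r["start"]) or pd.isna(r["end"]):
            continue
        if r["strand"] == "-":
            start, end = int(r["start"]), max(int(r["end"]), int(r["tss"]) + 1 + upstream)
        else:
            start, end = min(int(r["start"]), int(r["tss"]) - upstream), int(r["end"])
        regions.append((r["chrom"], start, end, gene))
    reg = pd.DataFrame(regions, columns=["chrom", "start", "end", "gene"])
    out: dict[str, tuple[str, ...]] = {}
    for chrom, units in unit_intervals.groupby("chrom", sort=False):
        sub = reg[reg["chrom"] == chrom]
        if sub.empty:
            continue
        gs = sub["start"].to_numpy()
        ge = sub["end"].to_numpy()
        names = sub["gene"].to_numpy()
        for uid, u in units.iterrows():
            hit = (u["start"] < ge) & (gs < u["end"])
            if hit.any():
                out[uid] = tuple(sorted(names[hit]))
    return out


def cpg_intervals(manifest: pd.DataFrame) -> pd.DataFrame:
    """1 bp intervals at each probe's CpG position."""
    return pd.DataFrame(
        {
            "chrom": manifest["chrom"],
            "start": manifest["pos"],
            "end": manifest["pos"] + 1,
        },
        index=manifest.index,
    )


def correlate(
    expr: ExpressionTable,
    meth: pd.DataFrame,
    unit_genes: Mapping[str, Sequence[str]],
    level: str = "cpg",
    method: str = "pearson",
    min_samples: int = 4,
    p_cut: float = P_SIG,
    rho_cut: float = RHO_SIG,
) -> pd.DataFrame:
    """Correlate FPKM with methylation for every mapped (gene, unit) pair.

    ``meth`` is a units x samples matrix (betas or segment means).  All
    samples with paired non-missing values are pooled.  Pairs with fewer
    than ``min_samples`` informative samples, or with constant methylation
    or expression, are skipped (and counted in the ``skipped`` attribute of
    the returned frame).
    """
    corr_fn = {"pearson": stats.pearsonr, "spearman": stats.spearmanr}[method]
    samples = [s for s in meth.columns if s in expr.fpkm.columns]
    if len(samples) < min_samples:
        raise DataValidationError("too few shared samples between expression and methylation")
    rows = []
    skipped = 0
    fpkm = expr.fpkm[samples]
    meth = meth[samples]
    for unit, genes in unit_genes.items():
        if unit not in meth.index:
            continue
        m = meth.loc[unit].to_numpy(dtype=float)
        for gene in genes:
            if gene not in fpkm.index:
                continue
            e = fpkm.loc[gene].to_numpy(dtype=float)
            ok = ~(np.isnan(m) | np.isnan(e))
            if ok.sum() < min_samples:
                skipped += 1
                continue
            mm, ee = m[ok], e[ok]
            if np.ptp(mm) == 0 or np.ptp(ee) == 0:
                skipped += 1
                continue
            r = corr_fn(ee, mm)
            rho, p = float(r.statistic), float(r.pvalue)
            rows.append(
                {
                    "gene": gene,
                    "unit_id": unit,
                    "level": level,
                    "rho": rho,
                    "p": p,
                    "n_samples": int(ok.sum()),
                    "sign": "positive" if rho >= 0 else "negative",
                    "significant": (p < p_cut) and (abs(rho) > rho_cut),
                }
            )
    out = pd.DataFrame(rows, columns=CORR_COLUMNS)
    out = out.sort_values(["gene", "unit_id"], kind="stable").reset_index(drop=True)
    out.attrs["skipped"] = skipped
    return out


@dataclass
class OverlapResult:
    """Overlap of DM genes with methylation-expression-correlated genes."""

    level: str
    n_dm_genes: int
    n_corr_genes: int
    n_overlap: int
    universe_size: int
    overlap_fraction: float  # n_overlap / n_dm_genes
    odds_ratio: float
    p: float

    def __post_init__(self) -> None:
        if self.n_overlap > min(self.n_dm_genes, self.n_corr_genes):
            raise ValueError("overlap exceeds set sizes")


def overlap_dm_correlated(
    dm_genes,
    corrs: pd.DataFrame,
    universe,
    level: str = "cpg",
    method: str = "logistic",
) -> tuple[OverlapResult, EnrichmentResult]:
    """Overlap DM genes with significantly correlated genes over a universe.

    The universe is the set of genes both expressed (post FPKM filter) and
    represented on the array; enrichment over random expectation uses the
    2x2 logistic / Fisher machinery.
    """
    universe = set(universe)
    if not universe:
        raise DataValidationError("empty gene universe")
    dm = set(dm_genes) & universe
    corr = set(corrs.loc[corrs["significant"], "gene"]) & universe
    both = dm & corr
    n11 = len(both)
    n10 = len(dm - corr)
    n01 = len(corr - dm)
    n00 = len(universe) - n11 - n10 - n01
    enr = enrichment_from_counts(n11, n10, n01, n00, feature="correlated", method=method)
    res = OverlapResult(
        level=level,
        n_dm_genes=len(dm),
        n_corr_genes=len(corr),
        n_overlap=n11,
        universe_size=len(universe),
        overlap_fraction=(n11 / len(dm)) if dm else float("nan"),
        odds_ratio=enr.odds_ratio,
        p=enr.p,
    )
    return res, enr


def stringency_sweep(
    records: pd.DataFrame,
    unit_genes: Mapping[str, Sequence[str]],
    corrs: pd.DataFrame,
    universe,
    thresholds: Sequence[dict],
    level: str = "cpg",
) -> pd.DataFrame:
    """Overlap enrichment as DM stringency increases.

    Each threshold dict may set ``p_cut``, ``dfm_cut`` and ``min_units``;
    the lenient gene list is recomputed at each setting and overlapped with
    the correlated genes.  Rows with zero DM genes are flagged.
    """
    from .dm_testing import classify_lenient_genes

    rows = []
    for thr in thresholds:
        p_cut = thr.get("p_cut", 0.05)
        dfm_cut = thr.get("dfm_cut")
        min_units = thr.get("min_units", 2)
        recs = records
        if dfm_cut is not None:
            # raise the effect-size bar uniformly for this sweep level
            recs = records.copy()
            recs["qualifies_dfm"] = recs["dfm"].abs() > dfm_cut
            recs = recs[recs["qualifies_dfm"] | recs["p"].isna()]
        calls = classify_lenient_genes(recs, unit_genes, min_units=min_units, p_cut=p_cut)
        dm_genes = set(calls.loc[calls["lenient"], "gene"])
        if not dm_genes:
            rows.append(
                {"p_cut": p_cut, "dfm_cut": dfm_cut, "min_units": min_units,
                 "n_dm_genes": 0, "n_overlap": 0, "odds_ratio": np.nan,
                 "p": np.nan, "flagged_empty": True}
            )
            continue
        res, _ = overlap_dm_correlated(dm_genes, corrs, universe, level=level)
        rows.append(
            {"p_cut": p_cut, "dfm_cut": dfm_cut, "min_units": min_units,
             "n_dm_genes": res.n_dm_genes, "n_overlap": res.n_overlap,
             "odds_ratio": res.odds_ratio, "p": res.p, "flagged_empty": False}
        )
    return pd.DataFrame(rows)
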