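"""Two-group differential-methylation testing at CpG and segment level.

Each unit (CpG probe or regulatory segment) is tested with a two-sample
Student's t-test (pooled variance by default; Welch optionally) on its
non-missing per-sample methylation values.  P-values are adjusted with the
Benjamini-Hochberg step-up procedure separately per level, with m equal to
the number of evaluable units at that level.  Two classifications are
derived:

* stringent: FDR q < 0.05 and |DFM| > 0.15 for CpGs; q < 0.05 and
  |DFM| > 0.10 for multi-CpG segments (> 0.15 for single-CpG segments),
  where DFM is the case-minus-control difference in mean fractional
  methylation;
* lenient (per gene): at least two units annotated to the gene with nominal
  p < 0.05 and |DFM| above the level-appropriate threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_io import DataValidationError

#: stringent / lenient effect-size thresholds by level
DFM_CPG = 0.15
DFM_SEGMENT = 0.10
DFM_SINGLE_CPG_SEGMENT = 0.15
Q_STRINGENT = 0.05
P_LENIENT = 0.05

DM_COLUMNS = [
    "unit_id",
    "level",
    "mean_control",
    "mean_case",
    "dfm",
    "n_case",
    "n_control",
    "t_stat",
    "p",
    "q",
    "is_single_cpg_segment",
    "tested",
    "degenerate",
]


def test_units(
    values: pd.DataFrame,
    groups: pd.Series,
    level: str = "cpg",
    min_per_group: int = 3,
    equal_var: bool = True,
    single_cpg_flags: Mapping[str, bool] | None = None,
) -> pd.DataFrame:
    """Two-sample t-test per unit (row) of a units x samples matrix.

    Units with fewer than ``min_per_group`` non-missing values in either
    group are reported untested (p missing).  Units with zero pooled
    variance and unequal means are flagged degenerate; with equal means
    they get t = 0, p = 1.
    """
    if level not in ("cpg", "segment"):
        raise ValueError(f"level must be cpg or segment, got {level!r}")
    case_cols = [s for s in values.columns if groups[s] == "case"]
    ctrl_cols = [s for s in values.columns if groups[s] == "control"]
    if not case_cols or not ctrl_cols:
        raise DataValidationError("both case and control samples are required")

    x1 = values[case_cols].to_numpy(dtype=float)
    x0 = values[ctrl_cols].to_numpy(dtype=float)
    n1 = (~np.isnan(x1)).sum(axis=1)
    n0 = (~np.isnan(x0)).sum(axis=1)
    m1 = _nanmean_rows(x1)
    m0 = _nanmean_rows(x0)
    v1 = _nanvar_rows(x1, m1)  # sum of squared deviations
    v0 = _nanvar_rows(x0, m0)

    testable = (n1 >= min_per_group) & (n0 >= min_per_group)
    t_stat = np.full(len(values), np.nan)
    p = np.full(len(values), np.nan)
    degenerate = np.zeros(len(values), dtype=bool)

    df = n1 + n0 - 2
    if equal_var:
        with np.errstate(divide="ignore", invalid="ignore"):
            sp2 = (v1 + v0) / np.maximum(df, 1)
            se = np.sqrt(sp2 * (1.0 / np.maximum(n1, 1) + 1.0 / np.maximum(n0, 1)))
        dof = df.astype(float)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            s1 = v1 / np.maximum(n1 - 1, 1)
            s0 = v0 / np.maximum(n0 - 1, 1)
            a1 = s1 / np.maximum(n1, 1)
            a0 = s0 / np.maximum(n0, 1)
            se = np.sqrt(a1 + a0)
            dof = (a1 + a0) ** 2 / np.where(
                (n1 > 1) & (n0 > 1),
                a1**2 / np.maximum(n1 - 1, 1) + a0**2 / np.maximum(n0 - 1, 1),
                np.nan,
            )

    diff = m1 - m0
    # tolerance absorbs float error when a group is numerically constant
    zero_se = testable & (se <= 1e-12)
    degenerate[zero_se & (np.abs(diff) > 1e-12)] = True
    flat = zero_se & (np.abs(diff) <= 1e-12)
    t_stat[flat] = 0.0
    p[flat] = 1.0

    ok = testable & (se > 1e-12)
    t_stat[ok] = diff[ok] / se[ok]
    p[ok] = 2.0 * stats.t.sf(np.abs(t_stat[ok]), dof[ok])

    if not testable.any():
        raise DataValidationError(
            f"no unit has >= {min_per_group} non-missing values per group"
        )

    single = (
        pd.Series(False, index=values.index)
        if single_cpg_flags is None
        else pd.Series(values.index.map(lambda u: bool(single_cpg_flags.get(u, False))),
                       index=values.index)
    )
    out = pd.DataFrame(
        {
            "unit_id": values.index,
            "level": level,
            "mean_control": m0,
            "mean_case": m1,
            "dfm": diff,
            "n_case": n1,
            "n_control": n0,
            "t_stat": t_stat,
            "p": p,
            "q": np.nan,
            "is_single_cpg_segment": single.to_numpy(),
            "tested": testable & ~degenerate,
            "degenerate": degenerate,
        }
    ).sort_values("unit_id", kind="stable").reset_index(drop=True)
    return out


def _nanmean_rows(x: np.ndarray) -> np.ndarray:
    cnt = (~np.isnan(x)).sum(axis=1)
    total = np.nansum(x, axis=1)
    return np.where(cnt > 0, total / np.maximum(cnt, 1), np.nan)


def _nanvar_rows(x: np.ndarray, means: np.ndarray) -> np.ndarray:
    """Row-wise sum of squared deviations around the row mean (nan-aware)."""
    d = x - means[:, None]
    return np.nansum(d * d, axis=1)


def adjust_bh(records: pd.DataFrame) -> pd.DataFrame:
    """Benjamini-Hochberg step-up q-values over the tested units.

    m is the number of units with a p-value (the evaluable units at this
    level); untested units keep q missing.
    """
    out = records.copy()
    has_p = out["p"].notna()
    if has_p.any():
        q = multipletests(out.loc[has_p, "p"].to_numpy(), method="fdr_bh")[1]
        out.loc[has_p, "q"] = q
    return out


def classify_stringent(records: pd.DataFrame) -> pd.DataFrame:
    """Flag stringent DM units (FDR and effect-size criteria, per level)."""
    out = records.copy()
    q_ok = out["q"] < Q_STRINGENT
    absdfm = out["dfm"].abs()
    is_seg = out["level"] == "segment"
    thr = np.where(
        is_seg,
        np.where(out["is_single_cpg_segment"], DFM_SINGLE_CPG_SEGMENT, DFM_SEGMENT),
        DFM_CPG,
    )
    out["stringent"] = (q_ok & (absdfm > thr)).fillna(False)
    return out


def classify_lenient_genes(
    records: pd.DataFrame,
    unit_genes: Mapping[str, Sequence[str]],
    min_units: int = 2,
    p_cut: float = P_LENIENT,
    require_same_sign: bool = False,
) -> pd.DataFrame:
    """Per-gene lenient DM calls from unit-level results.

    A gene is lenient-DM at a level when at least ``min_units`` of its
    units have nominal p < ``p_cut`` and |DFM| above the level-appropriate
    threshold.  By default qualifying units need not agree in direction;
    ``require_same_sign=True`` demands at least ``min_units`` sharing a
    sign.  Units without gene annotation are excluded from gene calls.
    """
    recs = records.copy()
    absdfm = recs["dfm"].abs()
    is_seg = recs["level"] == "segment"
    thr = np.where(
        is_seg,
        np.where(recs["is_single_cpg_segment"], DFM_SINGLE_CPG_SEGMENT, DFM_SEGMENT),
        DFM_CPG,
    )
    recs["qualifies"] = ((recs["p"] < p_cut) & (absdfm > thr)).fillna(False)
    if "stringent" not in recs.columns:
        recs = classify_stringent(recs)

    rows = []
    gene_units: dict[str, list[int]] = {}
    for i, unit in enumerate(recs["unit_id"]):
        for g in unit_genes.get(unit, ()):
            gene_units.setdefault(g, []).append(i)
    for gene in sorted(gene_units):
        idx = gene_units[gene]
        sub = recs.iloc[idx]
        qual = sub[sub["qualifies"]]
        if require_same_sign and len(qual):
            n_q = int(max((qual["dfm"] > 0).sum(), (qual["dfm"] < 0).sum()))
        else:
            n_q = int(len(qual))
        rows.append(
            {
                "gene": gene,
                "level": sub["level"].iloc[0],
                "n_qualifying_units": n_q,
                "lenient": n_q >= min_units,
                "stringent": bool(sub["stringent"].any()),
            }
        )
    return pd.DataFrame(rows, columns=["gene", "level", "n_qualifying_units", "lenient", "stringent"])


def standardize_for_heatmap(values: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Per-unit z-scores across samples (population SD), for heat maps.

    Constant rows are returned as zeros and flagged.  Returns the z-score
    matrix and a boolean Series marking zero-variance units.
    """
    x = values.to_numpy(dtype=float)
    mean = np.nanmean(x, axis=1, keepdims=True)
    sd = np.sqrt(np.nanmean((x - mean) ** 2, axis=1, keepdims=True))
    flat = (sd[:, 0] == 0) | np.isnan(sd[:, 0])
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (x - mean) / sd
    z[flat] = 0.0
    z[np.isnan(x)] = np.nan
    return (
        pd.DataFrame(z, index=values.index, columns=values.columns),
        pd.Series(flat, index=values.index, name="zero_variance"),
    )
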