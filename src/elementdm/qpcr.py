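"""Delta-Ct qPCR quantification and dose-response summaries.

Relative expression follows the delta-Ct convention: replicate Ct values
for target and housekeeping genes are averaged, dCt = mean(Ct_target) -
mean(Ct_housekeeping), relative expression = 2^(-dCt).  Group fold changes
use the ddCt form 2^(mean dCt_b - mean dCt_a) for the a-over-b expression
ratio, with a two-sample t-test on the dCt values.  Dose-response tables
(e.g. under the hypomethylating drug 5-aza-dC at 0/1.0/1.5/2.0 uM)
normalise relative expression to a declared baseline stratum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import DataValidationError

CT_CAP = 40.0  # cycles; replicates above this are "undetermined"
CT_WARN = 32.0  # average Ct above this is flagged as low-abundance


@dataclass
class QpcrRecord:
    """One sample x target qPCR measurement after delta-Ct reduction."""

    sample_id: str
    group: str
    dose_uM: float | None
    target_gene: str
    housekeeping_gene: str
    ct_target: tuple
    ct_housekeeping: tuple
    delta_ct: float
    rel_expr: float
    flagged: bool = False
    warn_high_ct: bool = False


def delta_ct(
    sample_id: str,
    group: str,
    target_gene: str,
    housekeeping_gene: str,
    ct_target: Sequence[float],
    ct_housekeeping: Sequence[float],
    dose_uM: float | None = None,
    ct_cap: float = CT_CAP,
    ct_warn: float = CT_WARN,
) -> QpcrRecord:
    """Reduce replicate Cts to dCt and 2^-dCt.

    Replicates above ``ct_cap`` (undetermined) are dropped; a record with
    no usable replicate for either gene is flagged (dCt missing).
    """
    tgt = tuple(float(c) for c in ct_target if float(c) <= ct_cap)
    hk = tuple(float(c) for c in ct_housekeeping if float(c) <= ct_cap)
    if not tgt or not hk:
        return QpcrRecord(
            sample_id, group, dose_uM, target_gene, housekeeping_gene,
            tuple(ct_target), tuple(ct_housekeeping),
            delta_ct=float("nan"), rel_expr=float("nan"), flagged=True,
        )
    dct = float(np.mean(tgt) - np.mean(hk))
    return QpcrRecord(
        sample_id, group, dose_uM, target_gene, housekeeping_gene,
        tgt, hk, delta_ct=dct, rel_expr=float(2.0 ** (-dct)),
        warn_high_ct=float(np.mean(tgt)) > ct_warn,
    )


def records_from_table(df: pd.DataFrame, ct_cap: float = CT_CAP) -> list[QpcrRecord]:
    """Build records from a Ct table as read by ``data_io.read_ct_table``."""
    return [
        delta_ct(
            r.sample_id, r.group, r.target_gene, r.housekeeping_gene,
            r.ct_target, r.ct_housekeeping,
            dose_uM=None if pd.isna(r.dose_uM) else float(r.dose_uM),
            ct_cap=ct_cap,
        )
        for r in df.itertuples(index=False)
    ]


def fold_change(
    group_a: Sequence[QpcrRecord], group_b: Sequence[QpcrRecord]
) -> tuple[float, float]:
    """Expression fold of group a over group b, with a t-test on dCt.

    fold = 2^(mean dCt_b - mean dCt_a); lower dCt means higher expression.
    With fewer than two usable records in a group the fold is still
    reported but the p-value is missing.
    """
    a = np.array([r.delta_ct for r in group_a if not r.flagged])
    b = np.array([r.delta_ct for r in group_b if not r.flagged])
    if len(a) == 0 or len(b) == 0:
        raise DataValidationError("fold_change needs at least one usable record per group")
    fold = float(2.0 ** (np.mean(b) - np.mean(a)))
    if len(a) < 2 or len(b) < 2:
        return fold, float("nan")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        p = 1.0 if np.mean(a) == np.mean(b) else float("nan")
    else:
        p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
    return fold, p


def dose_response(
    records: Sequence[QpcrRecord],
    baseline_group: str = "control",
    baseline_dose: float = 0.0,
) -> pd.DataFrame:
    """Normalised expression per gene x group x dose.

    Within each target gene, every (group, dose) stratum's mean relative
    expression is divided by the mean of the baseline stratum (by default
    the untreated control group), which is therefore 1 by construction.
    Genes lacking the baseline stratum are skipped with a warning column.
    """
    rows = [
        {
            "target_gene": r.target_gene,
            "group": r.group,
            "dose_uM": r.dose_uM,
            "rel_expr": r.rel_expr,
        }
        for r in records
        if not r.flagged and r.dose_uM is not None
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(
            columns=["target_gene", "group", "dose_uM", "mean_rel_expr", "normalized", "n"]
        )
    out = []
    for gene, sub in df.groupby("target_gene", sort=True):
        base = sub[(sub["group"] == baseline_group) & (sub["dose_uM"] == baseline_dose)]
        if base.empty:
            continue  # baseline missing: stratum skipped
        base_mean = base["rel_expr"].mean()
        for (group, dose), cell in sub.groupby(["group", "dose_uM"], sort=True):
            out.append(
                {
                    "target_gene": gene,
                    "group": group,
                    "dose_uM": dose,
                    "mean_rel_expr": cell["rel_expr"].mean(),
                    "normalized": cell["rel_expr"].mean() / base_mean,
                    "n": len(cell),
                }
            )
    return pd.DataFrame(out)
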