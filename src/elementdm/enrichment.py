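"""Chromatin-state enrichment of DM units and methylation-level summaries.

Enrichment is assessed with a univariate logistic regression of the DM
indicator on the feature indicator; the odds ratio is exp(slope) and the
p-value comes from the slope's Wald test.  For any non-degenerate 2x2
table this OR equals the contingency cross-product ratio, and Fisher's
exact test is available as a cross-check.  log2(OR) symmetrises
over-representation and depletion for plotting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .data_io import DataValidationError


@dataclass
class EnrichmentResult:
    """2x2 DM-by-feature association."""

    feature: str
    n11: int  # DM & feature
    n10: int  # DM & not feature
    n01: int  # not DM & feature
    n00: int  # neither
    odds_ratio: float
    log2_or: float
    p: float
    method: str
    degenerate: bool = False


def _counts(dm: np.ndarray, feat: np.ndarray) -> tuple[int, int, int, int]:
    n11 = int(np.sum(dm & feat))
    n10 = int(np.sum(dm & ~feat))
    n01 = int(np.sum(~dm & feat))
    n00 = int(np.sum(~dm & ~feat))
    return n11, n10, n01, n00


def state_enrichment(
    dm_flags: pd.Series,
    feature_flags: pd.Series,
    feature: str = "feature",
    method: str = "logistic",
) -> EnrichmentResult:
    """Association of a binary DM flag with a binary feature flag.

    Both series must cover the same unit universe.  A zero margin
    (feature never or always present, or no DM calls) yields a degenerate
    result with OR missing.
    """
    if not dm_flags.index.equals(feature_flags.index):
        feature_flags = feature_flags.reindex(dm_flags.index)
        if feature_flags.isna().any():
            raise DataValidationError("dm and feature flags cover different units")
    dm = dm_flags.to_numpy(dtype=bool)
    feat = feature_flags.to_numpy(dtype=bool)
    n11, n10, n01, n00 = _counts(dm, feat)
    return enrichment_from_counts(n11, n10, n01, n00, feature=feature, method=method)


def enrichment_from_counts(
    n11: int, n10: int, n01: int, n00: int, feature: str = "feature", method: str = "logistic"
) -> EnrichmentResult:
    """Enrichment statistics from 2x2 counts (DM x feature)."""
    margins = (n11 + n10, n01 + n00, n11 + n01, n10 + n00)
    if min(margins) == 0:
        return EnrichmentResult(
            feature, n11, n10, n01, n00, math.nan, math.nan, math.nan, method, degenerate=True
        )
    if method == "fisher":
        oratio, p = stats.fisher_exact([[n11, n10], [n01, n00]], alternative="two-sided")
        if min(n11, n10, n01, n00) == 0:
            oratio = math.nan
        return EnrichmentResult(
            feature, n11, n10, n01, n00, float(oratio),
            math.log2(oratio) if oratio and not math.isnan(oratio) else math.nan,
            float(p), "fisher", degenerate=min(n11, n10, n01, n00) == 0,
        )
    if method != "logistic":
        raise ValueError(f"unknown enrichment method {method!r}")
    if min(n11, n10, n01, n00) == 0:
        # perfect separation: slope diverges
        return EnrichmentResult(
            feature, n11, n10, n01, n00, math.nan, math.nan, math.nan, "logistic",
            degenerate=True,
        )
    # fit on the four distinct covariate/outcome rows with frequency weights
    y = np.array([1.0, 1.0, 0.0, 0.0])
    x = sm.add_constant(np.array([1.0, 0.0, 1.0, 0.0]))
    w = np.array([n11, n10, n01, n00], dtype=float)
    fit = sm.GLM(y, x, family=sm.families.Binomial(), freq_weights=w).fit()
    slope = fit.params[1]
    p = float(fit.pvalues[1])
    oratio = float(np.exp(slope))
    return EnrichmentResult(
        feature, n11, n10, n01, n00, oratio, math.log2(oratio), p, "logistic"
    )


def enrichment_panel(
    dm_flags: pd.Series,
    state_membership: pd.DataFrame,
    method: str = "logistic",
) -> list[EnrichmentResult]:
    """One enrichment result per chromatin state column.

    ``state_membership`` is a units x states boolean DataFrame (a unit is a
    member of a state when any queried cell line annotates it so); rows
    must match the ``dm_flags`` universe.
    """
    return [
        state_enrichment(dm_flags, state_membership[col], feature=col, method=method)
        for col in state_membership.columns
    ]


def probe_state_membership(manifest: pd.DataFrame, tracks) -> pd.DataFrame:
    """Boolean probes x states membership from per-cell-line tracks."""
    from .data_io import STATES

    states = [s for s in STATES if s != "other"]
    out = pd.DataFrame(False, index=manifest.index, columns=states)
    by_chrom = {c: sub.sort_values("pos") for c, sub in manifest.groupby("chrom", sort=False)}
    for tr in tracks:
        for r in tr.intervals.itertuples(index=False):
            if r.state == "other":
                continue
            sub = by_chrom.get(r.chrom)
            if sub is None:
                continue
            pos = sub["pos"].to_numpy()
            lo, hi = np.searchsorted(pos, [r.start, r.end])
            if lo < hi:
                out.loc[sub.index[lo:hi], r.state] = True
    return out


@dataclass
class MethylationDistribution:
    """Histogram and low/intermediate/high fractions for one stratum."""

    stratum: str
    bin_edges: np.ndarray
    counts: np.ndarray
    class_fractions: dict
    n: int


def methylation_distribution(
    values,
    stratum: str = "all",
    n_bins: int = 20,
    low_cut: float = 0.3,
    high_cut: float = 0.7,
) -> MethylationDistribution:
    """Histogram of methylation levels plus low/intermediate/high fractions.

    ``low`` is < ``low_cut``; ``high`` is > ``high_cut``; values at the
    boundaries count as intermediate.  Empty strata return zero counts.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(x, bins=edges)
    n = len(x)
    if n:
        fractions = {
            "low": float(np.mean(x < low_cut)),
            "intermediate": float(np.mean((x >= low_cut) & (x <= high_cut))),
            "high": float(np.mean(x > high_cut)),
        }
    else:
        fractions = {"low": 0.0, "intermediate": 0.0, "high": 0.0}
    return MethylationDistribution(stratum, edges, counts, fractions, n)


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])
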