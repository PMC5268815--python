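"""Probe-level quality control for 450K-style beta matrices.

Cleaning proceeds in a fixed order: (1) beta values whose detection p-value
exceeds the threshold are set missing; (2) probes on the sex chromosomes are
removed; (3) probes missing in more than ``max_missing_frac`` of samples are
removed; (4) probes querying a common SNP (minor allele frequency above
``snp_maf_cut``) are removed.  Each probe is attributed to the first rule
that removes it, so the per-rule counts in the report sum exactly to the
number of probes removed.  All boundaries are strict inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import BetaMatrix, DataValidationError

SEX_CHROMS = frozenset({"chrX", "chrY"})


@dataclass
class FilterReport:
    """Per-rule accounting of probe QC."""

    n_input: int
    n_masked_values: int
    n_removed_xy: int
    n_removed_missingness: int
    n_removed_snp: int
    n_retained: int

    def __post_init__(self) -> None:
        removed = self.n_removed_xy + self.n_removed_missingness + self.n_removed_snp
        if self.n_retained != self.n_input - removed:
            raise ValueError("filter report counts are inconsistent")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def mask_low_detection(bm: BetaMatrix, alpha: float = 0.05) -> BetaMatrix:
    """Set beta values with detection p-value > ``alpha`` to missing.

    Missing detection p-values are treated as passing; with no detection-p
    table at all, the matrix is returned unchanged (as a copy).
    """
    out = bm.copy()
    if out.detection_p is None:
        return out
    fail = out.detection_p.to_numpy(dtype=float) > alpha  # NaN compares False
    beta = out.beta.to_numpy(dtype=float)
    beta[fail] = np.nan
    out.beta = pd.DataFrame(beta, index=out.beta.index, columns=out.beta.columns)
    return out


def filter_probes(
    bm: BetaMatrix,
    manifest: pd.DataFrame,
    max_missing_frac: float = 0.20,
    snp_maf_cut: float = 0.01,
    detection_alpha: float = 0.05,
) -> tuple[BetaMatrix, FilterReport]:
    """Remove sex-chromosome, poorly detected, and SNP-confounded probes.

    Expects :func:`mask_low_detection` to have been applied already; the
    missingness fraction is computed on the masked matrix.  Probes absent
    from the manifest are an error.  A probe with no SNP annotation is
    treated as having MAF 0 (retained).
    """
    absent = bm.beta.index.difference(manifest.index)
    if len(absent):
        raise DataValidationError(
            f"probes absent from manifest: {list(absent[:5])}"
            + (" ..." if len(absent) > 5 else "")
        )
    man = manifest.loc[bm.beta.index]
    n_input = len(bm.beta)
    # cells masked by the detection rule (reported, not re-applied here)
    n_masked = (
        0
        if bm.detection_p is None
        else int((bm.detection_p.to_numpy(dtype=float) > detection_alpha).sum())
    )

    removed = pd.Series(False, index=bm.beta.index)

    on_xy = man["chrom"].isin(SEX_CHROMS)
    n_xy = int(on_xy.sum())
    removed |= on_xy

    miss_frac = bm.beta.isna().mean(axis=1)
    high_missing = (miss_frac > max_missing_frac) & ~removed
    n_missing = int(high_missing.sum())
    removed |= high_missing

    maf = man["snp_maf"].fillna(0.0)
    snp = (maf > snp_maf_cut) & ~removed
    n_snp = int(snp.sum())
    removed |= snp

    keep = bm.beta.index[~removed]
    out = BetaMatrix(
        bm.beta.loc[keep].copy(),
        None if bm.detection_p is None else bm.detection_p.loc[keep].copy(),
        bm.groups.copy(),
    )
    report = FilterReport(
        n_input=n_input,
        n_masked_values=n_masked,
        n_removed_xy=n_xy,
        n_removed_missingness=n_missing,
        n_removed_snp=n_snp,
        n_retained=len(keep),
    )
    return out, report
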