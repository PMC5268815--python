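"""Clone-based bisulfite sequencing summaries and oxBS 5hmC decomposition.

Standard bisulfite conversion scores 5mC + 5hmC; oxidative bisulfite
conversion scores 5mC only.  With clone calls from both chemistries over
the same amplicon, the per-CpG 5hmC contribution is inferred by
subtraction: hmC = BS fraction - oxBS fraction, clamped at zero (sampling
noise can make the raw difference negative) and flagged when clamped.
Group comparisons of clone counts use Fisher's exact test per CpG.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import DataValidationError


@dataclass
class CloneBisulfiteSet:
    """Clone x CpG binary methylation calls for one amplicon/chemistry/sample.

    ``calls`` is a float matrix with 1 = methylated, 0 = unmethylated,
    NaN = missing.
    """

    amplicon_id: str
    chemistry: str  # "BS" | "oxBS"
    sample_id: str
    cpg_positions: tuple
    calls: np.ndarray
    clone_ids: tuple = ()

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.ndim != 2 or self.calls.shape[0] < 1:
            raise DataValidationError("calls must be a clone x CpG matrix with >= 1 clone")
        if self.calls.shape[1] != len(self.cpg_positions):
            raise DataValidationError(
                f"{self.calls.shape[1]} call columns vs {len(self.cpg_positions)} CpGs"
            )
        if self.chemistry not in ("BS", "oxBS"):
            raise DataValidationError(f"chemistry must be BS or oxBS, got {self.chemistry!r}")
        if not self.clone_ids:
            self.clone_ids = tuple(f"clone{i + 1}" for i in range(self.calls.shape[0]))

    @property
    def n_clones(self) -> int:
        return self.calls.shape[0]


def summarize_clones(cs: CloneBisulfiteSet) -> tuple[np.ndarray, list[str]]:
    """Per-CpG methylated fraction and per-clone lollipop pattern strings.

    Fractions are methylated / (methylated + unmethylated); a CpG with no
    informative call gets NaN.  Patterns use '1', '0' and '.' per CpG, one
    string per clone, preserving clone order.
    """
    informative = (~np.isnan(cs.calls)).sum(axis=0)
    meth = np.nansum(cs.calls, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(informative > 0, meth / np.maximum(informative, 1), np.nan)
    patterns = [
        "".join("." if np.isnan(v) else str(int(v)) for v in row) for row in cs.calls
    ]
    return frac, patterns


@dataclass
class HydroxymethylProfile:
    """Per-CpG decomposition of net methylation into 5mC and 5hmC."""

    amplicon_id: str
    sample_id: str
    cpg_positions: tuple
    bs_frac: np.ndarray
    oxbs_frac: np.ndarray
    mc_frac: np.ndarray
    hmc_frac: np.ndarray
    clamped: np.ndarray
    hmc_ci_low: np.ndarray
    hmc_ci_high: np.ndarray
    n_clones_bs: np.ndarray
    n_clones_oxbs: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pos": [p + 1 for p in self.cpg_positions],
                "bs_frac": self.bs_frac,
                "oxbs_frac": self.oxbs_frac,
                "mc_frac": self.mc_frac,
                "hmc_frac": self.hmc_frac,
                "clamped": self.clamped,
                "hmc_ci_low": self.hmc_ci_low,
                "hmc_ci_high": self.hmc_ci_high,
                "n_clones_bs": self.n_clones_bs,
                "n_clones_oxbs": self.n_clones_oxbs,
            }
        )


def infer_5hmc(
    bs: CloneBisulfiteSet, oxbs: CloneBisulfiteSet, conf_level: float = 0.95
) -> HydroxymethylProfile:
    """Decompose net methylation into 5mC and 5hmC by BS - oxBS subtraction.

    The chemistries are summarised independently (clone numbers need not
    match).  5mC is the oxBS fraction; 5hmC is max(BS - oxBS, 0) with a
    ``clamped`` flag where the raw difference was negative.  A Wald
    two-proportion confidence interval on the difference (clipped to
    [-1, 1]) conveys the clone-sampling uncertainty.
    """
    if bs.amplicon_id != oxbs.amplicon_id or bs.sample_id != oxbs.sample_id:
        raise DataValidationError("BS and oxBS sets must share amplicon and sample")
    if tuple(bs.cpg_positions) != tuple(oxbs.cpg_positions):
        diff = set(bs.cpg_positions) ^ set(oxbs.cpg_positions)
        raise DataValidationError(f"misaligned CpG coordinates: {sorted(diff)}")
    bs_frac, _ = summarize_clones(bs)
    ox_frac, _ = summarize_clones(oxbs)
    n_bs = (~np.isnan(bs.calls)).sum(axis=0)
    n_ox = (~np.isnan(oxbs.calls)).sum(axis=0)
    raw = bs_frac - ox_frac
    clamped = raw < 0
    hmc = np.where(clamped, 0.0, raw)
    z = stats.norm.ppf(0.5 + conf_level / 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(
            bs_frac * (1 - bs_frac) / np.maximum(n_bs, 1)
            + ox_frac * (1 - ox_frac) / np.maximum(n_ox, 1)
        )
    lo = np.clip(raw - z * se, -1.0, 1.0)
    hi = np.clip(raw + z * se, -1.0, 1.0)
    return HydroxymethylProfile(
        amplicon_id=bs.amplicon_id,
        sample_id=bs.sample_id,
        cpg_positions=tuple(bs.cpg_positions),
        bs_frac=bs_frac,
        oxbs_frac=ox_frac,
        mc_frac=ox_frac.copy(),
        hmc_frac=hmc,
        clamped=clamped,
        hmc_ci_low=lo,
        hmc_ci_high=hi,
        n_clones_bs=n_bs,
        n_clones_oxbs=n_ox,
    )


def compare_amplicon_groups(
    case_sets: list[CloneBisulfiteSet], control_sets: list[CloneBisulfiteSet]
) -> tuple[pd.DataFrame, float]:
    """Case/control comparison of pooled clone calls for one amplicon.

    Clones are pooled within each group; each CpG gets a two-sided Fisher
    exact test on the 2x2 (group x methylated) table.  CpGs with no
    informative clone in either group are skipped.  Also returns the
    per-amplicon difference of mean per-CpG fractions (case - control).
    """
    if not case_sets or not control_sets:
        raise DataValidationError("need at least one clone set per group")
    positions = tuple(case_sets[0].cpg_positions)
    for cs in case_sets + control_sets:
        if tuple(cs.cpg_positions) != positions:
            raise DataValidationError("clone sets have misaligned CpG coordinates")
    case = np.vstack([cs.calls for cs in case_sets])
    ctrl = np.vstack([cs.calls for cs in control_sets])
    rows = []
    for j, pos in enumerate(positions):
        ca = case[:, j]
        co = ctrl[:, j]
        ca_m = int(np.nansum(ca))
        ca_u = int((ca == 0).sum())
        co_m = int(np.nansum(co))
        co_u = int((co == 0).sum())
        if ca_m + ca_u == 0 or co_m + co_u == 0:
            continue
        _, p = stats.fisher_exact([[ca_m, ca_u], [co_m, co_u]], alternative="two-sided")
        rows.append(
            {
                "pos": pos + 1,
                "case_meth": ca_m,
                "case_unmeth": ca_u,
                "control_meth": co_m,
                "control_unmeth": co_u,
                "case_frac": ca_m / (ca_m + ca_u),
                "control_frac": co_m / (co_m + co_u),
                "p": float(p),
            }
        )
    df = pd.DataFrame(rows)
    mean_diff = float((df["case_frac"] - df["control_frac"]).mean()) if len(df) else float("nan")
    return df, mean_diff


# ---------------------------------------------------------------------------
# lollipop rendering
# ---------------------------------------------------------------------------


@dataclass
class LollipopModel:
    """Plot-ready representation of a clone set (QUMA-style lollipops)."""

    amplicon_id: str
    sample_id: str
    cpg_positions: tuple
    rows: list  # one list of {"1","0","."} per clone

    def to_patterns(self) -> list[str]:
        return ["".join(r) for r in self.rows]


def lollipop_model(cs: CloneBisulfiteSet) -> LollipopModel:
    _, patterns = summarize_clones(cs)
    return LollipopModel(
        amplicon_id=cs.amplicon_id,
        sample_id=cs.sample_id,
        cpg_positions=tuple(cs.cpg_positions),
        rows=[list(p) for p in patterns],
    )


def plot_lollipops(model: LollipopModel, path) -> None:
    """Render a lollipop plot (filled = methylated) to a vector file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_clones = len(model.rows)
    n_cpgs = len(model.cpg_positions)
    fig, ax = plt.subplots(figsize=(max(2, n_cpgs * 0.3), max(1.5, n_clones * 0.25)))
    for i, row in enumerate(model.rows):
        y = n_clones - i
        ax.plot(range(n_cpgs), [y] * n_cpgs, color="0.7", lw=0.5, zorder=1)
        for j, v in enumerate(row):
            if v == ".":
                continue
            ax.scatter(
                j, y, s=40, zorder=2,
                facecolor="black" if v == "1" else "white", edgecolor="black",
            )
    ax.set_yticks([])
    ax.set_xticks(range(n_cpgs))
    ax.set_xticklabels([p + 1 for p in model.cpg_positions], rotation=90, fontsize=6)
    ax.set_title(f"{model.amplicon_id} / {model.sample_id}", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
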