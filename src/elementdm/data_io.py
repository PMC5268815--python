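"""Readers and writers for the tabular and interval formats used by the pipeline.

All genomic intervals are held internally as 0-based half-open ``[start, end)``;
probe manifests declare 1-based CpG positions and are converted to internal
coordinates exactly once, at read time.  Chromosome names are normalised to
the ``chrN`` form on read.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: the seven internal chromatin-state labels
STATES = (
    "promoter_active",
    "promoter_weak",
    "promoter_poised",
    "enhancer_active",
    "enhancer_poised",
    "insulator",
    "other",
)

#: state label -> element class ("other" maps to no class)
CLASS_OF_STATE: Mapping[str, str | None] = {
    "promoter_active": "promoter",
    "promoter_weak": "promoter",
    "promoter_poised": "promoter",
    "enhancer_active": "enhancer",
    "enhancer_poised": "enhancer",
    "insulator": "insulator",
    "other": None,
}

STATE_CLASSES = ("promoter", "enhancer", "insulator")

GROUPS = ("case", "control")


class DataValidationError(ValueError):
    """Raised when an input table violates the pipeline's contracts."""


def normalize_chrom(chrom: str) -> str:
    """Normalise a chromosome name to the ``chrN`` convention."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        return "chr" + c[3:]
    return "chr" + c


# ---------------------------------------------------------------------------
# beta matrix
# ---------------------------------------------------------------------------


@dataclass
class BetaMatrix:
    """Probes x samples fractional methylation with optional detection p-values.

    Parameters
    ----------
    beta
        DataFrame of fractional methylation in [0, 1]; NaN marks missing.
        Index = probe ids, columns = sample ids.
    detection_p
        Optional DataFrame of detection p-values, same shape/labels as
        ``beta``; NaN is treated as "no detection p available" (pass).
    groups
        Series mapping sample id -> ``"case"`` or ``"control"``.
    """

    beta: pd.DataFrame
    detection_p: pd.DataFrame | None
    groups: pd.Series

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.beta.index.has_duplicates:
            dups = self.beta.index[self.beta.index.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate probe ids: {dups[:5]}")
        vals = self.beta.to_numpy(dtype=float)
        bad = (vals < 0) | (vals > 1)
        if np.any(bad & ~np.isnan(vals)):
            i, j = np.argwhere(bad & ~np.isnan(vals))[0]
            raise DataValidationError(
                f"beta value out of [0,1] at probe {self.beta.index[i]!r}, "
                f"sample {self.beta.columns[j]!r}: {vals[i, j]}"
            )
        if self.detection_p is not None:
            if self.detection_p.shape != self.beta.shape:
                raise DataValidationError(
                    "detection_p shape "
                    f"{self.detection_p.shape} != beta shape {self.beta.shape}"
                )
        missing = set(self.beta.columns) - set(self.groups.index)
        if missing:
            raise DataValidationError(f"samples without group label: {sorted(missing)}")
        bad_groups = set(self.groups.unique()) - set(GROUPS)
        if bad_groups:
            raise DataValidationError(f"unknown group labels: {sorted(bad_groups)}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.columns

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.beta.columns if self.groups[s] == group]

    def copy(self) -> "BetaMatrix":
        return BetaMatrix(
            self.beta.copy(),
            None if self.detection_p is None else self.detection_p.copy(),
            self.groups.copy(),
        )


def read_sample_sheet(path: str | Path) -> pd.Series:
    """Read a two-column (sample_id, group) sheet; groups must be case/control."""
    df = _read_table(path)
    if df.shape[1] < 2:
        raise DataValidationError(f"{path}: sample sheet needs columns sample_id, group")
    df = df.rename(columns={df.columns[0]: "sample_id", df.columns[1]: "group"})
    if df["sample_id"].duplicated().any():
        raise DataValidationError(f"{path}: duplicate sample ids")
    groups = df.set_index("sample_id")["group"].astype(str)
    bad = set(groups) - set(GROUPS)
    if bad:
        raise DataValidationError(f"{path}: groups must be in {GROUPS}, got {sorted(bad)}")
    return groups


def read_beta_matrix(
    path: str | Path,
    sample_sheet: str | Path,
    detection_p_path: str | Path | None = None,
) -> BetaMatrix:
    """Read a beta matrix (first column probe id, one column per sample).

    An optional parallel detection-p table may be supplied; if absent, all
    detection p-values are missing and detection masking is a no-op.
    """
    beta = _read_matrix(path, "beta")
    detp = None
    if detection_p_path is not None:
        detp = _read_matrix(detection_p_path, "detection p")
        if detp.empty:
            detp = pd.DataFrame(np.nan, index=beta.index, columns=beta.columns)
        else:
            if not detp.index.equals(beta.index) or not detp.columns.equals(beta.columns):
                try:
                    detp = detp.loc[beta.index, beta.columns]
                except KeyError as exc:
                    raise DataValidationError(
                        f"{detection_p_path}: probe/sample labels do not match beta matrix"
                    ) from exc
    groups = read_sample_sheet(sample_sheet)
    extra = set(beta.columns) - set(groups.index)
    if extra:
        raise DataValidationError(
            f"{path}: samples absent from sample sheet: {sorted(extra)}"
        )
    return BetaMatrix(beta, detp, groups.loc[list(beta.columns)])


def _read_matrix(path: str | Path, what: str) -> pd.DataFrame:
    df = _read_table(path)
    if df.empty:
        return pd.DataFrame()
    df = df.set_index(df.columns[0])
    df.index.name = "probe_id"
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            row = bad.index[0] if len(bad) else "?"
            raise DataValidationError(
                f"{path}: non-numeric {what} value at row {row!r}, column {col!r}"
            ) from exc
    return df.astype(float)


# ---------------------------------------------------------------------------
# probe manifest
# ---------------------------------------------------------------------------


def read_manifest(path: str | Path, chromosomes: Iterable[str] | None = None) -> pd.DataFrame:
    """Read a probe manifest into a DataFrame indexed by probe id.

    Expected columns: probe_id, chrom, pos (1-based), genes (';'-joined,
    may be empty), snp_maf (may be empty = no common SNP).  The returned
    frame carries 0-based internal positions in column ``pos``.
    """
    df = _read_table(path)
    required = {"probe_id", "chrom", "pos"}
    if not required.issubset(df.columns):
        raise DataValidationError(f"{path}: manifest needs columns {sorted(required)}")
    if df["probe_id"].duplicated().any():
        raise DataValidationError(f"{path}: duplicate probe ids in manifest")
    pos1 = pd.to_numeric(df["pos"])
    if (pos1 < 1).any():
        raise DataValidationError(f"{path}: manifest positions must be >= 1 (1-based)")
    genes_col = df["genes"] if "genes" in df.columns else pd.Series([""] * len(df))
    out = pd.DataFrame(
        {
            "chrom": df["chrom"].map(normalize_chrom).to_numpy(),
            "pos": (pos1.astype(int) - 1).to_numpy(),  # -> 0-based internal
            "genes": [
                tuple(g for g in str(s).split(";") if g) for s in genes_col.fillna("")
            ],
            "snp_maf": pd.to_numeric(df.get("snp_maf"), errors="coerce").to_numpy()
            if "snp_maf" in df.columns
            else np.full(len(df), np.nan),
        },
        index=pd.Index(df["probe_id"], name="probe_id"),
    )
    if chromosomes is not None:
        allowed = {normalize_chrom(c) for c in chromosomes}
        bad = set(out["chrom"]) - allowed
        if bad:
            raise DataValidationError(f"{path}: chromosomes outside declared set: {sorted(bad)}")
    return out


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    """Write a manifest back to text (positions re-encoded as 1-based)."""
    out = pd.DataFrame(
        {
            "probe_id": manifest.index,
            "chrom": manifest["chrom"].to_numpy(),
            "pos": manifest["pos"].to_numpy() + 1,
            "genes": [";".join(g) for g in manifest["genes"]],
            "snp_maf": manifest["snp_maf"].to_numpy(),
        }
    )
    _write_table(out, path)


# ---------------------------------------------------------------------------
# chromatin states
# ---------------------------------------------------------------------------


@dataclass
class ChromatinStateTrack:
    """Chromatin-state intervals for one cell line (0-based half-open)."""

    cell_line: str
    intervals: pd.DataFrame  # columns chrom, start, end, state

    def __post_init__(self) -> None:
        iv = self.intervals
        if len(iv) and not (iv["start"] < iv["end"]).all():
            bad = iv[~(iv["start"] < iv["end"])].iloc[0]
            raise DataValidationError(
                f"track {self.cell_line}: start >= end at "
                f"{bad['chrom']}:{bad['start']}-{bad['end']}"
            )
        unknown = set(iv["state"]) - set(STATES)
        if unknown:
            raise DataValidationError(
                f"track {self.cell_line}: unknown states {sorted(unknown)}"
            )


def read_chromatin_bed(
    paths: Sequence[str | Path],
    state_map: Mapping[str, str] | None = None,
    cell_lines: Sequence[str] | None = None,
    on_unknown_chrom: str = "keep",
    chromosomes: Iterable[str] | None = None,
) -> list[ChromatinStateTrack]:
    """Read BED-like chromatin-state files, one track per cell line.

    ``state_map`` translates track-specific state names (e.g. ChromHMM's
    ``Strong_Enhancer``) to the seven internal labels; unmapped names become
    ``"other"``.  Lines with start >= end are rejected.  Chromosomes outside
    ``chromosomes`` are skipped or rejected per ``on_unknown_chrom``
    ("skip" | "fail" | "keep").
    """
    state_map = dict(state_map or {})
    allowed = None if chromosomes is None else {normalize_chrom(c) for c in chromosomes}
    tracks = []
    for k, path in enumerate(paths):
        name = cell_lines[k] if cell_lines is not None else Path(path).stem
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split()
                if len(parts) < 4:
                    raise DataValidationError(f"{path}:{lineno}: expected chrom/start/end/name")
                chrom = normalize_chrom(parts[0])
                start, end = int(parts[1]), int(parts[2])
                if start >= end:
                    raise DataValidationError(
                        f"{path}:{lineno}: start {start} >= end {end}"
                    )
                if allowed is not None and chrom not in allowed:
                    if on_unknown_chrom == "skip":
                        continue
                    if on_unknown_chrom == "fail":
                        raise DataValidationError(f"{path}:{lineno}: unknown chromosome {chrom}")
                raw_state = parts[3]
                state = state_map.get(raw_state, raw_state if raw_state in STATES else "other")
                rows.append((chrom, start, end, state))
        tracks.append(
            ChromatinStateTrack(
                cell_line=name,
                intervals=pd.DataFrame(rows, columns=["chrom", "start", "end", "state"]),
            )
        )
    return tracks


def write_chromatin_bed(track: ChromatinStateTrack, path: str | Path) -> None:
    track.intervals.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


@dataclass
class ExpressionTable:
    """Per-gene FPKM values plus gene coordinates.

    ``fpkm`` is genes x samples; ``gene_info`` is indexed by gene with
    columns chrom, tss (0-based), strand, start, end (0-based half-open).
    """

    fpkm: pd.DataFrame
    gene_info: pd.DataFrame

    def __post_init__(self) -> None:
        if self.fpkm.index.has_duplicates:
            raise DataValidationError("duplicate gene symbols in expression table")
        vals = self.fpkm.to_numpy(dtype=float)
        if np.any(vals[~np.isnan(vals)] < 0):
            raise DataValidationError("negative FPKM values")


def read_expression(path: str | Path) -> ExpressionTable:
    """Read an expression table.

    Expected columns: gene, chrom, tss (1-based), strand, start (1-based),
    end (inclusive), then one FPKM column per sample.
    """
    df = _read_table(path)
    meta_cols = ["gene", "chrom", "tss", "strand", "start", "end"]
    if not set(meta_cols).issubset(df.columns):
        raise DataValidationError(f"{path}: expression table needs columns {meta_cols}")
    sample_cols = [c for c in df.columns if c not in meta_cols]
    gene_info = pd.DataFrame(
        {
            "chrom": df["chrom"].map(normalize_chrom).to_numpy(),
            "tss": (pd.to_numeric(df["tss"]).astype(int) - 1).to_numpy(),
            "strand": df["strand"].to_numpy(),
            "start": (pd.to_numeric(df["start"]).astype(int) - 1).to_numpy(),
            "end": pd.to_numeric(df["end"]).astype(int).to_numpy(),  # 1-based inclusive -> half-open
        },
        index=pd.Index(df["gene"], name="gene"),
    )
    fpkm = df.set_index("gene")[sample_cols].astype(float)
    return ExpressionTable(fpkm, gene_info)


def write_expression(expr: ExpressionTable, path: str | Path) -> None:
    info = expr.gene_info
    out = pd.DataFrame(
        {
            "gene": info.index,
            "chrom": info["chrom"].to_numpy(),
            "tss": info["tss"].to_numpy() + 1,
            "strand": info["strand"].to_numpy(),
            "start": info["start"].to_numpy() + 1,
            "end": info["end"].to_numpy(),
        }
    )
    out = pd.concat([out.reset_index(drop=True), expr.fpkm.reset_index(drop=True)], axis=1)
    _write_table(out, path)


# ---------------------------------------------------------------------------
# clone bisulfite call tables
# ---------------------------------------------------------------------------


def read_clone_table(path: str | Path):
    """Read a clone x CpG call table.

    Format: a header line ``#amplicon=<id> chemistry=<BS|oxBS> sample=<id>
    positions=<comma-joined 1-based>`` followed by one row per clone:
    clone id then one call per CpG in {1, 0, .}.
    """
    from .clone_bisulfite import CloneBisulfiteSet

    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise DataValidationError(f"{path}: missing '#' header line")
        meta = dict(tok.split("=", 1) for tok in header[1:].split())
        positions = tuple(int(p) - 1 for p in meta["positions"].split(","))
        rows = []
        clone_ids = []
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            clone_ids.append(parts[0])
            calls = parts[1:]
            if len(calls) != len(positions):
                raise DataValidationError(
                    f"{path}: clone {parts[0]} has {len(calls)} calls, "
                    f"expected {len(positions)}"
                )
            rows.append([np.nan if c == "." else float(c) for c in calls])
    return CloneBisulfiteSet(
        amplicon_id=meta["amplicon"],
        chemistry=meta["chemistry"],
        sample_id=meta["sample"],
        cpg_positions=positions,
        calls=np.asarray(rows, dtype=float),
        clone_ids=tuple(clone_ids),
    )


def write_clone_table(cs, path: str | Path) -> None:
    with open(path, "w") as fh:
        pos = ",".join(str(p + 1) for p in cs.cpg_positions)
        fh.write(
            f"#amplicon={cs.amplicon_id} chemistry={cs.chemistry} "
            f"sample={cs.sample_id} positions={pos}\n"
        )
        for cid, row in zip(cs.clone_ids, cs.calls):
            calls = "\t".join("." if np.isnan(v) else str(int(v)) for v in row)
            fh.write(f"{cid}\t{calls}\n")


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

CT_COLUMNS = [
    "sample_id",
    "group",
    "dose_uM",
    "target_gene",
    "housekeeping_gene",
    "ct_target",
    "ct_housekeeping",
]


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a qPCR Ct table; replicate Cts are comma-joined within a cell."""
    df = _read_table(path)
    if not set(CT_COLUMNS).issubset(df.columns):
        raise DataValidationError(f"{path}: Ct table needs columns {CT_COLUMNS}")
    for col in ("ct_target", "ct_housekeeping"):
        df[col] = df[col].map(lambda s: tuple(float(x) for x in str(s).split(",")))
    df["dose_uM"] = pd.to_numeric(df["dose_uM"], errors="coerce")
    return df


def write_ct_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    for col in ("ct_target", "ct_housekeeping"):
        out[col] = out[col].map(lambda t: ",".join(format(x, "g") for x in t))
    _write_table(out, path)


# ---------------------------------------------------------------------------
# generic result tables
# ---------------------------------------------------------------------------


def write_results(records, path: str | Path, sort_by: Sequence[str] | None = None) -> None:
    """Write a result collection to tab-separated text.

    Accepts a DataFrame or a list of dataclass instances.  Column order is
    deterministic, the sort (by ``sort_by`` if given, else by existing
    coordinate-ish columns) is stable, and missing values are written as
    empty fields.  Round-tripping through :func:`read_results` reproduces
    float values to 1e-12.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        recs = list(records)
        if recs and dataclasses.is_dataclass(recs[0]):
            df = pd.DataFrame([dataclasses.asdict(r) for r in recs])
        else:
            df = pd.DataFrame(recs)
    if sort_by is None:
        sort_by = [
            c for c in ("chrom", "pos", "start", "segment_id", "unit_id", "gene")
            if c in df.columns
        ]
    if sort_by and len(df):
        df = df.sort_values(list(sort_by), kind="stable")
    df.to_csv(path, sep="\t", index=False, na_rep="", float_format="%.12g")


def read_results(path: str | Path) -> pd.DataFrame:
    return _read_table(path)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a tab- or comma-separated table with a header line."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(path)
    if p.stat().st_size == 0:
        return pd.DataFrame()
    with open(p) as fh:
        first = fh.readline()
    sep = "\t" if "\t" in first else ","
    return pd.read_csv(p, sep=sep)


def _write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="")
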