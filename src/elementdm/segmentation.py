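"""Grouping of CpGs into <=500 bp regulatory segments.

Chromatin-state intervals from all available cell lines are first collapsed,
per element class (promoter, enhancer, insulator), into a non-cell-specific
union of "regulatory elements": a CpG belongs to a class if any queried cell
line annotates its position with any sub-state of that class.  Within each
element, consecutive retained CpGs closer than 500 bp are clustered.  A
cluster spanning at most 500 bp becomes a single segment; a lone CpG gets a
500 bp window centred on it; a wider cluster is tiled with 500 bp windows
over the cluster extended by 100 bp flanks, stepping 400 bp (100 bp tile
overlap), with a final tile right-anchored at the extended end so the
cluster tail is always covered.  Tiles containing no retained CpG are
dropped; a CpG may sit in two overlapping tiles and in elements of several
classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import (
    CLASS_OF_STATE,
    STATE_CLASSES,
    BetaMatrix,
    ChromatinStateTrack,
    DataValidationError,
)


@dataclass(frozen=True)
class RegulatoryElement:
    """A merged, non-cell-specific interval of one element class."""

    chrom: str
    start: int
    end: int
    state_class: str
    substates: frozenset
    cell_lines: frozenset

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise DataValidationError(f"element {self.chrom}:{self.start}-{self.end} empty")


@dataclass(frozen=True)
class RegulatorySegment:
    """One unit of element-level testing with its member CpG probes."""

    segment_id: str
    chrom: str
    start: int
    end: int
    state_class: str
    member_probe_ids: tuple
    origin: str  # grouped | single_window | tile

    def __post_init__(self) -> None:
        if not self.member_probe_ids:
            raise DataValidationError(f"segment {self.segment_id} has no member probes")

    @property
    def is_single_cpg(self) -> bool:
        return len(self.member_probe_ids) == 1


@dataclass
class SegmentMethylation:
    """Per-segment per-sample mean beta over non-missing member CpGs."""

    means: pd.DataFrame  # segments x samples
    n_cpgs_used: pd.DataFrame  # segments x samples, int


def merge_states(tracks: list[ChromatinStateTrack]) -> list[RegulatoryElement]:
    """Union chromatin-state intervals across cell lines per element class.

    Overlapping or abutting intervals of the same class (any sub-state, any
    cell line) are merged; different classes are merged independently, so
    elements of different classes may overlap.
    """
    if not tracks:
        raise DataValidationError("merge_states requires at least one track")
    elements: list[RegulatoryElement] = []
    for klass in STATE_CLASSES:
        rows = []
        for tr in tracks:
            iv = tr.intervals
            sel = iv[iv["state"].map(lambda s: CLASS_OF_STATE.get(s) == klass)]
            for r in sel.itertuples(index=False):
                rows.append((r.chrom, int(r.start), int(r.end), r.state, tr.cell_line))
        rows.sort(key=lambda r: (r[0], r[1], r[2]))
        cur = None
        for chrom, start, end, state, cell in rows:
            if cur is not None and chrom == cur[0] and start <= cur[2]:
                cur[2] = max(cur[2], end)
                cur[3].add(state)
                cur[4].add(cell)
            else:
                if cur is not None:
                    elements.append(_element_from(cur, klass))
                cur = [chrom, start, end, {state}, {cell}]
        if cur is not None:
            elements.append(_element_from(cur, klass))
    return elements


def _element_from(cur, klass) -> RegulatoryElement:
    return RegulatoryElement(
        chrom=cur[0],
        start=cur[1],
        end=cur[2],
        state_class=klass,
        substates=frozenset(cur[3]),
        cell_lines=frozenset(cur[4]),
    )


def build_segments(
    elements: list[RegulatoryElement],
    manifest: pd.DataFrame,
    retained_probes,
    window: int = 500,
    flank: int = 100,
    overlap: int = 100,
) -> list[RegulatorySegment]:
    """Cluster and window retained CpGs within regulatory elements.

    Parameters
    ----------
    elements
        Merged elements from :func:`merge_states`.
    manifest
        Probe manifest (0-based internal positions).
    retained_probes
        Ids of probes surviving QC; only these generate segments.
    window, flank, overlap
        Segment window length, tiling flank, and tile overlap in bp.
    """
    if window <= overlap:
        raise DataValidationError(f"window ({window}) must exceed overlap ({overlap})")
    retained = manifest.loc[manifest.index.isin(set(retained_probes))]
    by_chrom = {
        chrom: sub.sort_values("pos")
        for chrom, sub in retained.groupby("chrom", sort=False)
    }
    segments: list[RegulatorySegment] = []
    for el in sorted(elements, key=lambda e: (e.chrom, e.start, e.end, e.state_class)):
        sub = by_chrom.get(el.chrom)
        if sub is None:
            continue
        pos = sub["pos"].to_numpy()
        lo, hi = np.searchsorted(pos, [el.start, el.end])
        if lo == hi:
            continue
        member_pos = pos[lo:hi]
        member_ids = sub.index.to_numpy()[lo:hi]
        for seg in _segment_cluster_runs(
            el, member_pos, member_ids, window=window, flank=flank, overlap=overlap
        ):
            segments.append(seg)
    return segments


def _segment_cluster_runs(el, member_pos, member_ids, *, window, flank, overlap):
    # split into clusters at inter-CpG gaps >= window (grouping is strict <)
    breaks = np.flatnonzero(np.diff(member_pos) >= window)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks + 1, [len(member_pos)]))
    for a, b in zip(starts, ends):
        cpos = member_pos[a:b]
        cids = member_ids[a:b]
        first, last = int(cpos[0]), int(cpos[-1])
        span = last - first
        if len(cpos) == 1:
            s, e = first - window // 2, first + window - window // 2
            yield _make_segment(el, s, e, tuple(cids), "single_window")
        elif span <= window:
            yield _make_segment(el, first, last + 1, tuple(cids), "grouped")
        else:
            region_start = first - flank
            region_end = last + flank
            step = window - overlap
            tile_starts = list(range(region_start, region_end - window + 1, step))
            anchor = region_end - window
            if anchor not in tile_starts:
                tile_starts.append(anchor)
            for ts in tile_starts:
                inside = (cpos >= ts) & (cpos < ts + window)
                if not inside.any():
                    continue
                yield _make_segment(el, ts, ts + window, tuple(cids[inside]), "tile")


def _make_segment(el, start, end, probe_ids, origin) -> RegulatorySegment:
    return RegulatorySegment(
        segment_id=f"{el.chrom}:{start}-{end}:{el.state_class}",
        chrom=el.chrom,
        start=int(start),
        end=int(end),
        state_class=el.state_class,
        member_probe_ids=probe_ids,
        origin=origin,
    )


def summarize_segments(bm: BetaMatrix, segments: list[RegulatorySegment]) -> SegmentMethylation:
    """Average member-CpG betas per segment per sample (non-missing only)."""
    beta = bm.beta
    means = np.empty((len(segments), beta.shape[1]))
    counts = np.empty((len(segments), beta.shape[1]), dtype=int)
    index = []
    for i, seg in enumerate(segments):
        missing = [p for p in seg.member_probe_ids if p not in beta.index]
        if missing:
            raise DataValidationError(
                f"segment {seg.segment_id} references unretained probes: {missing}"
            )
        sub = beta.loc[list(seg.member_probe_ids)].to_numpy(dtype=float)
        ok = ~np.isnan(sub)
        counts[i] = ok.sum(axis=0)
        with np.errstate(invalid="ignore"):
            means[i] = np.where(
                counts[i] > 0, np.nansum(sub, axis=0) / np.maximum(counts[i], 1), np.nan
            )
        index.append(seg.segment_id)
    idx = pd.Index(index, name="segment_id")
    return SegmentMethylation(
        means=pd.DataFrame(means, index=idx, columns=beta.columns),
        n_cpgs_used=pd.DataFrame(counts, index=idx, columns=beta.columns),
    )


def segments_frame(segments: list[RegulatorySegment]) -> pd.DataFrame:
    """Tabular view of a segment list (probe ids comma-joined)."""
    return pd.DataFrame(
        {
            "segment_id": [s.segment_id for s in segments],
            "chrom": [s.chrom for s in segments],
            "start": [s.start for s in segments],
            "end": [s.end for s in segments],
            "state_class": [s.state_class for s in segments],
            "origin": [s.origin for s in segments],
            "probe_ids": [",".join(s.member_probe_ids) for s in segments],
        }
    )
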