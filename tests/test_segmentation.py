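"""Segmentation tests, including an independent brute-force oracle.

The oracle clusters CpGs by transitive closure of pairwise distance < 500
(union-find over all pairs) and enumerates tiles by the stated stepping
rule, testing tile membership CpG by CpG -- a deliberately O(n^2) path
independent of the implementation.
"""

import numpy as np
import pandas as pd
import pytest

from elementdm import segmentation as seg
from elementdm.data_io import BetaMatrix, ChromatinStateTrack, DataValidationError

WINDOW, FLANK, OVERLAP = 500, 100, 100


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------


def oracle_segments(elements, probe_positions):
    """Expected (class, start, end, origin, members) set, brute force."""
    out = set()
    for el in elements:
        members = sorted(
            (pos, pid) for pid, (chrom, pos) in probe_positions.items()
            if chrom == el.chrom and el.start <= pos < el.end
        )
        if not members:
            continue
        # union-find over all pairs closer than the window
        parent = list(range(len(members)))

        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i

        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if abs(members[i][0] - members[j][0]) < WINDOW:
                    parent[find(j)] = find(i)
        clusters = {}
        for i in range(len(members)):
            clusters.setdefault(find(i), []).append(members[i])
        for cl in clusters.values():
            cl.sort()
            pos = [p for p, _ in cl]
            ids = frozenset(pid for _, pid in cl)
            first, last = pos[0], pos[-1]
            if len(cl) == 1:
                out.add((el.state_class, first - 250, first + 250, "single_window", ids))
            elif last - first <= WINDOW:
                out.add((el.state_class, first, last + 1, "grouped", ids))
            else:
                rs, re = first - FLANK, last + FLANK
                starts = []
                s = rs
                while s + WINDOW <= re:
                    starts.append(s)
                    s += WINDOW - OVERLAP
                if re - WINDOW not in starts:
                    starts.append(re - WINDOW)
                for ts in starts:
                    inside = frozenset(pid for p, pid in cl if ts <= p < ts + WINDOW)
                    if inside:
                        out.add((el.state_class, ts, ts + WINDOW, "tile", inside))
    return out


def _as_set(segments):
    return {
        (s.state_class, s.start, s.end, s.origin, frozenset(s.member_probe_ids))
        for s in segments
    }


def _manifest_from(probe_positions):
    df = pd.DataFrame(
        [(pid, c, p) for pid, (c, p) in probe_positions.items()],
        columns=["probe_id", "chrom", "pos"],
    ).set_index("probe_id")
    df["genes"] = [()] * len(df)
    df["snp_maf"] = np.nan
    return df


def random_instance(rng, max_cpgs=200):
    """Random disjoint elements per class plus scattered probes."""
    elements = []
    cursor = 1000
    for _ in range(rng.integers(2, 8)):
        length = int(rng.integers(80, 2500))
        klass = rng.choice(["promoter", "enhancer", "insulator"])
        elements.append(
            seg.RegulatoryElement("chr1", cursor, cursor + length, klass,
                                  frozenset(), frozenset())
        )
        cursor += length + int(rng.integers(600, 2000))
    probes = {}
    n = int(rng.integers(5, max_cpgs))
    positions = rng.choice(np.arange(500, cursor + 500), size=n, replace=False)
    for i, p in enumerate(sorted(positions)):
        probes[f"cg{i:04d}"] = ("chr1", int(p))
    return elements, probes


# ---------------------------------------------------------------------------
# merge_states
# ---------------------------------------------------------------------------


def _track(cell, rows):
    return ChromatinStateTrack(cell, pd.DataFrame(rows, columns=["chrom", "start", "end", "state"]))


class TestMergeStates:
    def test_cross_cell_line_union(self):
        a = _track("A", [("chr1", 1000, 1400, "enhancer_active")])
        b = _track("B", [("chr1", 1300, 1700, "enhancer_poised")])
        (el,) = seg.merge_states([a, b])
        assert (el.chrom, el.start, el.end, el.state_class) == ("chr1", 1000, 1700, "enhancer")
        assert el.substates == {"enhancer_active", "enhancer_poised"}
        assert el.cell_lines == {"A", "B"}

    def test_different_classes_kept_independently(self):
        a = _track("A", [("chr1", 100, 300, "promoter_active"), ("chr1", 200, 400, "insulator")])
        els = seg.merge_states([a])
        classes = {e.state_class for e in els}
        assert classes == {"promoter", "insulator"}
        assert len(els) == 2

    def test_single_interval_identity(self):
        a = _track("A", [("chr1", 10, 20, "insulator")])
        (el,) = seg.merge_states([a])
        assert (el.start, el.end) == (10, 20)

    def test_empty_track_list_rejected(self):
        with pytest.raises(DataValidationError):
            seg.merge_states([])

    def test_union_matches_coverage_oracle(self, rng):
        # brute force: mark covered bases, extract maximal runs
        for _ in range(20):
            n = rng.integers(1, 12)
            rows = []
            for _ in range(n):
                s = int(rng.integers(0, 3000))
                e = s + int(rng.integers(1, 800))
                rows.append(("chr1", s, e, "enhancer_active"))
            track = _track("A", rows)
            els = [e for e in seg.merge_states([track]) if e.state_class == "enhancer"]
            covered = np.zeros(5000, dtype=bool)
            for _, s, e, _ in rows:
                covered[s:e] = True
            runs = []
            in_run = False
            for i, c in enumerate(covered):
                if c and not in_run:
                    start, in_run = i, True
                elif not c and in_run:
                    runs.append((start, i))
                    in_run = False
            assert [(e.start, e.end) for e in sorted(els, key=lambda x: x.start)] == runs


# ---------------------------------------------------------------------------
# build_segments
# ---------------------------------------------------------------------------


class TestBuildSegments:
    def test_grouped_pair_within_window(self):
        el = seg.RegulatoryElement("chr1", 1000, 1400, "enhancer", frozenset(), frozenset())
        probes = {"cg1": ("chr1", 1050), "cg2": ("chr1", 1300)}
        (s,) = seg.build_segments([el], _manifest_from(probes), set(probes))
        assert s.origin == "grouped"
        assert set(s.member_probe_ids) == {"cg1", "cg2"}

    def test_single_cpg_centered_window(self):
        el = seg.RegulatoryElement("chr1", 4900, 5100, "insulator", frozenset(), frozenset())
        probes = {"cg1": ("chr1", 5000)}
        (s,) = seg.build_segments([el], _manifest_from(probes), set(probes))
        assert (s.start, s.end, s.origin) == (4750, 5250, "single_window")
        assert s.end - s.start == 500

    def test_tiling_example(self):
        # cluster 10,000 / 10,450 / 10,900 / 11,190 spans 1,190 bp:
        # region [9,900, 11,290), tile starts 9,900 / 10,300 / 10,700 and a
        # right-anchored 10,790
        el = seg.RegulatoryElement("chr1", 9900, 11300, "enhancer", frozenset(), frozenset())
        probes = {f"cg{i}": ("chr1", p) for i, p in enumerate([10000, 10450, 10900, 11190])}
        segs = seg.build_segments([el], _manifest_from(probes), set(probes))
        tiles = {(s.start, s.end): set(s.member_probe_ids) for s in segs}
        assert set(tiles) == {(9900, 10400), (10300, 10800), (10700, 11200), (10790, 11290)}
        assert tiles[(10300, 10800)] == {"cg1"}
        assert "cg1" not in tiles[(9900, 10400)]
        assert all(s.end - s.start == 500 for s in segs)

    def test_window_must_exceed_overlap(self):
        el = seg.RegulatoryElement("chr1", 0, 100, "promoter", frozenset(), frozenset())
        with pytest.raises(DataValidationError, match="window"):
            seg.build_segments([el], _manifest_from({"cg1": ("chr1", 50)}), {"cg1"},
                               window=100, overlap=100)

    def test_probes_outside_elements_generate_nothing(self):
        el = seg.RegulatoryElement("chr1", 1000, 1100, "promoter", frozenset(), frozenset())
        probes = {"cg1": ("chr1", 5000)}
        assert seg.build_segments([el], _manifest_from(probes), set(probes)) == []

    def test_matches_bruteforce_oracle_on_random_instances(self, rng):
        for _ in range(30):
            elements, probes = random_instance(rng)
            got = _as_set(seg.build_segments(elements, _manifest_from(probes), set(probes)))
            assert got == oracle_segments(elements, probes)

    def test_every_element_cpg_is_covered(self, segmented_dataset):
        ds, bm, elements, segments, _ = segmented_dataset
        man = ds.annotation.manifest
        in_seg = {p for s in segments for p in s.member_probe_ids}
        for pid in bm.beta.index:
            pos = man.loc[pid, "pos"]
            chrom = man.loc[pid, "chrom"]
            inside = any(
                e.chrom == chrom and e.start <= pos < e.end for e in elements
            )
            assert (pid in in_seg) == inside

    def test_no_consecutive_members_further_than_window(self, segmented_dataset):
        ds, _, _, segments, _ = segmented_dataset
        man = ds.annotation.manifest
        for s in segments:
            if s.origin == "tile":
                continue
            pos = sorted(man.loc[list(s.member_probe_ids), "pos"])
            assert all(b - a < 500 for a, b in zip(pos, pos[1:]))


class TestSummarizeSegments:
    def _setup(self, betas):
        beta = pd.DataFrame(betas, index=["cg1", "cg2"])
        groups = pd.Series(["case", "control"], index=beta.columns)
        bm = BetaMatrix(beta, None, groups)
        s = seg.RegulatorySegment("seg1", "chr1", 0, 500, "promoter", ("cg1", "cg2"), "grouped")
        return bm, [s]

    def test_mean_of_members(self):
        bm, segs = self._setup({"s1": [0.2, 0.4], "s2": [0.6, 0.8]})
        sm = seg.summarize_segments(bm, segs)
        assert sm.means.loc["seg1", "s1"] == pytest.approx(0.3)
        assert sm.n_cpgs_used.loc["seg1", "s1"] == 2

    def test_missing_member_reduces_count(self):
        bm, segs = self._setup({"s1": [np.nan, 0.4], "s2": [0.6, 0.8]})
        sm = seg.summarize_segments(bm, segs)
        assert sm.means.loc["seg1", "s1"] == pytest.approx(0.4)
        assert sm.n_cpgs_used.loc["seg1", "s1"] == 1

    def test_all_members_missing_gives_missing(self):
        bm, segs = self._setup({"s1": [np.nan, np.nan], "s2": [0.6, 0.8]})
        sm = seg.summarize_segments(bm, segs)
        assert np.isnan(sm.means.loc["seg1", "s1"])
        assert sm.n_cpgs_used.loc["seg1", "s1"] == 0

    def test_unretained_member_probe_fails(self):
        bm, _ = self._setup({"s1": [0.2, 0.4], "s2": [0.6, 0.8]})
        bad = seg.RegulatorySegment("segX", "chr1", 0, 500, "promoter", ("cgZ",), "grouped")
        with pytest.raises(DataValidationError, match="cgZ"):
            seg.summarize_segments(bm, [bad])
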