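"""Windowed two-sample coverage comparison (male:female log2 ratio scan).

Per-base depth from each sex is averaged in fixed non-overlapping windows
(500 bp by default), the male library is rescaled onto the female library
by the median window ratio, and windows whose |log2 ratio| exceeds a
threshold (default 4) are flagged. A flagged window where the depleted
sample is essentially uncovered is called sex-specific — the signature of
U- or V-linkage in a haploid dioecious genome — otherwise merely enriched.
Runs of flagged windows with the same call merge into regions.

Sample A is the male and sample B the female by convention throughout; all
coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError, NormalizationError

CALLS = ("a_specific", "b_specific", "a_enriched", "b_enriched", "balanced")

WINDOW_COLUMNS = ["seg", "start", "end", "width", "cov", "partial"]


# ---------------------------------------------------------------------------
# coverage tracks
# ---------------------------------------------------------------------------

@dataclass
class CoverageTrack:
    """Per-base depth vectors for one sample, one array per segment."""

    depth: dict[str, np.ndarray]

    @property
    def segment_lengths(self) -> dict[str, int]:
        return {s: len(a) for s, a in self.depth.items()}

    @classmethod
    def from_arrays(cls, depth: dict[str, np.ndarray]) -> "CoverageTrack":
        for seg, arr in depth.items():
            if np.any(np.asarray(arr) < 0):
                raise InputError(f"negative depth on {seg}")
        return cls({s: np.asarray(a, dtype=float) for s, a in depth.items()})

    @classmethod
    def from_bedgraph(cls, path: str | Path,
                      segment_lengths: dict[str, int]) -> "CoverageTrack":
        """Load a BedGraph (seg, start, end, depth); uncovered bases are 0."""
        depth = {s: np.zeros(l, dtype=float)
                 for s, l in segment_lengths.items()}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("track", "#")):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise InputError(f"{path}:{lineno}: expected 4 columns")
                seg, start, end, value = (
                    parts[0], int(parts[1]), int(parts[2]), float(parts[3]))
                if seg not in depth:
                    raise InputError(f"{path}:{lineno}: unknown segment {seg}")
                if value < 0:
                    raise InputError(f"{path}:{lineno}: negative depth")
                depth[seg][start:end] = value
        return cls(depth)

    @classmethod
    def from_alignments(cls, path: str | Path, min_mapq: int = 0
                        ) -> "CoverageTrack":
        """Depth from a coordinate-sorted, indexed SAM/BAM/CRAM file.

        Primary alignments only, filtered at the given MAPQ minimum.
        """
        import pysam

        depth: dict[str, np.ndarray] = {}
        with pysam.AlignmentFile(str(path)) as af:
            for seg, length in zip(af.references, af.lengths):
                counts = af.count_coverage(
                    seg, 0, length,
                    quality_threshold=0,
                    read_callback=lambda r: (
                        not r.is_secondary and not r.is_supplementary
                        and not r.is_unmapped
                        and r.mapping_quality >= min_mapq))
                depth[seg] = np.asarray(counts, dtype=float).sum(axis=0)
        return cls(depth)

    def write_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for seg in sorted(self.depth):
                arr = self.depth[seg]
                if arr.size == 0:
                    continue
                boundaries = np.flatnonzero(np.diff(arr)) + 1
                starts = np.concatenate(([0], boundaries))
                ends = np.concatenate((boundaries, [arr.size]))
                for s, e in zip(starts, ends):
                    fh.write(f"{seg}\t{s}\t{e}\t{arr[s]:g}\n")


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

def window_coverage(track: CoverageTrack, width: int = 500) -> pd.DataFrame:
    """Tile each segment with fixed windows and average depth per window.

    Windows start at 0; a terminal partial window is emitted with its true
    width and marked ``partial``. The mean is over the window's true width.
    """
    if width < 1:
        raise ValueError("window width must be >= 1")
    rows = []
    for seg in sorted(track.depth):
        arr = track.depth[seg]
        length = arr.size
        for start in range(0, length, width):
            end = min(start + width, length)
            w = end - start
            rows.append((seg, start, end, w,
                         float(arr[start:end].sum()) / w, w < width))
    return pd.DataFrame(rows, columns=WINDOW_COLUMNS)


def combine_windows(windows_a: pd.DataFrame, windows_b: pd.DataFrame
                    ) -> pd.DataFrame:
    """Join two samples' window tables on identical tilings."""
    key = ["seg", "start", "end", "width", "partial"]
    if len(windows_a) != len(windows_b) or not (
            windows_a[key].reset_index(drop=True)
            .equals(windows_b[key].reset_index(drop=True))):
        raise InputError("window tables were tiled differently")
    out = windows_a[key].copy().reset_index(drop=True)
    out["cov_a"] = windows_a["cov"].to_numpy()
    out["cov_b"] = windows_b["cov"].to_numpy()
    return out


def estimate_scale(windows: pd.DataFrame,
                   baseline: str | set[str] = "all") -> float:
    """Median cov_a/cov_b over baseline windows where both depths are > 0.

    ``baseline`` restricts the estimate to a set of segment ids (e.g.
    putative autosomes); ``"all"`` uses every segment. The scale is applied
    as ratio = cov_a / (scale * cov_b), so equal libraries give scale 1.
    """
    df = windows
    if baseline != "all":
        df = df[df["seg"].isin(baseline)]
    eligible = df[(df["cov_a"] > 0) & (df["cov_b"] > 0)]
    if eligible.empty:
        raise NormalizationError("no window with positive depth in both samples")
    return float(np.median(eligible["cov_a"] / eligible["cov_b"]))


def log2_ratio(cov_a, cov_b, scale: float = 1.0, pseudocount: float = 0.1):
    """Pseudo-counted log2 coverage ratio of sample A over rescaled sample B.

    The scale is split symmetrically between the samples before the
    pseudo-count is added: log2((a/sqrt(s) + p) / (sqrt(s)*b + p)). At
    scale 1 this is the plain log2((a + p)/(b + p)); for any scale it is
    exactly antisymmetric under swapping the samples and inverting the
    scale, which the naive one-sided form is not.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if scale <= 0:
        raise ValueError("scale must be > 0")
    a = np.asarray(cov_a, dtype=float)
    b = np.asarray(cov_b, dtype=float)
    rs = np.sqrt(scale)
    out = np.log2((a / rs + pseudocount) / (b * rs + pseudocount))
    return out if out.ndim else float(out)


def add_ratios(windows: pd.DataFrame, scale: float | None = None,
               pseudocount: float = 0.1,
               baseline: str | set[str] = "all") -> pd.DataFrame:
    """Attach scale and log2 ratio columns to a combined window table."""
    out = windows.copy()
    if scale is None:
        scale = estimate_scale(windows, baseline=baseline)
    out["scale"] = scale
    out["log2_ratio"] = log2_ratio(
        out["cov_a"].to_numpy(), out["cov_b"].to_numpy(),
        scale=scale, pseudocount=pseudocount)
    return out


def flag_windows(windows: pd.DataFrame, enrich_threshold: float = 4.0,
                 absent_depth: float = 2.0) -> pd.DataFrame:
    """Flag windows with |log2 ratio| above threshold and call their class.

    A flagged window whose depleted sample has raw mean depth <= the
    ``absent_depth`` floor is sample-specific (``a_specific`` when cov_b is
    the low one, ``b_specific`` when cov_a is); other flagged windows are
    merely enriched. Partial terminal windows are never flagged.
    """
    if enrich_threshold <= 0 or absent_depth <= 0:
        raise ValueError("thresholds must be > 0")
    out = windows.copy()
    r = out["log2_ratio"].to_numpy()
    flagged = (np.abs(r) > enrich_threshold) & ~out["partial"].to_numpy()
    call = np.full(len(out), "balanced", dtype=object)
    a_low = out["cov_a"].to_numpy() <= absent_depth
    b_low = out["cov_b"].to_numpy() <= absent_depth
    pos, neg = r > 0, r < 0
    call[flagged & pos & b_low] = "a_specific"
    call[flagged & pos & ~b_low] = "a_enriched"
    call[flagged & neg & a_low] = "b_specific"
    call[flagged & neg & ~a_low] = "b_enriched"
    out["flag"] = flagged
    out["call"] = call
    return out


# ---------------------------------------------------------------------------
# regions
# ---------------------------------------------------------------------------

REGION_COLUMNS = ["seg", "start", "end", "n_windows", "mean_log2_ratio", "call"]


def merge_regions(windows: pd.DataFrame, max_gap: int = 0) -> pd.DataFrame:
    """Merge runs of flagged windows with identical calls into regions.

    ``max_gap`` is the number of intervening unflagged (or differently
    called) windows tolerated inside a region; 0 requires adjacency.
    Windows must be sorted by (seg, start).
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    for seg, grp in windows.groupby("seg", sort=False):
        if not grp["start"].is_monotonic_increasing:
            raise InputError(f"windows on {seg} are not sorted by start")
    rows = []
    cur = None  # [seg, start, end, n, ratios, call, gap_run]
    for t in windows.itertuples():
        if not t.flag:
            if cur is not None:
                cur[6] += 1
                if cur[6] > max_gap:
                    rows.append(cur)
                    cur = None
            continue
        if cur is not None and t.seg == cur[0] and t.call == cur[5] \
                and cur[6] <= max_gap:
            cur[2] = t.end
            cur[3] += 1
            cur[4].append(t.log2_ratio)
            cur[6] = 0
        else:
            if cur is not None:
                rows.append(cur)
            cur = [t.seg, t.start, t.end, 1, [t.log2_ratio], t.call, 0]
    if cur is not None:
        rows.append(cur)
    return pd.DataFrame(
        [(r[0], r[1], r[2], r[3], float(np.mean(r[4])), r[5]) for r in rows],
        columns=REGION_COLUMNS)


@dataclass
class RegionSummary:
    n_regions: int
    total_bp: int
    per_call: dict[str, int]


def summarize_regions(regions: pd.DataFrame) -> RegionSummary:
    """Region count, total bp covered, and per-call region counts."""
    if regions.empty:
        return RegionSummary(0, 0, {})
    total = int((regions["end"] - regions["start"]).sum())
    per_call = regions["call"].value_counts().to_dict()
    return RegionSummary(len(regions), total, per_call)


def write_regions_bed(regions: pd.DataFrame, path: str | Path) -> None:
    """Regions as BED: name = call, score = mean ratio x100 clamped 0-1000."""
    with open(path, "w") as fh:
        for t in regions.itertuples():
            score = int(np.clip(abs(t.mean_log2_ratio) * 100, 0, 1000))
            fh.write(f"{t.seg}\t{t.start}\t{t.end}\t{t.call}\t{score}\t.\n")


def read_regions_bed(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise InputError(f"{path}:{lineno}: expected >= 4 BED columns")
            rows.append((parts[0], int(parts[1]), int(parts[2]), parts[3]))
    return pd.DataFrame(rows, columns=["seg", "start", "end", "call"])
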