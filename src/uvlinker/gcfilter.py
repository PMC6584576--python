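"""GC-content screening and k-mer coverage estimation.

The decontamination stage: a plant host at ~45% GC sequenced together with
a microbial community at ~65% GC separates cleanly on read and scaffold GC,
so reads above a GC threshold (default 55%) are discarded — pairs travel
together, because assemblers need intact mates. Scaffold GC bimodality and
the k-mer multiplicity histogram provide the supporting diagnostics.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import InputError, PairingError

_GC_SET = frozenset("GCgc")
_ACGT = frozenset("ACGTacgt")
_RC = str.maketrans("ACGT", "TGCA")


def gc_content(sequence: str) -> float:
    """GC fraction over unambiguous bases, case-insensitive.

    N (or any ambiguity code) is excluded from numerator and denominator;
    a sequence with no A/C/G/T at all has no defined GC content.
    """
    gc = acgt = 0
    for ch in sequence:
        if ch in _ACGT:
            acgt += 1
            if ch in _GC_SET:
                gc += 1
    if acgt == 0:
        raise InputError("sequence has no unambiguous bases; GC undefined")
    return gc / acgt


# ---------------------------------------------------------------------------
# paired-read filtering
# ---------------------------------------------------------------------------

def _open_maybe_gz(path: str | Path, mode: str = "rt"):
    return gzip.open(path, mode) if str(path).endswith(".gz") else open(path, mode)


def _iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (header, sequence, quality) from a FASTQ file (gz accepted)."""
    with _open_maybe_gz(path) as fh:
        while True:
            header = fh.readline().rstrip("\n")
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not qual and not plus:
                raise InputError(f"{path}: truncated FASTQ record")
            yield header, seq, qual


@dataclass
class GcFilterReport:
    """Kept/discarded accounting of one pair-aware GC filtering run."""

    threshold: float
    n_pairs_in: int = 0
    n_pairs_kept: int = 0
    n_pairs_discarded: int = 0
    kept_gc: list[float] = field(default_factory=list)
    discarded_gc: list[float] = field(default_factory=list)

    def histogram(self, which: str = "kept", bins: int = 50
                  ) -> tuple[np.ndarray, np.ndarray]:
        values = self.kept_gc if which == "kept" else self.discarded_gc
        return np.histogram(values, bins=bins, range=(0.0, 1.0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "threshold": self.threshold,
            "pairs_in": self.n_pairs_in,
            "pairs_kept": self.n_pairs_kept,
            "pairs_discarded": self.n_pairs_discarded,
        }])


def filter_reads_by_gc(fastq1: str | Path, fastq2: str | Path,
                       out1: str | Path, out2: str | Path,
                       discard1: str | Path | None = None,
                       discard2: str | Path | None = None,
                       threshold: float = 0.55) -> GcFilterReport:
    """Discard read pairs in which either mate has GC strictly above threshold.

    The comparison is strict (> threshold discarded, == kept), mirroring a
    ">55%" removal rule. Mates are processed in lockstep; unequal record
    counts raise ``PairingError``.
    """
    report = GcFilterReport(threshold=threshold)
    it1, it2 = _iter_fastq(fastq1), _iter_fastq(fastq2)
    sentinel = object()
    with _open_maybe_gz(out1, "wt") as k1, _open_maybe_gz(out2, "wt") as k2:
        d1 = _open_maybe_gz(discard1, "wt") if discard1 else None
        d2 = _open_maybe_gz(discard2, "wt") if discard2 else None
        try:
            while True:
                r1 = next(it1, sentinel)
                r2 = next(it2, sentinel)
                if r1 is sentinel and r2 is sentinel:
                    break
                if r1 is sentinel or r2 is sentinel:
                    raise PairingError("mate files differ in record count")
                report.n_pairs_in += 1
                gc1, gc2 = gc_content(r1[1]), gc_content(r2[1])
                keep = gc1 <= threshold and gc2 <= threshold
                if keep:
                    report.n_pairs_kept += 1
                    report.kept_gc.extend((gc1, gc2))
                    k1.write(f"{r1[0]}\n{r1[1]}\n+\n{r1[2]}\n")
                    k2.write(f"{r2[0]}\n{r2[1]}\n+\n{r2[2]}\n")
                else:
                    report.n_pairs_discarded += 1
                    report.discarded_gc.extend((gc1, gc2))
                    if d1:
                        d1.write(f"{r1[0]}\n{r1[1]}\n+\n{r1[2]}\n")
                    if d2:
                        d2.write(f"{r2[0]}\n{r2[1]}\n+\n{r2[2]}\n")
        finally:
            if d1:
                d1.close()
            if d2:
                d2.close()
    return report


def classify_pairs_by_gc(pairs: Iterable[tuple[str, str]],
                         threshold: float = 0.55) -> np.ndarray:
    """Boolean keep-mask for in-memory (seq1, seq2) pairs (True = kept)."""
    return np.array([
        gc_content(s1) <= threshold and gc_content(s2) <= threshold
        for s1, s2 in pairs])


# ---------------------------------------------------------------------------
# scaffold GC table + bimodality
# ---------------------------------------------------------------------------

@dataclass
class GcRecord:
    id: str
    length: int
    gc: float
    n_count: int


@dataclass
class GcBimodality:
    """Kernel-density summary of a scaffold GC distribution."""

    modes: list[float]          # up to two highest-density GC modes, sorted
    antimode: float | None      # density minimum between the two modes
    bandwidth: float


def _iter_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    name, chunks = None, []
    with _open_maybe_gz(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    yield name, "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        yield name, "".join(chunks)


def scaffold_gc_table(fasta: str | Path | Iterable[tuple[str, str]],
                      bandwidth: float = 0.02,
                      length_weighted: bool = False
                      ) -> tuple[pd.DataFrame, GcBimodality]:
    """Per-scaffold GC records plus a kernel-smoothed bimodality summary.

    ``fasta`` may be a path or an iterable of (id, sequence). The summary
    reports the two highest-density modes of the GC distribution (Gaussian
    kernel of the given absolute bandwidth on a 0.001 grid) and the
    antimode between them; with fewer than two detectable modes the
    antimode is None.
    """
    source = _iter_fasta(fasta) if isinstance(fasta, (str, Path)) else fasta
    records = []
    for name, seq in source:
        n_count = sum(1 for ch in seq if ch not in _ACGT)
        records.append(GcRecord(name, len(seq), gc_content(seq), n_count))
    if not records:
        raise InputError("no scaffolds in input")
    table = pd.DataFrame([r.__dict__ for r in records])

    values = table["gc"].to_numpy()
    weights = table["length"].to_numpy(dtype=float) if length_weighted \
        else np.ones(len(values))
    grid = np.arange(0.0, 1.0005, 0.001)
    density = np.zeros_like(grid)
    for v, w in zip(values, weights):
        density += w * np.exp(-0.5 * ((grid - v) / bandwidth) ** 2)

    peak_idx, _ = find_peaks(density)
    if peak_idx.size == 0:  # single scaffold or fully degenerate input
        modes = [float(grid[int(np.argmax(density))])]
        return table, GcBimodality(modes, None, bandwidth)
    top = peak_idx[np.argsort(density[peak_idx])[::-1][:2]]
    modes = sorted(float(grid[i]) for i in top)
    antimode = None
    if len(modes) == 2:
        lo, hi = (np.searchsorted(grid, modes[0]),
                  np.searchsorted(grid, modes[1]))
        antimode = float(grid[lo + int(np.argmin(density[lo:hi + 1]))])
    return table, GcBimodality(modes, antimode, bandwidth)


# ---------------------------------------------------------------------------
# k-mer histogram + coverage peak
# ---------------------------------------------------------------------------

@dataclass
class KmerHistogram:
    k: int
    counts: dict[int, int]  # multiplicity -> number of distinct k-mers

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.counts.items()), columns=["multiplicity", "count"])


@dataclass
class CoverageEstimate:
    """K-mer-peak coverage estimate and its base-coverage conversion."""

    kmer_peak: int | None
    base_coverage: float | None
    first_minimum: int | None


def _canonical(kmer: str) -> str:
    rc = kmer.translate(_RC)[::-1]
    return kmer if kmer <= rc else rc


def count_kmers(fastq_paths: Iterable[str | Path], k: int = 31
                ) -> KmerHistogram:
    """Canonical k-mer multiplicity histogram over one or more FASTQ files.

    K-mers containing ambiguous bases are skipped (canonicalization is
    undefined over ambiguity codes).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    table: Counter[str] = Counter()
    for path in fastq_paths:
        for _, seq, _ in _iter_fastq(path):
            if len(seq) < k:
                raise ValueError(
                    f"k={k} exceeds read length {len(seq)} in {path}")
            seq = seq.upper()
            for i in range(len(seq) - k + 1):
                kmer = seq[i:i + k]
                if _ACGT.issuperset(kmer):
                    table[_canonical(kmer)] += 1
    hist: Counter[int] = Counter(table.values())
    return KmerHistogram(k=k, counts=dict(hist))


def coverage_from_histogram(hist: KmerHistogram, read_len: int
                            ) -> CoverageEstimate:
    """Peak-based coverage estimate from a k-mer multiplicity histogram.

    Scans from multiplicity 1 upward for the first local minimum (the
    boundary of the error/low-abundance region), then takes the global
    maximum beyond it as the k-mer coverage peak; ties break toward lower
    multiplicity. Base coverage = peak * read_len / (read_len - k + 1).
    """
    if not hist.counts:
        return CoverageEstimate(None, None, None)
    max_mult = max(hist.counts)
    dense = np.zeros(max_mult + 2, dtype=np.int64)
    for mult, cnt in hist.counts.items():
        dense[mult] = cnt
    first_min = None
    for m in range(2, max_mult):
        if dense[m] <= dense[m - 1] and dense[m] <= dense[m + 1]:
            first_min = m
            break
    if first_min is None or first_min >= max_mult:
        return CoverageEstimate(None, None, None)
    tail = dense[first_min + 1:max_mult + 1]
    if tail.max() == 0:
        return CoverageEstimate(None, None, first_min)
    peak = first_min + 1 + int(np.argmax(tail))  # argmax takes first on ties
    base = peak * read_len / (read_len - hist.k + 1)
    return CoverageEstimate(peak, base, first_min)


def kmer_coverage(fastq_paths: Iterable[str | Path], k: int = 31,
                  read_len: int | None = None
                  ) -> tuple[KmerHistogram, CoverageEstimate]:
    """Count canonical k-mers and estimate sequencing coverage in one call."""
    paths = list(fastq_paths)
    if read_len is None:
        for _, seq, _ in _iter_fastq(paths[0]):
            read_len = len(seq)
            break
        if read_len is None:
            raise InputError("cannot infer read length from empty FASTQ")
    if k > read_len:
        raise ValueError(f"k={k} exceeds read length {read_len}")
    hist = count_kmers(paths, k=k)
    return hist, coverage_from_histogram(hist, read_len)
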