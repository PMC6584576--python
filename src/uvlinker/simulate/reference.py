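"""Reference genome simulation: labelled segments, genes, and a truth table.

Base composition is i.i.d. per site at the target GC of the segment's
compartment (host vs contaminant); genes are fixed-length, non-overlapping
intervals placed on the segment their class calls for. The truth table maps
every base of every segment to its compartment class, which is what the
recovery tests score against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ..errors import ConfigError
from .config import GENE_CLASS_SEGMENTS, SimConfig

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class Segment:
    id: str
    sequence: str
    label: str  # one of SEGMENT_CLASSES

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GeneRecord:
    gene_id: str
    segment: str
    start: int  # 0-based half-open
    end: int
    strand: str
    gene_class: str


@dataclass
class ReferenceSet:
    """Segments + genes + per-interval truth labels of one simulated genome."""

    segments: list[Segment]
    genes: list[GeneRecord]
    truth: pd.DataFrame  # columns seg, start, end, label (0-based half-open)

    def segment(self, seg_id: str) -> Segment:
        return self._index()[seg_id]

    def _index(self) -> dict[str, Segment]:
        return {s.id: s for s in self.segments}

    @property
    def segment_lengths(self) -> dict[str, int]:
        return {s.id: s.length for s in self.segments}

    def segments_for_sex(self, sex: str) -> list[Segment]:
        """Segments physically present in a plant of the given sex."""
        if sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
        drop = "U" if sex == "male" else "V"
        return [s for s in self.segments if s.label != drop]

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for seg in self.segments:
                fh.write(f">{seg.id} class={seg.label}\n")
                for i in range(0, seg.length, width):
                    fh.write(seg.sequence[i:i + width] + "\n")

    def write_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for g in self.genes:
                attrs = f"ID={g.gene_id};gene_class={g.gene_class}"
                fh.write("\t".join([
                    g.segment, "uvlinker_sim", "gene",
                    str(g.start + 1), str(g.end), ".", g.strand, ".", attrs,
                ]) + "\n")

    def write_truth_bed(self, path: str | Path) -> None:
        self.truth.to_csv(path, sep="\t", header=False, index=False)


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode("ascii")


def _place_genes(seg: Segment, n: int, gene_len: int, gene_class: str,
                 start_index: int) -> list[GeneRecord]:
    """Evenly spaced, non-overlapping fixed-length genes on one segment."""
    if n == 0:
        return []
    if n * gene_len > seg.length:
        raise ConfigError(
            f"{n} genes of {gene_len} bp do not fit on {seg.id} "
            f"({seg.length} bp)")
    slot = seg.length // n
    genes = []
    for i in range(n):
        start = i * slot + (slot - gene_len) // 2
        genes.append(GeneRecord(
            gene_id=f"{gene_class}_{start_index + i + 1:03d}",
            segment=seg.id, start=start, end=start + gene_len,
            strand="+", gene_class=gene_class,
        ))
    return genes


def simulate_reference(config: SimConfig) -> ReferenceSet:
    """Draw a labelled reference genome from a configuration.

    Deterministic in ``config.seed``: the same configuration always yields
    byte-identical FASTA/GFF3/BED outputs.
    """
    rng = np.random.default_rng(config.seed)
    segments: list[Segment] = []
    for i in range(config.n_autosomes):
        segments.append(Segment(
            f"chr{i + 1}",
            _random_sequence(rng, config.autosome_len, config.host_gc),
            "autosome"))
    if config.u_len > 0:
        segments.append(Segment(
            "chrU", _random_sequence(rng, config.u_len, config.host_gc), "U"))
    if config.v_len > 0:
        segments.append(Segment(
            "chrV", _random_sequence(rng, config.v_len, config.host_gc), "V"))
    for i, length in enumerate(config.organelle_lens):
        label = "mito" if i == 0 else "chloro"
        name = label if i < 2 else f"organelle{i + 1}"
        segments.append(Segment(
            name, _random_sequence(rng, length, config.host_gc), label))
    for i in range(config.n_contaminants):
        segments.append(Segment(
            f"contam{i + 1}",
            _random_sequence(rng, config.contam_len, config.contam_gc),
            "contaminant"))
    if not segments:
        raise ConfigError("configuration describes an empty genome")

    by_label: dict[str, list[Segment]] = {}
    for seg in segments:
        by_label.setdefault(seg.label, []).append(seg)

    genes: list[GeneRecord] = []
    for gene_class, n in config.n_genes_per_class.items():
        if n == 0:
            continue
        seg_label = GENE_CLASS_SEGMENTS[gene_class]
        targets = by_label.get(seg_label, [])
        if not targets:
            continue  # class requested but its chromosome absent: skip
        # paired-allele classes share the same relative slots on U and V;
        # spread other classes round-robin over the available segments
        per_seg = [n // len(targets) + (1 if i < n % len(targets) else 0)
                   for i in range(len(targets))]
        offset = 0
        for seg, n_seg in zip(targets, per_seg):
            genes.extend(_place_genes(seg, n_seg, config.gene_len,
                                      gene_class, offset))
            offset += n_seg

    # alleles of the same rank on U and V must not collide with the
    # sex-specific genes placed there: shift allele genes into the gaps
    genes = _resolve_overlaps(genes, {s.id: s.length for s in segments})

    truth = pd.DataFrame(
        [(s.id, 0, s.length, s.label) for s in segments],
        columns=["seg", "start", "end", "label"],
    )
    return ReferenceSet(segments=segments, genes=genes, truth=truth)


def _resolve_overlaps(genes: list[GeneRecord], seg_lens: dict[str, int]
                      ) -> list[GeneRecord]:
    """Shift genes right until no two genes on a segment overlap."""
    out: list[GeneRecord] = []
    by_seg: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_seg.setdefault(g.segment, []).append(g)
    for seg_id, glist in by_seg.items():
        glist.sort(key=lambda g: (g.start, g.gene_id))
        cursor = 0
        for g in glist:
            start = max(g.start, cursor)
            end = start + (g.end - g.start)
            if end > seg_lens[seg_id]:
                raise ConfigError(
                    f"genes overflow segment {seg_id}: reduce counts or length")
            out.append(GeneRecord(g.gene_id, seg_id, start, end,
                                  g.strand, g.gene_class))
            cursor = end
    out.sort(key=lambda g: (g.segment, g.start))
    return out
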