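"""Small readers shared by the CLI and the cascade: GFF3 genes, class maps."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import InputError


def read_gff3_genes(path: str | Path, feature: str = "gene") -> pd.DataFrame:
    """Gene records from a GFF3 file as a frame with 0-based half-open
    coordinates (columns gene_id, seg, start, end, strand, gene_class)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise InputError(f"{path}:{lineno}: expected 9 GFF3 columns")
            if parts[2] != feature:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv)
            rows.append({
                "gene_id": attrs.get("ID", f"{parts[0]}:{parts[3]}"),
                "seg": parts[0],
                "start": int(parts[3]) - 1,   # GFF3 is 1-based inclusive
                "end": int(parts[4]),
                "strand": parts[6],
                "gene_class": attrs.get("gene_class", ""),
            })
    return pd.DataFrame(
        rows, columns=["gene_id", "seg", "start", "end", "strand",
                       "gene_class"])


def read_class_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV subject_id -> chromosome class."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise InputError(f"{path}:{lineno}: expected 2 columns")
            out[parts[0]] = parts[1]
    return out


def read_fasta_dict(path: str | Path) -> dict[str, str]:
    """Whole-file FASTA into an id -> sequence dict (ids cut at whitespace)."""
    from .gcfilter import _iter_fasta

    return {name: seq for name, seq in _iter_fasta(path)}
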