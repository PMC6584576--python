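"""From differential-coverage regions to sex-marker candidates.

A region with sex-specific coverage becomes a credible marker candidate
when its scaffold also carries a predicted gene, that gene has a homolog in
a related reference genome, and the homolog's chromosome class agrees with
the coverage call (male-specific coverage + V-chromosome homolog, or
female-specific + U). Each region is annotated with the furthest stage it
reaches; discordant combinations are kept and noted, never dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import InputError

BLAST_COLUMNS = [
    "query", "subject", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

CASCADE_STAGES = ("region_only", "has_gene", "has_homolog", "sex_concordant")


# ---------------------------------------------------------------------------
# homology hits
# ---------------------------------------------------------------------------

def read_blast_table(path: str | Path) -> pd.DataFrame:
    """Parse a 12-column blast-like TSV (outfmt 6); strict about columns."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise InputError(
                    f"{path}:{lineno}: expected 12 columns, got {len(parts)}")
            try:
                rows.append((
                    parts[0], parts[1], float(parts[2]), int(parts[3]),
                    int(parts[4]), int(parts[5]), int(parts[6]), int(parts[7]),
                    int(parts[8]), int(parts[9]), float(parts[10]),
                    float(parts[11])))
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: {exc}") from None
    return pd.DataFrame(rows, columns=BLAST_COLUMNS)


def best_hit(hits: pd.DataFrame) -> pd.DataFrame:
    """Single best hit per query: max bitscore, ties by lower e-value, then
    lexicographically smallest subject id. Fully deterministic."""
    if hits.empty:
        return hits.copy()
    ordered = hits.sort_values(
        ["query", "bitscore", "evalue", "subject"],
        ascending=[True, False, True, True],
        kind="mergesort")
    return ordered.groupby("query", sort=True).head(1).reset_index(drop=True)


# ---------------------------------------------------------------------------
# cascade
# ---------------------------------------------------------------------------

@dataclass
class MarkerCandidate:
    seg: str
    start: int
    end: int
    call: str                     # coverage call of the region (a_* = male)
    gene_id: str | None
    homolog_id: str | None
    homolog_class: str            # U, V, autosome, organelle, unknown
    cascade_stage: str
    sex_prediction: str | None    # male / female, sex_concordant only
    note: str = ""


def _region_sex(call: str) -> str | None:
    # A = male, B = female convention
    if call == "a_specific":
        return "male"
    if call == "b_specific":
        return "female"
    return None


def cascade(regions: pd.DataFrame, genes: pd.DataFrame,
            besthits: pd.DataFrame, ref_classes: dict[str, str],
            max_distance: int | None = None
            ) -> tuple[list[MarkerCandidate], dict[str, int]]:
    """Annotate each region with the furthest filter stage it reaches.

    ``regions`` needs columns seg/start/end/call; ``genes`` columns
    gene_id/seg/start/end; ``besthits`` is a best-hit table keyed by query
    (gene id); ``ref_classes`` maps homology subject ids to the chromosome
    class of the related reference (U, V, autosome, ...). By default a gene
    anywhere on the region's scaffold counts; ``max_distance`` restricts to
    genes within that many bp of the region.

    Returns the candidates plus cumulative stage counts, which are monotone
    non-increasing along the cascade.
    """
    hit_by_gene = {}
    if not besthits.empty:
        hit_by_gene = besthits.set_index("query")["subject"].to_dict()

    genes_by_seg: dict[str, pd.DataFrame] = {
        str(seg): grp for seg, grp in genes.groupby("seg")
    } if not genes.empty else {}

    candidates: list[MarkerCandidate] = []
    for t in regions.itertuples():
        seg_genes = genes_by_seg.get(t.seg)
        gene_id = homolog = None
        homolog_class = "unknown"
        stage = "region_only"
        prediction = None
        note = ""
        if seg_genes is not None and not seg_genes.empty:
            sel = seg_genes
            if max_distance is not None:
                near = (sel["start"] < t.end + max_distance) & \
                       (sel["end"] > t.start - max_distance)
                sel = sel[near]
            if not sel.empty:
                # prefer the gene nearest the region midpoint, deterministically
                mid = (t.start + t.end) / 2
                dist = ((sel["start"] + sel["end"]) / 2 - mid).abs()
                order = sel.assign(_d=dist).sort_values(
                    ["_d", "gene_id"], kind="mergesort")
                # prefer a gene that has a homolog, if any does
                with_hit = order[order["gene_id"].isin(hit_by_gene)]
                chosen = (with_hit if not with_hit.empty else order).iloc[0]
                gene_id = str(chosen["gene_id"])
                stage = "has_gene"
        if gene_id is not None and gene_id in hit_by_gene:
            homolog = hit_by_gene[gene_id]
            homolog_class = ref_classes.get(homolog, "unknown")
            stage = "has_homolog"
            sex = _region_sex(t.call)
            if sex == "male" and homolog_class == "V":
                stage = "sex_concordant"
                prediction = "male"
            elif sex == "female" and homolog_class == "U":
                stage = "sex_concordant"
                prediction = "female"
            elif homolog_class in ("U", "V"):
                note = "discordant"
        candidates.append(MarkerCandidate(
            seg=t.seg, start=int(t.start), end=int(t.end), call=t.call,
            gene_id=gene_id, homolog_id=homolog,
            homolog_class=homolog_class, cascade_stage=stage,
            sex_prediction=prediction, note=note))

    order = {s: i for i, s in enumerate(CASCADE_STAGES)}
    counts = {s: 0 for s in CASCADE_STAGES}
    for c in candidates:
        for s in CASCADE_STAGES[:order[c.cascade_stage] + 1]:
            counts[s] += 1
    return candidates, counts


def cascade_report(candidates: list[MarkerCandidate]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in candidates])


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def export_candidates(candidates: list[MarkerCandidate],
                      sequences: dict[str, str],
                      bed_path: str | Path, fasta_path: str | Path) -> None:
    """Write sex-concordant candidates as BED + FASTA for primer design.

    FASTA ids encode segment:start-end:sex; the BED name column carries the
    sex prediction. Deterministic: candidates are emitted in (seg, start)
    order.
    """
    selected = [c for c in candidates if c.cascade_stage == "sex_concordant"]
    selected.sort(key=lambda c: (c.seg, c.start, c.end))
    for c in selected:
        if c.seg not in sequences:
            raise InputError(f"unknown segment {c.seg}")
        if c.end > len(sequences[c.seg]) or c.start < 0:
            raise InputError(
                f"region {c.seg}:{c.start}-{c.end} exceeds segment bounds")
    with open(bed_path, "w") as bed, open(fasta_path, "w") as fa:
        for c in selected:
            bed.write(f"{c.seg}\t{c.start}\t{c.end}\t{c.sex_prediction}\n")
            fa.write(f">{c.seg}:{c.start}-{c.end}:{c.sex_prediction}\n")
            fa.write(sequences[c.seg][c.start:c.end] + "\n")
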