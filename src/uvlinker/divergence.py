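"""Pairwise molecular divergence: codon alignments, NG86 dN/dS, %identity.

The estimator is the Nei–Gojobori (1986) counting method: synonymous and
nonsynonymous *sites* are mutational-fate fractions summed over codon
positions, observed differences are classified by averaging over all legal
substitution pathways between the two codons, and the resulting proportions
are corrected for multiple hits with the Jukes–Cantor formula. Changes that
would create a stop codon are excluded from site denominators and pathways
through stop codons are skipped, on both the site and the difference side,
so S + N = 3L holds exactly for L retained codons.

A transition/transversion-weighted variant (kappa > 1 up-weights transitions
in both site fractions and pathway averaging) is available through the
``kappa`` argument of :func:`dnds`; the unweighted NG86 counting is the
default contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd

from .codontab import (
    STOP_CODONS,
    codon_neighbors,
    is_stop,
    is_transition,
    translate,
)
from .errors import ConsistencyError, FrameError, InputError, SaturationError

GENE_CLASSES = (
    "autosomal",
    "male_specific",
    "female_specific",
    "male_allele",
    "female_allele",
    "mitochondrial",
    "chloroplast",
)

#: pseudo-ratio added to omega == 0 before log transformation
LOG_OMEGA_EPSILON = 1e-4


# ---------------------------------------------------------------------------
# codon alignment construction
# ---------------------------------------------------------------------------

@dataclass
class CodonAlignment:
    """A gap- and stop-stripped pair of aligned coding sequences.

    ``seq_a``/``seq_b`` are equal-length, length divisible by 3, and contain
    no internal stop codons. ``keep_mask`` has one boolean per column of the
    *protein* alignment the object was built from (True = codon retained).
    """

    seq_a: str
    seq_b: str
    keep_mask: list[bool] = field(default_factory=list)
    n_removed_gap: int = 0
    n_removed_stop: int = 0

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise InputError("aligned CDS rows differ in length")
        if len(self.seq_a) % 3:
            raise InputError("aligned CDS length not divisible by 3")

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3

    def codon_pairs(self):
        a, b = self.seq_a.upper(), self.seq_b.upper()
        for i in range(0, len(a), 3):
            yield a[i:i + 3], b[i:i + 3]


def backtranslate_align(prot_a: str, prot_b: str, cds_a: str, cds_b: str
                        ) -> CodonAlignment:
    """Expand a pairwise protein alignment to its codon alignment.

    Each amino-acid column is replaced by the source codon; columns gapped in
    either row and columns where either codon is a stop are removed (the
    mask records both kinds of removal).

    Raises ``FrameError`` when a CDS length is not three times its ungapped
    protein length and ``ConsistencyError`` when the CDS does not translate
    to the protein row.
    """
    if len(prot_a) != len(prot_b):
        raise InputError("protein alignment rows differ in length")
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    # tolerate a trailing stop codon on the CDS
    for name in ("a", "b"):
        prot = {"a": prot_a, "b": prot_b}[name]
        cds = {"a": cds_a, "b": cds_b}[name]
        ungapped = len(prot) - prot.count("-")
        if len(cds) == 3 * (ungapped + 1) and is_stop(cds[-3:]):
            cds = cds[:-3]
            if name == "a":
                cds_a = cds
            else:
                cds_b = cds
        if len(cds) != 3 * ungapped:
            raise FrameError(
                f"CDS {name}: length {len(cds)} != 3 x {ungapped} residues")

    def codons_for(prot: str, cds: str) -> list[str]:
        out, j = [], 0
        for col, aa in enumerate(prot):
            if aa == "-":
                out.append(None)
                continue
            codon = cds[3 * j:3 * j + 3]
            trans = translate(codon)
            if trans != aa.upper() and not (trans == "*" and aa == "*"):
                raise ConsistencyError(
                    f"residue {j + 1} (column {col + 1}): codon {codon} "
                    f"translates to {trans}, protein says {aa}")
            out.append(codon)
            j += 1
        return out

    cod_a = codons_for(prot_a, cds_a)
    cod_b = codons_for(prot_b, cds_b)

    kept_a, kept_b, mask = [], [], []
    n_gap = n_stop = 0
    for ca, cb in zip(cod_a, cod_b):
        if ca is None or cb is None:
            mask.append(False)
            n_gap += 1
        elif is_stop(ca) or is_stop(cb):
            mask.append(False)
            n_stop += 1
        else:
            mask.append(True)
            kept_a.append(ca)
            kept_b.append(cb)
    return CodonAlignment("".join(kept_a), "".join(kept_b), mask, n_gap, n_stop)


def codon_alignment_from_cds(cds_a: str, cds_b: str) -> CodonAlignment:
    """Codon alignment for two already length-matched, gapless CDS."""
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    if len(cds_a) != len(cds_b):
        raise InputError("CDS pair differs in length; align first")
    if len(cds_a) % 3:
        raise InputError("CDS length not divisible by 3")
    kept_a, kept_b, mask = [], [], []
    n_stop = 0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i:i + 3], cds_b[i:i + 3]
        if is_stop(ca) or is_stop(cb):
            mask.append(False)
            n_stop += 1
        else:
            mask.append(True)
            kept_a.append(ca)
            kept_b.append(cb)
    return CodonAlignment("".join(kept_a), "".join(kept_b), mask, 0, n_stop)


# ---------------------------------------------------------------------------
# NG86 counting
# ---------------------------------------------------------------------------

def _mutation_weight(src: str, dst: str, kappa: float) -> float:
    return kappa if is_transition(src, dst) else 1.0


def ng86_sites(codon: str, kappa: float = 1.0) -> tuple[float, float]:
    """Synonymous and nonsynonymous site fractions of one codon.

    For each position, the fraction of possible point mutations that are
    synonymous; mutations creating stop codons are excluded from the
    denominator. With ``kappa`` > 1 transitions carry weight kappa and
    transversions weight 1. Returns (s, n) with s + n == 3.
    """
    codon = codon.upper()
    if is_stop(codon):
        raise ValueError(f"stop codon {codon} has no site decomposition")
    aa = translate(codon)
    s = 0.0
    for pos in range(3):
        syn_w = tot_w = 0.0
        for p, base, mutant in codon_neighbors(codon):
            if p != pos or mutant in STOP_CODONS:
                continue
            w = _mutation_weight(codon[pos], base, kappa)
            tot_w += w
            if translate(mutant) == aa:
                syn_w += w
        if tot_w > 0:
            s += syn_w / tot_w
        # a position whose three mutants are all stops cannot occur in the
        # standard code, so tot_w == 0 never happens for sense codons
    return s, 3.0 - s


def ng86_diffs(codon_a: str, codon_b: str, kappa: float = 1.0
               ) -> tuple[float, float]:
    """Synonymous/nonsynonymous difference counts between two sense codons.

    All orderings of the differing positions are enumerated (1, 2 or 6
    pathways); pathways passing through a stop codon are skipped; the
    synonymous and nonsynonymous step counts are averaged over the legal
    pathways. With ``kappa`` > 1 pathways are weighted by the product of
    their per-step mutation weights. If every pathway passes through a stop
    (possible only for 2-3 differences), the average is taken over all
    pathways instead so that sd + nd always equals the number of differing
    positions.
    """
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    if is_stop(codon_a) or is_stop(codon_b):
        raise ValueError("stop codons are not comparable")
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order: tuple[int, ...], forbid_stops: bool):
        sd = nd = 0.0
        weight = 1.0
        cur = codon_a
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if forbid_stops and nxt in STOP_CODONS:
                return None
            weight *= _mutation_weight(cur[pos], codon_b[pos], kappa)
            if nxt not in STOP_CODONS and translate(nxt) == translate(cur):
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return sd, nd, weight

    for forbid in (True, False):
        acc_s = acc_n = acc_w = 0.0
        for order in permutations(diff_pos):
            res = walk(order, forbid)
            if res is None:
                continue
            sd, nd, w = res
            acc_s += sd * w
            acc_n += nd * w
            acc_w += w
        if acc_w > 0:
            return acc_s / acc_w, acc_n / acc_w
    raise AssertionError("unreachable: unrestricted pathways always exist")


def jc_correct(p: float) -> float:
    """Jukes–Cantor multiple-hit correction d = -(3/4) ln(1 - 4p/3).

    Raises ``SaturationError`` for p >= 3/4 (the correction diverges).
    """
    if p < 0:
        raise ValueError(f"proportion {p} < 0")
    if p >= 0.75:
        raise SaturationError(f"proportion {p} >= 3/4: distance undefined")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


# ---------------------------------------------------------------------------
# per-ortholog estimate
# ---------------------------------------------------------------------------

@dataclass
class DnDsEstimate:
    """NG86 counting summary for one ortholog pair."""

    gene_id: str
    gene_class: str | None
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float | None
    dN: float | None
    omega: float | None
    flags: set[str] = field(default_factory=set)
    log_omega: float | None = None

    def as_row(self) -> dict:
        return {
            "gene": self.gene_id, "class": self.gene_class,
            "S": self.S, "N": self.N, "Sd": self.Sd, "Nd": self.Nd,
            "pS": self.pS, "pN": self.pN, "dS": self.dS, "dN": self.dN,
            "omega": self.omega, "flags": ",".join(sorted(self.flags)),
        }


def estimate_kappa(alignment: CodonAlignment, default: float = 2.0) -> float:
    """Transition/transversion ratio from fourfold-degenerate third positions.

    Counts transitions and transversions at third positions of codon pairs
    whose first two bases match and whose third position is fourfold
    degenerate in that context. Returns ``default`` when no transversion (or
    no difference at all) is observed.
    """
    ts = tv = 0
    for ca, cb in alignment.codon_pairs():
        if ca[:2] != cb[:2] or ca[2] == cb[2]:
            continue
        stem = ca[:2]
        aas = {translate(stem + b) for b in "ACGT"}
        if len(aas) != 1:
            continue
        if is_transition(ca[2], cb[2]):
            ts += 1
        else:
            tv += 1
    if tv == 0:
        return default
    return max(ts / tv, 1.0)


def dnds(alignment: CodonAlignment, gene_id: str = "",
         gene_class: str | None = None,
         kappa: float | str | None = None) -> DnDsEstimate:
    """Pairwise dN/dS for one codon alignment by NG86 counting.

    S and N are averaged over the two sequences; Sd and Nd are summed over
    codon pairs; proportions are Jukes–Cantor corrected. ``kappa`` selects
    the transition-weighted variant: a float uses that weight, ``"auto"``
    estimates it from fourfold-degenerate sites (default 2 when
    inestimable), and None (default) is plain NG86.
    """
    if alignment.n_codons == 0:
        raise InputError("empty codon alignment: no retained codons")
    if kappa == "auto":
        kappa = estimate_kappa(alignment)
    k = 1.0 if kappa is None else float(kappa)
    if k < 1.0:
        raise ValueError(f"kappa {k} < 1")

    s_a = n_a = s_b = n_b = sd = nd = 0.0
    for ca, cb in alignment.codon_pairs():
        sa, na = ng86_sites(ca, k)
        sb, nb = ng86_sites(cb, k)
        s_a += sa
        n_a += na
        s_b += sb
        n_b += nb
        d_s, d_n = ng86_diffs(ca, cb, k)
        sd += d_s
        nd += d_n
    S = (s_a + s_b) / 2.0
    N = (n_a + n_b) / 2.0
    pS = sd / S if S > 0 else 0.0
    pN = nd / N if N > 0 else 0.0

    flags: set[str] = set()
    dS = dN = omega = None
    try:
        dS = jc_correct(pS)
    except SaturationError:
        flags.add("pS_saturated")
    try:
        dN = jc_correct(pN)
    except SaturationError:
        flags.add("pN_saturated")
    if dS is not None and dS == 0.0:
        flags.add("dS_zero")
    if dN is not None and dN > 2.0:
        flags.add("dN_gt2")
    if dS is not None and dN is not None and dS > 0.0:
        omega = dN / dS
        if omega > 10.0:
            flags.add("omega_gt10")
    return DnDsEstimate(gene_id, gene_class, S, N, sd, nd, pS, pN,
                        dS, dN, omega, flags)


def filter_estimates(estimates: list[DnDsEstimate]
                     ) -> tuple[list[DnDsEstimate], list[tuple[DnDsEstimate, str]]]:
    """Apply the removal conventions: drop dS = 0, dN > 2 and omega > 10.

    Saturated estimates (undefined dS or dN) are also removed, with their
    saturation flag as the reason. Retained estimates get ``log_omega``
    (natural log; omega == 0 entries receive log(omega + 1e-4)).
    Returns (retained, removed-with-reason).
    """
    retained: list[DnDsEstimate] = []
    removed: list[tuple[DnDsEstimate, str]] = []
    for est in estimates:
        reason = None
        for flag in ("pS_saturated", "pN_saturated", "dS_zero",
                     "dN_gt2", "omega_gt10"):
            if flag in est.flags:
                reason = flag
                break
        if reason is not None:
            removed.append((est, reason))
            continue
        w = est.omega
        est.log_omega = math.log(w + LOG_OMEGA_EPSILON) if w == 0 else math.log(w)
        retained.append(est)
    return retained, removed


def estimates_to_frame(estimates: list[DnDsEstimate]) -> pd.DataFrame:
    return pd.DataFrame([e.as_row() for e in estimates])


# ---------------------------------------------------------------------------
# percent identity
# ---------------------------------------------------------------------------

def percent_identity(row_a: str, row_b: str) -> tuple[float, int]:
    """%ID of one pairwise alignment and the number of aligned columns.

    Columns gapped in both rows are excluded; a column gapped in exactly one
    row counts as a mismatch. Case-insensitive.
    """
    if len(row_a) != len(row_b):
        raise InputError("alignment rows differ in length")
    a, b = row_a.upper(), row_b.upper()
    matches = cols = 0
    for x, y in zip(a, b):
        if x == "-" and y == "-":
            continue
        cols += 1
        if x == y:
            matches += 1
    if cols == 0:
        raise InputError("alignment has no non-gap columns")
    return 100.0 * matches / cols, cols


@dataclass
class IdentitySummary:
    """Per-class aggregation of pairwise %ID values."""

    seq_class: str
    n: int
    total_bp: int
    mean: float
    se: float | None
    length_weighted_mean: float


def summarize_identity(values: list[tuple[float, int]], seq_class: str
                       ) -> IdentitySummary:
    """Aggregate (%ID, aligned bp) pairs of one sequence class."""
    if not values:
        raise InputError(f"no alignments for class {seq_class}")
    ids = np.array([v[0] for v in values], dtype=float)
    lens = np.array([v[1] for v in values], dtype=float)
    se = float(ids.std(ddof=1) / math.sqrt(len(ids))) if len(ids) > 1 else None
    return IdentitySummary(
        seq_class=seq_class,
        n=len(ids),
        total_bp=int(lens.sum()),
        mean=float(ids.mean()),
        se=se,
        length_weighted_mean=float(np.average(ids, weights=lens)),
    )
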