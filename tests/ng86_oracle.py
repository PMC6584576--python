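"""Independent brute-force Nei–Gojobori oracle used only by tests.

Deliberately written without reference to the package internals: the
genetic code comes from Biopython, pathway enumeration is recursive, and
everything is computed per call with no tables. Slow but transparent.
"""

from math import log

from Bio.Seq import Seq

STOPS = {"TAA", "TAG", "TGA"}
BASES = "ACGT"


def aa(codon: str) -> str:
    return str(Seq(codon).translate())


def site_fractions(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon."""
    assert codon not in STOPS
    syn_total = 0.0
    for pos in range(3):
        syn = tot = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if mut in STOPS:
                continue
            tot += 1
            if aa(mut) == aa(codon):
                syn += 1
        syn_total += syn / tot
    return syn_total, 3.0 - syn_total


def _paths(cur: str, target: str, allow_stops: bool):
    """Yield (sd, nd) for every substitution pathway cur -> target."""
    diffs = [i for i in range(3) if cur[i] != target[i]]
    if not diffs:
        yield (0.0, 0.0)
        return
    for i in diffs:
        nxt = cur[:i] + target[i] + cur[i + 1:]
        if nxt in STOPS and not allow_stops:
            continue
        step_syn = nxt not in STOPS and aa(nxt) == aa(cur)
        for sd, nd in _paths(nxt, target, allow_stops):
            yield (sd + (1.0 if step_syn else 0.0),
                   nd + (0.0 if step_syn else 1.0))


def diff_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (sd, nd); stop-free pathways preferred."""
    results = list(_paths(codon_a, codon_b, allow_stops=False))
    if not results:
        results = list(_paths(codon_a, codon_b, allow_stops=True))
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return sd, nd


def dnds_counts(seq_a: str, seq_b: str) -> dict:
    """S, N, Sd, Nd, pS, pN and (where defined) dS, dN for a codon pair."""
    assert len(seq_a) == len(seq_b) and len(seq_a) % 3 == 0
    S = N = Sd = Nd = 0.0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i:i + 3], seq_b[i:i + 3]
        sa, na = site_fractions(ca)
        sb, nb = site_fractions(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        sd, nd = diff_counts(ca, cb)
        Sd += sd
        Nd += nd
    out = {"S": S, "N": N, "Sd": Sd, "Nd": Nd,
           "pS": Sd / S if S else 0.0, "pN": Nd / N if N else 0.0}
    for key, p in (("dS", out["pS"]), ("dN", out["pN"])):
        out[key] = None if p >= 0.75 else -0.75 * log(1 - 4 * p / 3)
    return out
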