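"""Codon-pair evolution under a controlled dN/dS.

Each ortholog pair descends from a random sense-codon ancestor; the two
lineages evolve independently for half the requested divergence under a
continuous-time Markov process on the 61 sense codons in which every single
nucleotide change carries weight kappa when it is a transition (1
otherwise) times omega when it is nonsynonymous (1 otherwise). Stop codons
are simply absent from the state space, so they are never introduced.
Rates are normalized so that one unit of time corresponds to one expected
substitution per codon site at the uniform codon distribution; events are
drawn site by site with exponential waiting times (a vectorized Gillespie
scheme), which gives exact control of the realized omega.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ..codontab import SENSE_CODONS, codon_neighbors, is_transition

_N_SENSE = len(SENSE_CODONS)


@dataclass
class OrthologPair:
    gene_id: str
    cds_a: str
    cds_b: str
    omega_truth: float

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.gene_id}_a\n{self.cds_a}\n")
            fh.write(f">{self.gene_id}_b\n{self.cds_b}\n")


def _rate_tables(omega: float, kappa: float
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-codon total rates, neighbor cumulative probabilities, targets.

    Rates are scaled so the mean total rate over a uniform distribution of
    sense codons is 1 (one expected substitution per codon per time unit).
    """
    from ..codontab import CODON_INDEX, STOP_CODONS, translate

    max_nb = 9
    targets = np.zeros((_N_SENSE, max_nb), dtype=np.int64)
    weights = np.zeros((_N_SENSE, max_nb), dtype=float)
    for i, codon in enumerate(SENSE_CODONS):
        aa = translate(codon)
        k = 0
        for pos, base, mutant in codon_neighbors(codon):
            if mutant in STOP_CODONS:
                continue
            w = kappa if is_transition(codon[pos], base) else 1.0
            if translate(mutant) != aa:
                w *= omega
            targets[i, k] = CODON_INDEX[mutant]
            weights[i, k] = w
            k += 1
    totals = weights.sum(axis=1)
    mean_rate = totals.mean()
    if mean_rate == 0:
        # omega == 0 and a codon set with no synonymous moves cannot occur
        # for the full sense set, but guard the all-zero case anyway
        return totals, np.ones_like(weights), targets
    totals = totals / mean_rate
    with np.errstate(invalid="ignore", divide="ignore"):
        cum = np.cumsum(weights, axis=1)
        denom = cum[:, -1][:, None]
        cum = np.where(denom > 0, cum / denom, 1.0)
    return totals, cum, targets


def _evolve(states: np.ndarray, t: float, totals: np.ndarray,
            cum: np.ndarray, targets: np.ndarray,
            rng: np.random.Generator) -> np.ndarray:
    """Evolve codon states in place for time t; returns the array."""
    if t <= 0:
        return states
    remaining = np.full(states.shape, float(t))
    active = np.nonzero(totals[states] > 0)[0]
    while active.size:
        lam = totals[states[active]]
        waits = rng.exponential(1.0, size=active.size) / lam
        remaining[active] -= waits
        fired = remaining[active] > 0
        active = active[fired]
        if active.size == 0:
            break
        u = rng.random(active.size)
        rows = cum[states[active]]
        choice = (u[:, None] > rows).sum(axis=1)
        states[active] = targets[states[active], choice]
        zero = totals[states[active]] == 0
        if zero.any():
            active = active[~zero]
    return states


def simulate_ortholog_pairs(n: int, omega: float, kappa: float, t: float,
                            L: int, seed: int) -> list[OrthologPair]:
    """Simulate ``n`` ortholog CDS pairs of ``L`` codons at divergence ``t``.

    ``t`` is the expected total number of substitutions per codon site
    separating the two sequences (each lineage runs for t/2). ``omega`` is
    the nonsynonymous/synonymous rate ratio, ``kappa`` the
    transition/transversion weight.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if omega < 0:
        raise ValueError("omega must be >= 0")
    if kappa < 1:
        raise ValueError("kappa must be >= 1")
    if t < 0:
        raise ValueError("divergence t must be >= 0")
    rng = np.random.default_rng(seed)
    totals, cum, targets = _rate_tables(omega, kappa)
    codon_arr = np.array(SENSE_CODONS)
    pairs = []
    for i in range(n):
        ancestor = rng.integers(0, _N_SENSE, size=L)
        a = _evolve(ancestor.copy(), t / 2.0, totals, cum, targets, rng)
        b = _evolve(ancestor.copy(), t / 2.0, totals, cum, targets, rng)
        pairs.append(OrthologPair(
            gene_id=f"orth{i + 1:04d}",
            cds_a="".join(codon_arr[a]),
            cds_b="".join(codon_arr[b]),
            omega_truth=omega,
        ))
    return pairs
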