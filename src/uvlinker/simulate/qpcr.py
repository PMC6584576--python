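"""Synthetic qPCR quantitation-cycle (Cq) tables.

Emulates a factorial expression assay: several plants of each sex measured
for a panel of genes under hydrated and dehydrated conditions, with one
internal-control (housekeeping) gene. Sex-specific genes do not amplify in
the opposite sex (missing Cq); induced genes shift their Cq under
dehydration (one cycle lower per doubling of template); Gaussian technical
noise is added on the cycle scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..errors import ConfigError

STATES = ("hydrated", "dehydrated")


def simulate_cq_table(genes: dict[str, str],
                      effects: dict[str, float] | None = None,
                      seed: int = 0,
                      control_gene: str = "actin",
                      n_per_sex: int = 3,
                      baseline_cq: float | dict[str, float] = 25.0,
                      control_cq: float = 20.0,
                      noise_sd: float = 0.15) -> pd.DataFrame:
    """Simulate a Cq table for a sex x hydration-state factorial design.

    ``genes`` maps gene name to class (``male_specific``,
    ``female_specific``, or anything else for genes present in both sexes;
    the control gene may be listed or not). ``effects`` maps gene name to
    the Cq shift applied under dehydration (negative = induced: lower Cq
    means more template). Returns a tidy frame with columns
    ``sample, sex, gene, state, cq``; missing amplification is NaN.
    """
    if control_gene not in genes:
        raise ConfigError(f"control gene {control_gene!r} missing from panel")
    if genes[control_gene] in ("male_specific", "female_specific"):
        raise ConfigError("internal control gene cannot be sex-specific")
    all_genes = dict(genes)
    effects = effects or {}
    rng = np.random.default_rng(seed)

    def base_for(gene: str) -> float:
        if gene == control_gene:
            return control_cq
        if isinstance(baseline_cq, dict):
            return baseline_cq[gene]
        return float(baseline_cq)

    rows = []
    for sex in ("male", "female"):
        for i in range(n_per_sex):
            sample = f"{sex[0].upper()}{i + 1}"
            for state in STATES:
                for gene, gclass in all_genes.items():
                    absent = (
                        (gclass == "male_specific" and sex == "female")
                        or (gclass == "female_specific" and sex == "male"))
                    if absent:
                        cq = np.nan
                    else:
                        cq = base_for(gene)
                        if state == "dehydrated" and gene != control_gene:
                            cq += effects.get(gene, 0.0)
                        if noise_sd > 0:
                            cq += rng.normal(0.0, noise_sd)
                    rows.append((sample, sex, gene, state, cq))
    return pd.DataFrame(rows, columns=["sample", "sex", "gene", "state", "cq"])
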