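"""Group statistics: dN/dS by gene class, copy-number flags, qPCR ratios.

Class comparisons are run on natural-log-transformed omega (the ratio is
strongly right-skewed); means and standard errors are reported on the
untransformed scale, as is conventional in presentation. The targeted
contrasts compare each non-autosomal class against the autosomal baseline;
they are invariant to the log base. When per-gene scaffold ids are
available a scaffold random intercept is fitted (genes on one scaffold
share linkage history); otherwise ordinary least squares is used and the
output says so.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .divergence import DnDsEstimate
from .errors import InputError

COARSE_MAP = {
    "autosomal": "autosomal",
    "male_specific": "sex_linked",
    "female_specific": "sex_linked",
    "male_allele": "sex_linked",
    "female_allele": "sex_linked",
    "mitochondrial": "organellar",
    "chloroplast": "organellar",
}


# ---------------------------------------------------------------------------
# dN/dS class summaries
# ---------------------------------------------------------------------------

@dataclass
class ClassSummaryResult:
    table: pd.DataFrame           # per-class n, mean, se, contrast stats
    omnibus_stat: float | None    # F (OLS) or Wald chi2 (mixed model)
    omnibus_p: float | None
    model: str                    # "ols" or "mixed"


def _estimates_frame(estimates: list[DnDsEstimate],
                     scaffolds: dict[str, str] | None) -> pd.DataFrame:
    rows = []
    for e in estimates:
        if e.log_omega is None:
            raise InputError(
                f"{e.gene_id}: run filter_estimates first (log_omega unset)")
        rows.append({
            "gene": e.gene_id, "cls": e.gene_class, "omega": e.omega,
            "log_omega": e.log_omega,
            "scaffold": scaffolds.get(e.gene_id) if scaffolds else None,
        })
    return pd.DataFrame(rows)


def class_summary(estimates: list[DnDsEstimate],
                  grouping: str = "fine",
                  scaffolds: dict[str, str] | None = None,
                  baseline: str = "autosomal") -> ClassSummaryResult:
    """Per-class dN/dS summaries with contrasts against the autosomal class.

    ``grouping`` is ``"fine"`` (the seven specific classes) or ``"coarse"``
    (autosomal / sex_linked / organellar). Classes with no retained
    estimate are dropped with a warning. The omnibus test and contrasts run
    on log omega; a scaffold random intercept is used when ``scaffolds``
    maps gene ids to scaffold ids.
    """
    if grouping not in ("fine", "coarse"):
        raise ValueError("grouping must be 'fine' or 'coarse'")
    df = _estimates_frame(estimates, scaffolds)
    if grouping == "coarse":
        df["cls"] = df["cls"].map(lambda c: COARSE_MAP.get(c, c))
    df = df[df["cls"].notna()]
    classes = sorted(df["cls"].unique())
    if len(classes) < 2:
        raise InputError("need at least two gene classes for comparison")
    if baseline not in classes:
        raise InputError(f"baseline class {baseline!r} absent from data")

    per_class = []
    for cls, grp in df.groupby("cls"):
        w = grp["omega"].to_numpy(dtype=float)
        per_class.append({
            "cls": cls, "n": len(w),
            "mean_omega": float(w.mean()),
            "se_omega": float(w.std(ddof=1) / math.sqrt(len(w)))
            if len(w) > 1 else None,
            "mean_log_omega": float(grp["log_omega"].mean()),
        })
    summary = pd.DataFrame(per_class).set_index("cls")

    formula = f"log_omega ~ C(cls, Treatment('{baseline}'))"
    use_mixed = scaffolds is not None and df["scaffold"].notna().all()
    if scaffolds is not None and not use_mixed:
        warnings.warn("scaffold ids incomplete; falling back to fixed effects")
    if use_mixed:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.mixedlm(formula, df, groups=df["scaffold"]).fit(reml=False)
        model_kind = "mixed"
        terms = [p for p in fit.params.index if p.startswith("C(cls")]
        wald = fit.wald_test(terms, scalar=True)
        omnibus_stat, omnibus_p = float(wald.statistic), float(wald.pvalue)
    else:
        fit = smf.ols(formula, df).fit()
        model_kind = "ols"
        omnibus_stat, omnibus_p = float(fit.fvalue), float(fit.f_pvalue)

    # degenerate fit (zero residual variance) makes the t statistics 0/0;
    # report a null contrast as exactly null in that case
    degenerate = float(getattr(fit, "ssr", np.nan)) < 1e-18 * max(len(df), 1) \
        if model_kind == "ols" else False
    est, tval, pval = {}, {}, {}
    for name, coef in fit.params.items():
        if not name.startswith("C(cls"):
            continue
        cls = name.split("[T.")[1].rstrip("]")
        est[cls] = float(coef)
        if degenerate and abs(coef) < 1e-9:
            tval[cls], pval[cls] = 0.0, 1.0
        else:
            tval[cls] = float(fit.tvalues[name])
            pval[cls] = float(fit.pvalues[name])
    summary["contrast_vs_" + baseline] = pd.Series(est)
    summary["contrast_t"] = pd.Series(tval)
    summary["contrast_p"] = pd.Series(pval)
    holm_in = summary["contrast_p"].dropna()
    if len(holm_in):
        adj = multipletests(holm_in.to_numpy(), method="holm")[1]
        summary.loc[holm_in.index, "contrast_p_holm"] = adj
    else:
        summary["contrast_p_holm"] = np.nan
    return ClassSummaryResult(summary.reset_index(), omnibus_stat,
                              omnibus_p, model_kind)


def positive_selection_list(estimates: list[DnDsEstimate]) -> pd.DataFrame:
    """Genes with omega strictly above 1, sorted by omega descending."""
    rows = [e.as_row() for e in estimates
            if e.omega is not None and e.omega > 1.0]
    df = pd.DataFrame(rows, columns=[
        "gene", "class", "S", "N", "Sd", "Nd", "pS", "pN", "dS", "dN",
        "omega", "flags"])
    return df.sort_values(["omega", "gene"], ascending=[False, True],
                          kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# candidate-gene copy-number scan
# ---------------------------------------------------------------------------

@dataclass
class DhtFlag:
    gene_id: str
    log2_ratio: float          # male / female coverage
    flagged: bool
    direction: str             # male_higher / female_higher
    sex_linkage: str           # U / V / autosomal (annotation, if known)


def dht_scan(gene_ratios: pd.DataFrame | dict[str, float],
             threshold: float = 4.0,
             sex_linkage: dict[str, str] | None = None) -> pd.DataFrame:
    """Flag candidate genes whose |log2 male/female coverage| exceeds
    the threshold (strict inequality); positive ratios mean higher male
    coverage. Duplicate gene ids are an input error."""
    if isinstance(gene_ratios, dict):
        df = pd.DataFrame(
            {"gene": list(gene_ratios), "log2_ratio": list(gene_ratios.values())})
    else:
        df = gene_ratios.rename(columns={
            df_col: "log2_ratio" for df_col in ("ratio",)
            if df_col in gene_ratios.columns}).copy()
    if df["gene"].duplicated().any():
        dup = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
        raise InputError(f"duplicate gene id {dup!r}")
    r = df["log2_ratio"].to_numpy(dtype=float)
    df["flagged"] = np.abs(r) > threshold
    df["direction"] = np.where(r > 0, "male_higher", "female_higher")
    link = sex_linkage or {}
    df["sex_linkage"] = df["gene"].map(lambda g: link.get(g, "autosomal"))
    return df


# ---------------------------------------------------------------------------
# qPCR relative quantification
# ---------------------------------------------------------------------------

def qpcr_relative(cq_target: float | None, cq_control: float,
                  efficiency: float = 2.0) -> tuple[float | None, str]:
    """Relative expression ratio target vs internal control.

    ratio = efficiency ** (cq_control - cq_target); a missing target Cq
    (no amplification) returns (None, "no_amplification").
    """
    if not 1.0 < efficiency <= 2.0:
        raise ValueError("amplification efficiency must be in (1, 2]")
    if cq_target is None or (isinstance(cq_target, float)
                             and math.isnan(cq_target)):
        return None, "no_amplification"
    return efficiency ** (cq_control - cq_target), ""


def add_relative_ratios(cq: pd.DataFrame, control_gene: str = "actin",
                        efficiency: float = 2.0) -> pd.DataFrame:
    """Attach relative_ratio (target vs control) per sample x state.

    Requires one control Cq in every sample x state cell; target genes with
    missing Cq get a NaN ratio and a ``no_amplification`` note.
    """
    out = cq[cq["gene"] != control_gene].copy()
    ctrl = (cq[cq["gene"] == control_gene]
            .set_index(["sample", "state"])["cq"])
    if ctrl.index.duplicated().any():
        raise InputError("multiple control measurements per sample x state")
    ratios, notes = [], []
    for t in out.itertuples():
        try:
            c = ctrl.loc[(t.sample, t.state)]
        except KeyError:
            raise InputError(
                f"no control Cq for sample {t.sample} state {t.state}")
        ratio, note = qpcr_relative(t.cq, float(c), efficiency)
        ratios.append(np.nan if ratio is None else ratio)
        notes.append(note)
    out["relative_ratio"] = ratios
    out["note"] = notes
    return out


@dataclass
class QpcrModelResult:
    anova: pd.DataFrame                 # effect table of the factorial model
    gene_contrasts: pd.DataFrame        # per-gene dehydrated vs hydrated
    dropped_terms: list[str]
    model: str


def qpcr_model(records: pd.DataFrame) -> QpcrModelResult:
    """Factorial linear model on relative expression ratios.

    Fixed effects of gene, hydration state, sex and their interactions;
    rows with a missing ratio are excluded listwise; factors with a single
    level are dropped with a warning. Per-gene contrasts compare dehydrated
    to hydrated least-squares means (averaged over the sexes in which the
    gene amplifies); a Holm-adjusted p-value column is included.
    """
    df = records.dropna(subset=["relative_ratio"]).copy()
    if df["gene"].nunique() < 2:
        raise InputError("need at least two genes")
    if df["state"].nunique() < 2:
        raise InputError("both hydration states must be present")
    factors = []
    dropped = []
    for col in ("gene", "state", "sex"):
        if df[col].nunique() > 1:
            factors.append(col)
        else:
            dropped.append(col)
            warnings.warn(f"factor {col!r} has a single level; dropped")
    formula = "relative_ratio ~ " + " * ".join(f"C({f})" for f in factors)
    fit = smf.ols(formula, df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        anova = sm.stats.anova_lm(fit, typ=2)

    from patsy import build_design_matrices
    design_info = fit.model.data.design_info
    rows = []
    for gene, grp in df.groupby("gene"):
        sexes = sorted(grp["sex"].unique())
        lrows = {}
        for state in ("dehydrated", "hydrated"):
            mats = build_design_matrices(
                [design_info],
                pd.DataFrame({"gene": gene, "state": state, "sex": sexes}))
            lrows[state] = np.asarray(mats[0]).mean(axis=0)
        L = lrows["dehydrated"] - lrows["hydrated"]
        tt = fit.t_test(L)
        rows.append({
            "gene": gene,
            "estimate": float(np.ravel(tt.effect)[0]),
            "t": float(np.ravel(tt.tvalue)[0]),
            "p": float(np.ravel(tt.pvalue)[0]),
        })
    contrasts = pd.DataFrame(rows)
    contrasts["p_holm"] = multipletests(
        contrasts["p"].to_numpy(), method="holm")[1]
    return QpcrModelResult(anova=anova, gene_contrasts=contrasts,
                           dropped_terms=dropped, model="ols")


# ---------------------------------------------------------------------------
# completeness percentages
# ---------------------------------------------------------------------------

def _round_half_away(x: float, digits: int = 1) -> float:
    factor = 10 ** digits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass
class CompletenessSummary:
    n_complete: int
    n_fragmented: int
    n_total: int
    complete_pct: float
    fragmented_pct: float
    missing_pct: float


def completeness_summary(n_complete: int, n_fragmented: int, n_total: int
                         ) -> CompletenessSummary:
    """Ortholog-set completeness percentages, one decimal, half away from
    zero (783 complete of 1,440 reports as 54.4%)."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if n_complete < 0 or n_fragmented < 0 \
            or n_complete + n_fragmented > n_total:
        raise ValueError("counts must be non-negative and sum <= n_total")
    complete = _round_half_away(100.0 * n_complete / n_total)
    fragmented = _round_half_away(100.0 * n_fragmented / n_total)
    missing = _round_half_away(
        100.0 * (n_total - n_complete - n_fragmented) / n_total)
    return CompletenessSummary(n_complete, n_fragmented, n_total,
                               complete, fragmented, missing)
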