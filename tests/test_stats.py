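"""Tests for group statistics, copy-number flags, qPCR and completeness."""

import math

import numpy as np
import pandas as pd
import pytest

from uvlinker.divergence import DnDsEstimate, filter_estimates
from uvlinker.errors import InputError
from uvlinker.stats import (
    add_relative_ratios,
    class_summary,
    completeness_summary,
    dht_scan,
    positive_selection_list,
    qpcr_model,
    qpcr_relative,
)


def _estimates(omegas_by_class, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    i = 0
    for cls, omegas in omegas_by_class.items():
        for w in omegas:
            i += 1
            out.append(DnDsEstimate(
                gene_id=f"g{i}", gene_class=cls, S=100, N=200, Sd=10, Nd=10,
                pS=0.1, pN=0.05, dS=0.1, dN=0.05 if w else 0.0,
                omega=float(w), flags=set()))
    retained, _ = filter_estimates(out)
    return retained


class TestClassSummary:
    def test_identical_classes_give_null_contrast(self):
        est = _estimates({"autosomal": [0.5] * 5, "male_specific": [0.5] * 5})
        res = class_summary(est)
        row = res.table.set_index("cls").loc["male_specific"]
        assert row["contrast_vs_autosomal"] == pytest.approx(0.0, abs=1e-10)
        assert row["contrast_p"] > 0.9

    def test_single_gene_class_reports_absent_se(self):
        est = _estimates({"autosomal": [0.3, 0.4], "male_specific": [0.9]})
        res = class_summary(est)
        row = res.table.set_index("cls").loc["male_specific"]
        assert row["n"] == 1
        assert row["se_omega"] is None or np.isnan(row["se_omega"])

    def test_separated_classes_detected_across_seeds(self):
        """Autosomal omega around 0.2 vs a class around 0.8: the contrast
        must be significant at alpha = 0.01 for every tested seed."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            est = _estimates({
                "autosomal": np.exp(rng.normal(math.log(0.2), 0.5, 200)),
                "male_specific": np.exp(rng.normal(math.log(0.8), 0.5, 30)),
            }, seed=seed)
            res = class_summary(est)
            p = res.table.set_index("cls").loc["male_specific", "contrast_p"]
            assert p < 0.01

    def test_coarse_grouping_pools_sex_classes(self):
        est = _estimates({"autosomal": [0.2] * 4, "male_specific": [0.8] * 2,
                          "female_specific": [0.7] * 2})
        res = class_summary(est, grouping="coarse")
        assert set(res.table["cls"]) == {"autosomal", "sex_linked"}
        assert res.table.set_index("cls").loc["sex_linked", "n"] == 4

    def test_contrasts_invariant_to_log_base(self):
        est = _estimates({"autosomal": [0.2, 0.3, 0.25],
                          "male_specific": [0.8, 0.9, 0.7]})
        res = class_summary(est)
        t_natural = res.table.set_index("cls").loc["male_specific",
                                                   "contrast_t"]
        for e in est:  # rescale to log10: t statistic must not move
            e.log_omega = e.log_omega / math.log(10)
        res10 = class_summary(est)
        t_log10 = res10.table.set_index("cls").loc["male_specific",
                                                   "contrast_t"]
        assert t_natural == pytest.approx(t_log10, rel=1e-9)

    def test_mixed_model_used_when_scaffolds_known(self):
        est = _estimates({"autosomal": [0.2, 0.3, 0.25, 0.28] * 5,
                          "male_specific": [0.8, 0.9, 0.7, 0.85] * 5})
        scaffolds = {e.gene_id: f"sc{i % 4}" for i, e in enumerate(est)}
        res = class_summary(est, scaffolds=scaffolds)
        assert res.model == "mixed"
        assert res.table.set_index("cls").loc["male_specific",
                                              "contrast_p"] < 0.05


class TestPositiveSelection:
    def test_empty_when_all_below_one(self):
        est = _estimates({"autosomal": [0.5, 0.9], "male_specific": [1.0]})
        assert positive_selection_list(est).empty

    def test_strict_inequality_at_one(self):
        est = _estimates({"autosomal": [0.5, 1.0, 1.2]})
        listed = positive_selection_list(est)
        assert len(listed) == 1
        assert listed.iloc[0]["omega"] == pytest.approx(1.2)

    def test_recovery_of_simulated_diversifying_genes(self):
        """Pairs simulated at omega = 2 are listed as under diversifying
        selection at least 90% of the time."""
        from uvlinker.divergence import codon_alignment_from_cds, dnds
        from uvlinker.simulate import simulate_ortholog_pairs
        pairs = simulate_ortholog_pairs(30, 2.0, 1.0, 0.3, 2000, seed=9)
        est = [dnds(codon_alignment_from_cds(p.cds_a, p.cds_b),
                    gene_id=p.gene_id, gene_class="autosomal")
               for p in pairs]
        retained, _ = filter_estimates(est)
        listed = positive_selection_list(retained)
        assert len(listed) >= 0.9 * len(pairs)


class TestDhtScan:
    # coverage-ratio magnitudes of the kind the scan is built for
    RATIOS = {"HSF1": 14.3397, "CDPK": -9.7936, "GRP94": -16.4576,
              "ALDH": -4.2169, "HSP70": -7.318, "SOD": -4.095,
              "near_threshold": 3.9}

    def test_flag_directions(self):
        flags = dht_scan(self.RATIOS).set_index("gene")
        assert flags.loc["HSF1", "flagged"]
        assert flags.loc["HSF1", "direction"] == "male_higher"
        assert flags.loc["SOD", "flagged"]
        assert flags.loc["SOD", "direction"] == "female_higher"
        assert not flags.loc["near_threshold", "flagged"]

    def test_flag_set_monotone_in_threshold(self):
        counts = [dht_scan(self.RATIOS, threshold=t)["flagged"].sum()
                  for t in (2, 4, 8, 20)]
        assert counts == sorted(counts, reverse=True)

    def test_duplicate_genes_rejected(self):
        df = pd.DataFrame({"gene": ["a", "a"], "log2_ratio": [1.0, 2.0]})
        with pytest.raises(InputError):
            dht_scan(df)

    def test_sex_linkage_annotation(self):
        flags = dht_scan(self.RATIOS,
                         sex_linkage={"HSF1": "V", "CDPK": "U"})
        by_gene = flags.set_index("gene")
        assert by_gene.loc["HSF1", "sex_linkage"] == "V"
        assert by_gene.loc["SOD", "sex_linkage"] == "autosomal"


class TestQpcrRelative:
    def test_identity(self):
        ratio, note = qpcr_relative(24.0, 24.0)
        assert ratio == 1.0 and note == ""

    def test_two_cycle_advantage_is_fourfold(self):
        ratio, _ = qpcr_relative(22.0, 24.0)
        assert ratio == pytest.approx(4.0)

    def test_absent_target(self):
        ratio, note = qpcr_relative(float("nan"), 24.0)
        assert ratio is None and note == "no_amplification"

    def test_efficiency_validation(self):
        with pytest.raises(ValueError):
            qpcr_relative(20.0, 24.0, efficiency=1.0)

    def test_log_ratio_additivity(self):
        """ratio(a, c) == ratio(a, b) * ratio(b, c) for any Cq triple."""
        a, b, c = 21.3, 24.8, 19.05
        r_ac, _ = qpcr_relative(a, c)
        r_ab, _ = qpcr_relative(a, b)
        r_bc, _ = qpcr_relative(b, c)
        assert r_ac == pytest.approx(r_ab * r_bc, rel=1e-12)


class TestQpcrModel:
    def _table(self, seed=0, induced_gene="HSP70", shift=-2.0, noise=0.1):
        from uvlinker.simulate import simulate_cq_table
        genes = {"actin": "autosomal", "HSP70": "autosomal",
                 "GRP94": "autosomal", "CDPK": "female_specific"}
        cq = simulate_cq_table(genes, effects={induced_gene: shift},
                               seed=seed, noise_sd=noise)
        return add_relative_ratios(cq)

    def test_induced_gene_detected_others_not(self):
        hits = {"HSP70": 0, "GRP94": 0}
        for seed in range(10):
            res = qpcr_model(self._table(seed=seed))
            p = res.gene_contrasts.set_index("gene")["p"]
            if p["HSP70"] < 0.05:
                hits["HSP70"] += 1
            if p["GRP94"] < 0.05:
                hits["GRP94"] += 1
        assert hits["HSP70"] == 10
        assert hits["GRP94"] <= 1

    def test_flat_table_gives_null_effects(self):
        table = self._table(noise=0.0, shift=0.0)
        res = qpcr_model(table)
        assert (res.gene_contrasts["estimate"].abs() < 1e-9).all()

    def test_sex_specific_gene_handled_listwise(self):
        res = qpcr_model(self._table())
        assert "CDPK" in set(res.gene_contrasts["gene"])

    def test_single_level_factor_dropped(self):
        table = self._table()
        table = table[table["sex"] == "male"]
        with pytest.warns(UserWarning, match="single level"):
            res = qpcr_model(table)
        assert "sex" in res.dropped_terms


class TestCompleteness:
    @pytest.mark.parametrize("args,complete,fragmented", [
        ((783, 51, 1440), 54.4, 3.5),
        ((867, 42, 1440), 60.2, 2.9),
        ((0, 0, 10), 0.0, 0.0),
    ])
    def test_reported_percentages(self, args, complete, fragmented):
        s = completeness_summary(*args)
        assert s.complete_pct == complete
        assert s.fragmented_pct == fragmented

    def test_percentages_sum_to_hundred(self):
        for args in ((783, 51, 1440), (1, 1, 3), (10, 5, 17)):
            s = completeness_summary(*args)
            assert s.complete_pct + s.fragmented_pct + s.missing_pct == \
                pytest.approx(100.0, abs=0.1 + 1e-9)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            completeness_summary(0, 0, 0)
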