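"""Phenotype formulas, descriptives, marker segregation, and FPR/FNR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from breedqc.genotype_io import MarkerMeta, TraitMarkerDef
from breedqc.trait_validation import (
    classify_qtl,
    describe_phenotypes,
    kruskal_wallis,
    marker_calls,
    marker_quality,
    rdmc,
    tabulate_counts,
    tabulate_marker,
    tcc_from_icheck,
    trait_correlations,
)
from breedqc.synthetic_data import (
    SimConfig,
    TraitArchitecture,
    simulate_panel,
    worked_example_tables,
)
from conftest import make_matrix


class TestPhenotypeFormulas:
    @pytest.mark.parametrize("dry,fresh,expected", [(35, 100, 35.0), (0, 50, 0.0),
                                                    (80, 80, 100.0)])
    def test_rdmc(self, dry, fresh, expected):
        assert rdmc(dry, fresh) == pytest.approx(expected)

    def test_rdmc_rejects_dry_above_fresh(self):
        with pytest.raises(ValueError):
            rdmc(101, 100)
        with pytest.raises(ValueError):
            rdmc(10, 0)

    def test_tcc_dilution_factor(self):
        assert tcc_from_icheck(100, 5, 25) == pytest.approx(20.0)
        assert tcc_from_icheck(0, 5, 25) == 0.0
        # doubling the slurry volume halves the concentration
        assert tcc_from_icheck(100, 5, 50) == pytest.approx(10.0)

    def test_tcc_rejects_nonpositive_volume(self):
        with pytest.raises(ValueError):
            tcc_from_icheck(100, 5, 0)


class TestDescribePhenotypes:
    def test_constant_trait(self):
        df = pd.DataFrame({"dmc": [30.0] * 10})
        out = describe_phenotypes(df)
        assert out.loc["dmc", "sd"] == 0.0
        assert out.loc["dmc", "cv"] == 0.0

    def test_shapiro_p_uniform_under_normality(self, rng):
        """Under a true normal trait the Shapiro-Wilk p-value is uniform."""
        pvals = []
        for _ in range(300):
            df = pd.DataFrame({"t": rng.normal(30, 6, size=50)})
            pvals.append(describe_phenotypes(df).loc["t", "shapiro_p"])
        ks_p = stats.kstest(pvals, "uniform").pvalue
        assert ks_p > 0.01

    def test_lognormal_trait_rejected(self, rng):
        hits = 0
        for _ in range(40):
            df = pd.DataFrame({"t": rng.lognormal(1, 0.8, size=300)})
            hits += describe_phenotypes(df).loc["t", "shapiro_p"] < 0.05
        assert hits >= 39  # power > 95% at n=300


class TestTraitCorrelations:
    def test_perfect_correlation(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [2.0, 4, 6, 8]})
        r, p, sig = trait_correlations(df)
        assert r.loc["x", "y"] == pytest.approx(1.0)
        assert sig.loc["x", "y"]

    def test_independent_traits_null_envelope(self, rng):
        inside = 0
        for _ in range(60):
            df = pd.DataFrame({"x": rng.normal(size=300), "y": rng.normal(size=300)})
            r, _, _ = trait_correlations(df)
            inside += abs(r.loc["x", "y"]) < 0.15
        assert inside >= 57  # ~99% should be inside at n=300

    def test_sampling_distribution_around_strong_correlation(self, rng):
        """rho=0.75 at n=262: the observed r stays in its sampling envelope."""
        inside = 0
        reps = 60
        for _ in range(reps):
            z = rng.normal(size=262)
            x = z + rng.normal(0, np.sqrt(1 / 0.75**2 - 1), size=262)
            df = pd.DataFrame({"x": x, "z": z})
            r, _, _ = trait_correlations(df)
            inside += 0.65 <= r.loc["x", "z"] <= 0.83
        assert inside >= int(0.90 * reps)

    def test_constant_column_flagged_nan(self):
        df = pd.DataFrame({"x": [1.0, 1, 1, 1], "y": [1.0, 2, 3, 4]})
        r, _, _ = trait_correlations(df)
        assert np.isnan(r.loc["x", "y"])


class TestTabulateMarker:
    def test_cmd_resistance_marker_percentages(self):
        """Printed counts 40/238/53 give 71.90% het, 16.01% hom-favorable."""
        row = tabulate_counts("S12-7926132", 40, 238, 53, favorable_is_minor=False)
        assert row.pct_het == 71.90
        assert row.pct_hom_major == 16.01
        assert row.n_total == 331

    def test_carrier_percentage_sums_rounded_classes(self):
        """Counts 46/127/160 with a minor favorable allele: 51.95% carriers."""
        row = tabulate_counts("S14-4626854", 46, 127, 160, favorable_is_minor=True)
        assert row.pct_hom_minor == 13.81
        assert row.pct_het == 38.14
        assert row.pct_favorable_carriers == 51.95

    def test_all_heterozygous(self):
        row = tabulate_counts("m", 0, 12, 0, favorable_is_minor=True)
        assert row.pct_het == 100.0

    def test_from_genotype_matrix_with_missing_excluded(self):
        markers = [MarkerMeta(id="mk", alleles=("G", "T"), counted_allele_index=1)]
        d = np.array([[2], [1], [1], [0], [-1]], dtype=np.int16)
        G = make_matrix(d, marker_meta=markers)
        defn = TraitMarkerDef(marker_id="mk", trait="CMD", favorable_allele="T")
        row = tabulate_marker(G, "mk", defn)
        assert row.n_total == 4  # missing call dropped
        # T freq = (2+1+1)/8 = 0.5 -> counted as minor (tie goes to counted)
        assert row.n_het == 2

    def test_every_published_marker_row_is_self_consistent(self):
        """All printed class percentages that match their printed counts."""
        fx = worked_example_tables()["table3"]
        expected = {
            "S12-7926132": {"pct_het": 71.90, "pct_hom_major": 16.01},
            "S12-7926163": {"pct_hom_minor": 11.38, "pct_het": 72.16,
                            "pct_hom_major": 16.47,
                            "pct_favorable_carriers": 88.63},
            "S14-4626854": {"pct_hom_minor": 13.81, "pct_het": 38.14,
                            "pct_hom_major": 48.05,
                            "pct_favorable_carriers": 51.95},
            "S1-24197219": {"pct_hom_minor": 5.33, "pct_het": 50.16,
                            "pct_hom_major": 44.51},
            "S6-20589894": {"pct_favorable_carriers": 77.29},
            "S1-24155522": {"pct_hom_major": 38.49, "pct_het": 56.91,
                            "pct_favorable_carriers": 95.40},
            "S1-30543962": {"pct_hom_minor": 4.90},
            "S5-3387558": {"pct_hom_minor": 0.66, "pct_het": 44.70},
            "S8-25598183": {"pct_het": 21.10},
        }
        for mid, checks in expected.items():
            counts = fx[mid]["counts"]
            row = tabulate_counts(mid, *counts, fx[mid]["favorable_is_minor"])
            for attr, value in checks.items():
                assert getattr(row, attr) == value, (mid, attr)


class TestKruskalWallis:
    def test_matches_hand_computed_ranks(self):
        """n=6 with no ties: H from hand-ranked data."""
        vals = np.array([1.0, 3.0, 5.0, 2.0, 4.0, 6.0])
        classes = np.array(["a", "a", "a", "b", "b", "b"])
        # ranks: a -> 1,3,5 (sum 9); b -> 2,4,6 (sum 12)
        # H = 12/(6*7) * (9^2/3 + 12^2/3) - 3*7 = 12/42*75 - 21 = 3/7
        h, p, _ = kruskal_wallis(vals, classes)
        assert h == pytest.approx(3 / 7)

    def test_all_equal_values(self):
        h, p, stars = kruskal_wallis([2.0] * 6, ["a", "a", "a", "b", "b", "b"])
        assert h == 0.0 and stars == "ns"

    def test_invariant_under_monotone_transform(self, rng):
        vals = rng.normal(size=30)
        classes = rng.integers(0, 3, size=30)
        h1, _, _ = kruskal_wallis(vals, classes)
        h2, _, _ = kruskal_wallis(np.exp(vals), classes)
        assert h1 == pytest.approx(h2)

    def test_power_with_shifted_classes(self, rng):
        for _ in range(20):
            a = rng.normal(0, 1, size=50)
            b = rng.normal(3, 1, size=50)
            _, p, stars = kruskal_wallis(
                np.concatenate([a, b]), np.repeat(["a", "b"], 50)
            )
            assert p < 1e-4 and stars == "****"

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1.0, 2.0], ["a", "a"])


class TestClassifyQtl:
    def test_cmd_boundary_inclusive(self):
        df = pd.DataFrame({"cmd_severity": [2.0, 2.01, 1.0]},
                          index=["a", "b", "c"])
        calls = classify_qtl(df, "CMD")
        assert calls["a"] and not calls["b"] and calls["c"]

    def test_tcc_threshold_and_chart_fallback(self):
        df = pd.DataFrame(
            {"tcc_icheck": [14.9, 15.0, None], "tcc_chart": [8, 1, 4]},
            index=["a", "b", "c"],
        )
        calls = classify_qtl(df, "TCC")
        assert not calls["a"]  # iCheck wins over the chart
        assert calls["b"]
        assert calls["c"]  # chart >= 4 when iCheck absent

    def test_dmc_threshold(self):
        df = pd.DataFrame({"dmc": [30.0, 29.9]}, index=["a", "b"])
        calls = classify_qtl(df, "DMC")
        assert calls["a"] and not calls["b"]

    def test_missing_trait_samples_excluded(self):
        df = pd.DataFrame({"cmd_severity": [1.5, None]}, index=["a", "b"])
        calls = classify_qtl(df, "CMD")
        assert list(calls.index) == ["a"]

    def test_matches_planted_truth_exactly(self):
        cfg = SimConfig(seed=17, n_pops=2, fst_target=0.1, n_samples_per_pop=50,
                        n_markers_dense=100, n_markers_sparse=20,
                        missing_rate=0.0, n_duplicate_pairs=0,
                        trait_arch=[TraitArchitecture(0, "CMD"),
                                    TraitArchitecture(1, "DMC"),
                                    TraitArchitecture(2, "TCC")])
        _, _, pheno, truth = simulate_panel(cfg)
        for trait in ("CMD", "DMC", "TCC"):
            calls = classify_qtl(pheno, trait)
            pd.testing.assert_series_equal(
                calls, truth.qtl_status[trait], check_names=False
            )


class TestMarkerQuality:
    def test_perfect_marker(self):
        pheno = pd.Series([True, True, False, False], index=list("abcd"))
        marker = pd.Series([True, True, False, False], index=list("abcd"))
        q = marker_quality(pheno, marker, "m")
        assert q.fpr_pct == 0.0 and q.fnr_pct == 0.0

    def test_empty_phenotype_class_reported_absent(self):
        pheno = pd.Series([True, True], index=list("ab"))
        marker = pd.Series([True, False], index=list("ab"))
        q = marker_quality(pheno, marker, "m")
        assert q.fpr_pct is None
        assert q.fnr_pct == 50.0

    def test_independent_marker_limits(self, rng):
        """Marker independent of a 50/50 phenotype: FPR -> 100c, FNR -> 100(1-c)."""
        n = 20_000
        c = 0.3
        pheno = pd.Series(rng.uniform(size=n) < 0.5)
        marker = pd.Series(rng.uniform(size=n) < c)
        q = marker_quality(pheno, marker, "m")
        assert q.fpr_pct == pytest.approx(100 * c, abs=1.5)
        assert q.fnr_pct == pytest.approx(100 * (1 - c), abs=1.5)

    def test_penetrance_model_closed_form_exact(self):
        """With penetrance/phenocopy applied as exact class proportions the
        observed FPR/FNR equal the closed-form conditional probabilities."""
        pen, phe, n_c, n_n = 0.9, 0.2, 1000, 1000
        # carriers: first n_c samples; exactly pen*n_c of them are QTL+
        marker = pd.Series([True] * n_c + [False] * n_n)
        pheno = pd.Series(
            [True] * int(pen * n_c) + [False] * (n_c - int(pen * n_c))
            + [True] * int(phe * n_n) + [False] * (n_n - int(phe * n_n))
        )
        q = marker_quality(pheno, marker, "m")
        c = n_c / (n_c + n_n)
        exp_fpr = 100 * c * (1 - pen) / (c * (1 - pen) + (1 - c) * (1 - phe))
        exp_fnr = 100 * (1 - c) * phe / (c * pen + (1 - c) * phe)
        assert q.fpr_pct == pytest.approx(exp_fpr, abs=0.01)
        assert q.fnr_pct == pytest.approx(exp_fnr, abs=0.01)

    def test_fnr_monotone_in_penetrance(self):
        """Raising penetrance never increases the expected FNR."""
        fnrs = []
        for pen in (0.6, 0.8, 0.95):
            cfg = SimConfig(seed=29, n_pops=1, fst_target=0.1,
                            n_samples_per_pop=400, n_markers_dense=20,
                            n_markers_sparse=5, missing_rate=0.0,
                            n_duplicate_pairs=0,
                            trait_arch=[TraitArchitecture(0, "DMC",
                                                          penetrance=pen,
                                                          phenocopy=0.1)])
            dense, _, pheno, truth = simulate_panel(cfg)
            defn = truth.trait_defs[0]
            q = marker_quality(classify_qtl(pheno, "DMC"),
                               marker_calls(dense, defn), defn.marker_id)
            fnrs.append(q.fnr_pct)
        assert fnrs[0] >= fnrs[1] >= fnrs[2]

    def test_additive_model_requires_homozygote(self):
        markers = [MarkerMeta(id="mk", alleles=("A", "C"), counted_allele_index=1)]
        d = np.array([[2], [1], [0]], dtype=np.int16)
        G = make_matrix(d, marker_meta=markers)
        dom = TraitMarkerDef("mk", "DMC", "C", "dominant")
        add = TraitMarkerDef("mk", "DMC", "C", "additive")
        assert marker_calls(G, dom).tolist() == [True, True, False]
        assert marker_calls(G, add).tolist() == [True, False, False]
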