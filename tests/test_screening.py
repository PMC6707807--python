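"""Aggregation, the Spearman screen, KS target enrichment, and per-gene
CpG counting — each against an independent oracle where one exists."""

import itertools
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import methorr as m
from methorr import screening


class TestAggregation:
    def test_simple_mean(self):
        beta = pd.DataFrame({"s1": [0.2], "s2": [0.4]}, index=["cg01"])
        profiles = m.aggregate_to_cancer_profiles({"ACC": beta})
        assert profiles.loc["cg01", "ACC"] == pytest.approx(0.3)

    def test_fully_missing_probe_dropped_everywhere(self):
        a = pd.DataFrame({"s1": [0.2, np.nan], "s2": [0.4, np.nan]},
                         index=["cg01", "cg02"])
        b = pd.DataFrame({"t1": [0.5, 0.6]}, index=["cg01", "cg02"])
        profiles = m.aggregate_to_cancer_profiles({"A": a, "B": b})
        assert list(profiles.index) == ["cg01"]

    def test_partial_missing_uses_available_samples(self):
        beta = pd.DataFrame({"s1": [0.2], "s2": [np.nan], "s3": [0.6]}, index=["cg01"])
        profiles = m.aggregate_to_cancer_profiles({"A": beta})
        assert profiles.loc["cg01", "A"] == pytest.approx(0.4)

    def test_matches_brute_force_on_seeded_cohort(self, small_cohort, small_profiles):
        code = "C03"
        beta = small_cohort.matrices[code]
        for probe in beta.index[:100]:
            values = beta.loc[probe].to_numpy()
            assert small_profiles.loc[probe, code] == pytest.approx(
                values[~np.isnan(values)].mean(), abs=1e-12
            )

    def test_empty_intersection_rejected(self):
        a = pd.DataFrame({"s1": [0.1]}, index=["cg01"])
        b = pd.DataFrame({"t1": [0.2]}, index=["cg02"])
        with pytest.raises(ValueError, match="intersection"):
            m.aggregate_to_cancer_profiles({"A": a, "B": b})


class TestSpearman:
    def test_exact_small_n_matches_enumeration(self):
        """n = 6: p equals the exhaustive permutation distribution (720 orderings)."""
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([3.0, 1.0, 2.0, 6.0, 5.0, 4.0])
        rho, p = m.spearman(x, y)
        rho_obs = stats.spearmanr(x, y).statistic
        null = [
            stats.spearmanr(x, y[list(perm)]).statistic
            for perm in itertools.permutations(range(6))
        ]
        p_exact = np.mean([abs(r) >= abs(rho_obs) - 1e-12 for r in null])
        assert rho == pytest.approx(rho_obs, abs=1e-12)
        assert p == pytest.approx(p_exact, abs=1e-12)

    def test_large_n_matches_scipy(self, rng):
        x = rng.random(18)
        y = rng.random(18)
        rho, p = m.spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_vectorised_matches_scalar(self, rng):
        X = rng.random((30, 18))
        y = rng.random(18)
        rho_vec, p_vec = screening.spearman_vector(X, y)
        for i in range(30):
            ref = stats.spearmanr(X[i], y)
            assert rho_vec[i] == pytest.approx(ref.statistic, abs=1e-12)
            assert p_vec[i] == pytest.approx(ref.pvalue, rel=1e-9)

    def test_average_ranks_for_ties(self):
        rho, _ = m.spearman([1.0, 2.0, 2.0, 3.0], [1.0, 2.0, 3.0, 4.0])
        ref = stats.spearmanr([1, 2, 2, 3], [1, 2, 3, 4])
        assert rho == pytest.approx(ref.statistic, abs=1e-12)


class TestScreen:
    def test_perfect_monotone_probe_passes(self, orr_fixture):
        profiles = pd.DataFrame(
            {code: [0.1 + 0.8 * orr_fixture[code]] for code in orr_fixture.index},
            index=["cg_up"],
        )
        results = m.spearman_screen(profiles, orr_fixture)
        assert results.loc["cg_up", "rho"] == pytest.approx(1.0)
        assert bool(results.loc["cg_up", "passes"])

    def test_printed_top_rows_satisfy_filter(self):
        top = m.load_top_cpgs_fixture()
        assert (top["rho"].abs() >= 0.7).all()
        assert (top["p_value"] <= 0.001).all()

    def test_too_few_cancer_types_rejected(self):
        profiles = pd.DataFrame({"A": [0.1], "B": [0.2], "C": [0.3]}, index=["cg01"])
        orr = pd.Series({"A": 0.1, "B": 0.2, "C": 0.3})
        with pytest.raises(ValueError, match="4 cancer types"):
            m.spearman_screen(profiles, orr)

    def test_monotone_transform_invariance(self, small_profiles, small_cohort):
        results = m.spearman_screen(small_profiles, small_cohort.orr)
        transformed = m.spearman_screen(np.exp(small_profiles) / np.e, small_cohort.orr)
        pd.testing.assert_series_equal(
            results["rho"].sort_index(), transformed["rho"].sort_index(), atol=1e-12
        )

    def test_pass_count_monotone_in_thresholds(self, small_profiles, small_cohort):
        counts_rho = [
            m.spearman_screen(small_profiles, small_cohort.orr, rho_threshold=r)["passes"].sum()
            for r in (0.5, 0.7, 0.9)
        ]
        assert counts_rho == sorted(counts_rho, reverse=True)
        counts_p = [
            m.spearman_screen(small_profiles, small_cohort.orr, p_threshold=p)["passes"].sum()
            for p in (1e-5, 1e-3, 0.05)
        ]
        assert counts_p == sorted(counts_p)

    def test_bh_column_is_monotone_in_p(self, small_profiles, small_cohort):
        results = m.spearman_screen(small_profiles, small_cohort.orr).dropna()
        ordered = results.sort_values("p_value")
        assert (ordered["q_value"].diff().dropna() >= -1e-12).all()


def _annotation(probe_genes: dict) -> pd.DataFrame:
    return pd.DataFrame(
        {"genes": list(probe_genes.values()),
         "chromosome": ["1"] * len(probe_genes),
         "coordinate": [float(i + 1) for i in range(len(probe_genes))]},
        index=pd.Index(probe_genes.keys(), name="probe_id"),
    )


def _results(rhos: dict) -> pd.DataFrame:
    return pd.DataFrame(
        {"rho": list(rhos.values()), "p_value": 0.5, "q_value": 0.5,
         "passes": False},
        index=pd.Index(rhos.keys(), name="probe_id"),
    )


class TestKsEnrichment:
    def test_identical_distributions(self):
        rhos = {f"cg{i}": v for i, v in enumerate([0.1, 0.4, 0.9, 0.1, 0.4, 0.9])}
        ann = _annotation({f"cg{i}": (("GOLD",) if i < 3 else ("X",)) for i in range(6)})
        d, p = m.ks_target_enrichment(_results(rhos), ["GOLD"], ann)
        assert d == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_full_separation(self):
        rhos = {f"cg{i}": (0.9 if i < 4 else 0.1) for i in range(8)}
        ann = _annotation({f"cg{i}": (("GOLD",) if i < 4 else ("X",)) for i in range(8)})
        d, _ = m.ks_target_enrichment(_results(rhos), ["GOLD"], ann)
        assert d == pytest.approx(1.0)

    def test_matches_reference_ks_implementation(self, rng):
        n_gold, n_other = 20, 35
        gold_rho = rng.normal(0.6, 0.15, n_gold).clip(0, 1)
        other_rho = rng.normal(0.45, 0.15, n_other).clip(0, 1)
        rhos = {f"g{i}": v for i, v in enumerate(gold_rho)}
        rhos.update({f"o{i}": v for i, v in enumerate(other_rho)})
        ann = _annotation(
            {k: (("GOLD",) if k.startswith("g") else ("X",)) for k in rhos}
        )
        d, p = m.ks_target_enrichment(_results(rhos), ["GOLD"], ann)

        # brute-force one-sided D: sup of (other ECDF − gold ECDF)
        pooled = np.concatenate([gold_rho, other_rho])
        f_gold = np.array([(gold_rho <= t).mean() for t in pooled])
        f_other = np.array([(other_rho <= t).mean() for t in pooled])
        assert d == pytest.approx(float((f_other - f_gold).max()), abs=1e-9)

        if shutil.which("Rscript"):
            script = (
                f"g <- c({','.join(map(str, gold_rho))});"
                f"o <- c({','.join(map(str, other_rho))});"
                "r <- ks.test(g, o, alternative='less');"
                "cat(sprintf('%.12f %.12f', r$statistic, r$p.value))"
            )
            out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                                 text=True, check=True).stdout.split()
            assert d == pytest.approx(float(out[0]), abs=1e-9)
            assert p == pytest.approx(float(out[1]), abs=1e-6)

    def test_no_gold_overlap_rejected(self):
        rhos = {"cg0": 0.5}
        ann = _annotation({"cg0": ("X",)})
        with pytest.raises(ValueError, match="gold"):
            m.ks_target_enrichment(_results(rhos), ["GOLD"], ann)


class TestGeneEnrichment:
    def test_counts_passing_probes_per_gene(self):
        results = _results({f"cg{i}": 0.9 for i in range(7)})
        results["passes"] = [True] * 6 + [False]
        ann = _annotation({f"cg{i}": ("HLA-E",) for i in range(7)})
        table = m.gene_cpg_enrichment(results, ann)
        assert table.iloc[0]["gene_symbol"] == "HLA-E"
        assert table.iloc[0]["cpg_count"] == 6

    def test_multi_gene_probe_counts_once_per_gene(self):
        results = _results({"cg0": 0.9})
        results["passes"] = True
        ann = _annotation({"cg0": ("A", "B")})
        table = m.gene_cpg_enrichment(results, ann).set_index("gene_symbol")
        assert table.loc["A", "cpg_count"] == 1
        assert table.loc["B", "cpg_count"] == 1

    def test_no_passing_probes_gives_empty_table(self):
        results = _results({"cg0": 0.1})
        ann = _annotation({"cg0": ("A",)})
        assert m.gene_cpg_enrichment(results, ann).empty
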