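"""Cohort genetic-architecture statistics against brute-force oracles and
printed-count fixtures."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from raredx.cohort_stats import (
    Diagnosis,
    Variant,
    autozygosity_stratify,
    carrier_amenable,
    clinvar_quartiles,
    denovo_normalized_burden,
    diagnoses_from_frame,
    diagnoses_to_frame,
    format_percent,
    moi_distribution,
    rate_summary,
    year_comparison,
    year_histogram,
    yield_table,
)


def _diag(pid="p1", gene="G1", moi="AD_de_novo", variants=None, **kw):
    if variants is None:
        n = 2 if moi == "AR_comp_het" else 1
        variants = [Variant("P")] * n
    return Diagnosis(patient_id=pid, gene=gene, moi=moi, variants=variants, **kw)


def fisher_two_sided_oracle(a, b, c, d):
    """Exhaustive hypergeometric tail enumeration for a 2x2 table,
    independent of scipy.stats.fisher_exact."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    p_obs = hypergeom.pmf(a, n, col1, row1)
    total = 0.0
    for x in range(lo, hi + 1):
        p = hypergeom.pmf(x, n, col1, row1)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(1.0, total)


class TestYieldTable:
    def test_single_group_printed_counts(self):
        cohort = pd.DataFrame(
            {
                "disease_category": ["all"] * 1577,
                "solved": [1] * 499 + [0] * (1577 - 499),
            }
        )
        yt = yield_table(cohort)
        frac = float(yt.per_group["yield"].iloc[0])
        assert round(100 * frac) == 32

    def test_identical_groups_null(self):
        cohort = pd.DataFrame(
            {
                "disease_category": ["a"] * 40 + ["b"] * 40,
                "solved": ([1] * 10 + [0] * 30) * 2,
            }
        )
        yt = yield_table(cohort)
        row = yt.pairwise.iloc[0]
        assert row["odds_ratio"] == pytest.approx(1.0)
        assert row["p"] == pytest.approx(1.0)

    def test_fisher_matches_enumeration_oracle(self):
        cohort = pd.DataFrame(
            {
                "disease_category": ["a"] * 10 + ["b"] * 10,
                "solved": [1] * 8 + [0] * 2 + [1] * 3 + [0] * 7,
            }
        )
        yt = yield_table(cohort)
        assert yt.pairwise["p"].iloc[0] == pytest.approx(
            fisher_two_sided_oracle(8, 2, 3, 7), rel=1e-9
        )

    def test_fisher_oracle_sweep_small_tables(self, rng):
        """Every Fisher p matches exhaustive enumeration for n <= 30."""
        for _ in range(25):
            a, b, c, d = rng.integers(0, 8, size=4)
            if (a + b) == 0 or (c + d) == 0:
                continue
            cohort = pd.DataFrame(
                {
                    "disease_category": ["x"] * (a + b) + ["y"] * (c + d),
                    "solved": [1] * a + [0] * b + [1] * c + [0] * d,
                }
            )
            yt = yield_table(cohort)
            assert yt.pairwise["p"].iloc[0] == pytest.approx(
                fisher_two_sided_oracle(int(a), int(b), int(c), int(d)),
                rel=1e-9, abs=1e-12,
            )

    def test_bonferroni_over_pairwise_tests(self):
        cohort = pd.DataFrame(
            {
                "disease_category": ["a"] * 20 + ["b"] * 20 + ["c"] * 20,
                "solved": [1] * 15 + [0] * 5 + [1] * 5 + [0] * 15 + [1] * 10 + [0] * 10,
            }
        )
        yt = yield_table(cohort)
        assert len(yt.pairwise) == 3
        assert np.allclose(
            yt.pairwise["p_adj"], np.minimum(1.0, 3 * yt.pairwise["p"])
        )


class TestMoiAndBurden:
    def test_printed_de_novo_share(self):
        diagnoses = [
            _diag(pid=f"p{i}", moi="AD_de_novo") for i in range(228)
        ] + [_diag(pid=f"q{i}", moi="AD") for i in range(510 - 228)]
        moi = moi_distribution(diagnoses)
        assert int(moi.loc["AD_de_novo", "count"]) == 228
        assert round(100 * moi.loc["AD_de_novo", "fraction"]) == 45

    def test_fractions_sum_to_one(self, rng):
        mois = rng.choice(
            ["AD", "AD_de_novo", "AR_hom", "AR_comp_het", "XL", "MT"], 50
        )
        diagnoses = [_diag(pid=f"p{i}", moi=m) for i, m in enumerate(mois)]
        assert moi_distribution(diagnoses)["fraction"].sum() == pytest.approx(1.0)

    def test_burden_identical_compositions(self):
        comp = {"AD": 0.2, "AD_de_novo": 0.4, "AR_hom": 0.2,
                "AR_comp_het": 0.1, "XL": 0.1, "MT": 0.0}
        assert denovo_normalized_burden(comp, comp) == pytest.approx(1.0)

    def test_burden_arithmetic_example(self):
        high = {"AD_de_novo": 0.10, "AR_hom": 0.50, "AR_comp_het": 0.20}
        low = {"AD_de_novo": 0.50, "AR_hom": 0.05, "AR_comp_het": 0.15}
        assert denovo_normalized_burden(high, low) == pytest.approx(17.5)

    def test_burden_zero_denovo_undefined(self):
        high = {"AD_de_novo": 0.0, "AR_hom": 0.5, "AR_comp_het": 0.1}
        low = {"AD_de_novo": 0.5, "AR_hom": 0.1, "AR_comp_het": 0.1}
        with pytest.raises(ValueError):
            denovo_normalized_burden(high, low)


class TestAutozygosity:
    def _cohort(self, values):
        return pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(len(values))],
                "autozygosity": values,
                "solved": [1] * len(values),
            }
        )

    def test_exact_threshold_goes_low(self):
        cohort = self._cohort([0.02, 0.021, 0.0])
        diagnoses = [_diag(pid=f"p{i}") for i in range(3)]
        strata = autozygosity_stratify(cohort, diagnoses)
        assert strata["low"]["n"] == 2
        assert strata["high"]["n"] == 1

    def test_all_zero_high_group_empty(self):
        cohort = self._cohort([0.0] * 5)
        strata = autozygosity_stratify(cohort, [_diag(pid="p0")])
        assert strata["high"]["n"] == 0

    def test_missing_autozygosity_flagged(self):
        cohort = self._cohort([0.0, np.nan, 0.05])
        with pytest.warns(UserWarning, match="without autozygosity"):
            strata = autozygosity_stratify(cohort, [_diag(pid="p0")])
        assert strata["low"]["n"] + strata["high"]["n"] == 2

    def test_high_group_size_tracks_consanguinity_rate(self):
        """10% consanguineous at F around 0.06 lands within the binomial
        band of 10%."""
        rng = np.random.default_rng(5)
        n = 2000
        consang = rng.random(n) < 0.10
        f = np.where(consang, 0.06 + 0.02 * rng.standard_normal(n), 0.001)
        cohort = self._cohort(np.clip(f, 0, 1))
        cohort["solved"] = 0
        strata = autozygosity_stratify(cohort, [])
        se = np.sqrt(0.1 * 0.9 / n)
        assert abs(strata["high"]["n"] / n - 0.10) < 3 * se


class TestCarrierScreening:
    def test_hom_pathogenic(self):
        d = _diag(moi="AR_hom", variants=[Variant("P")])
        assert carrier_amenable(d)

    def test_hom_lof_nmd_escape_unsubmitted(self):
        d = _diag(
            moi="AR_hom",
            variants=[Variant(None, lof=True, nmd_escape=True)],
        )
        assert not carrier_amenable(d)

    def test_hom_lof_no_escape(self):
        d = _diag(moi="AR_hom", variants=[Variant(None, lof=True)])
        assert carrier_amenable(d)

    def test_comp_het_one_vus_fails_strict(self):
        d = _diag(
            moi="AR_comp_het", variants=[Variant("P"), Variant("VUS")]
        )
        assert not carrier_amenable(d)

    def test_comp_het_lof_rule_flag(self):
        d = _diag(
            moi="AR_comp_het",
            variants=[Variant("LP"), Variant(None, lof=True)],
        )
        assert not carrier_amenable(d, strict_comp_het=True)
        assert carrier_amenable(d, strict_comp_het=False)

    def test_non_ar_rejected(self):
        with pytest.raises(ValueError):
            carrier_amenable(_diag(moi="AD"))

    def test_monotone_in_classification(self):
        """Upgrading VUS to P never flips amenable -> not amenable."""
        for moi in ("AR_hom", "AR_comp_het"):
            nvar = 2 if moi == "AR_comp_het" else 1
            for combo in itertools.product(["VUS", "P"], repeat=nvar):
                base = _diag(moi=moi, variants=[Variant(c) for c in combo])
                upgraded = _diag(moi=moi, variants=[Variant("P")] * nvar)
                assert carrier_amenable(upgraded) >= carrier_amenable(base)


class TestRates:
    def test_printed_cohort_rates(self):
        """Headline rates recomputed from the printed cohort counts:
        yield 32% (499/1,577), dual diagnoses 2% (11/499), mosaicism
        1.3% (3/228), carrier-amenable 75% (94/125)."""
        n, solved = 1577, 499
        cohort = pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(n)],
                "solved": [1] * solved + [0] * (n - solved),
            }
        )
        diagnoses = []
        # 228 de novo (3 mosaic), 125 AR (94 amenable), rest AD; 11 dual
        for i in range(228):
            diagnoses.append(
                _diag(pid=f"p{i}", moi="AD_de_novo", mosaic=i < 3)
            )
        for i in range(125):
            amen = i < 94
            diagnoses.append(
                _diag(
                    pid=f"p{228 + i}", moi="AR_hom",
                    variants=[Variant("P" if amen else "VUS")],
                )
            )
        for i in range(353, solved):
            diagnoses.append(_diag(pid=f"p{i}", moi="AD"))
        for i in range(11):  # dual diagnoses
            diagnoses.append(_diag(pid=f"p{i}", gene="G2", moi="AD"))
        rates = rate_summary(cohort, diagnoses)
        assert rates.loc["diagnostic_yield", "formatted"] == "32%"
        assert rates.loc["dual_diagnosis", "formatted"] == "2.2%"
        assert rates.loc["parental_mosaicism", "formatted"] == "1.3%"
        assert rates.loc["carrier_amenable", "formatted"] == "75%"
        assert rates.loc["carrier_amenable", "percent"] >= 75.0
        # diagnosis-level bookkeeping: diagnoses >= solved patients
        assert rates.loc["dual_diagnosis", "denominator"] == solved
        assert len(diagnoses) >= solved

    def test_percent_formatting(self):
        assert format_percent(499, 1577) == "32%"
        assert format_percent(3, 228) == "1.3%"
        assert format_percent(11, 499) == "2.2%"


class TestClinvarQuartiles:
    def test_four_equal_genes_one_per_quartile(self):
        counts = pd.DataFrame(
            {"gene": list("abcd"), "plp_submissions": [5, 5, 5, 5]}
        )
        q = clinvar_quartiles(counts)
        assert sorted(q["genes"]["quartile"]) == ["Q1", "Q2", "Q3", "Q4"]

    def test_single_dominant_gene_midpoint_rule(self):
        counts = pd.DataFrame({"gene": ["a"], "plp_submissions": [100]})
        q = clinvar_quartiles(counts)
        # spans all bins; midpoint 0.5 falls in the second quartile
        assert q["genes"]["quartile"].iloc[0] == "Q2"

    def test_exclusion_list_applied_first(self):
        counts = pd.DataFrame(
            {"gene": ["keep", "drop"], "plp_submissions": [10, 1000]}
        )
        q = clinvar_quartiles(counts, exclude=["drop"])
        assert list(q["genes"]["gene"]) == ["keep"]

    def test_zipf_mass_balance(self):
        """Each quartile's submission mass is 1/4 up to the largest
        single-gene fraction, for a long-tailed count distribution."""
        rng = np.random.default_rng(11)
        counts = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(1000)],
                "plp_submissions": rng.zipf(1.5, 1000),
            }
        )
        q = clinvar_quartiles(counts)
        delta = (
            counts["plp_submissions"].max() / counts["plp_submissions"].sum()
        )
        for frac in q["summary"]["submission_fraction"]:
            assert 0.25 - delta <= frac <= 0.25 + delta

    def test_cohort_tally_and_unassigned_flag(self):
        counts = pd.DataFrame(
            {"gene": ["a", "b"], "plp_submissions": [10, 10]}
        )
        diagnoses = [
            _diag(pid="p1", gene="a"),
            _diag(pid="p2", gene="a"),
            _diag(pid="p3", gene="zzz"),
        ]
        with pytest.warns(UserWarning, match="unassigned"):
            q = clinvar_quartiles(counts, diagnoses=diagnoses)
        assert q["unassigned"] == ["zzz"]
        assert int(q["summary"]["cohort_variants"].sum()) == 2


class TestYearComparison:
    def test_identical_samples(self):
        d, _ = year_comparison([2000, 2010, 2020], [2000, 2010, 2020])
        assert d == 0.0

    def test_disjoint_supports(self):
        d, p = year_comparison([1990] * 20, [2015] * 20)
        assert d == 1.0
        assert p < 0.001

    def test_matches_bruteforce_sup_difference(self, rng):
        a = rng.integers(1990, 2021, 50)
        b = rng.integers(1995, 2021, 50)
        d, _ = year_comparison(a, b)
        # brute-force sup over empirical CDF differences
        points = np.union1d(a, b)
        sup = max(
            abs((a <= x).mean() - (b <= x).mean()) for x in points
        )
        assert d == pytest.approx(sup)

    def test_histogram_bins(self):
        h = year_histogram([1991, 1999, 2001, 2015], start=1990, end=2020)
        assert int(h["count"].sum()) == 4
        assert h["interval"].iloc[0] == "1991-2000"


class TestDiagnosisIO:
    def test_comp_het_requires_two_variants(self):
        with pytest.raises(ValueError, match="exactly 2"):
            Diagnosis("p", "g", "AR_comp_het", variants=[Variant("P")])

    def test_frame_round_trip(self):
        diagnoses = [
            _diag(pid="p1", moi="AR_comp_het",
                  variants=[Variant("P", af=0.001), Variant("LP", lof=True)]),
            _diag(pid="p2", moi="AD_de_novo", mosaic=True,
                  year_first_assoc=2015, novel_gene=True),
        ]
        back = diagnoses_from_frame(diagnoses_to_frame(diagnoses))
        assert back[0].variants[1].clinvar_class == "LP"
        assert back[0].variants[1].lof
        assert back[1].mosaic and back[1].novel_gene
        assert back[1].year_first_assoc == 2015
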