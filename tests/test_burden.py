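import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from pedscan.burden import (
    BurdenResult,
    FamilyCohort,
    collapse_per_family,
    gene_burden_test,
    singleton_report,
)
from pedscan.pedigree import Individual, Pedigree
from pedscan.simulate import multiplex_cohort_pedigrees, simulate_burden_cohort


class TestCollapse:
    def test_table_counts(self):
        """12 affected carriers in 6 families, 5 unaffected relatives and 5
        unrelated unaffected subjects collapse to 6 MS families and 5
        control subjects."""
        carriers = (
            [{"individual": f"p{i}", "family": f"f{i % 6}", "status": "affected"}
             for i in range(12)]
            + [{"individual": f"r{i}", "family": f"f{i}", "status": "unaffected"}
               for i in range(5)]
            + [{"individual": f"u{i}", "family": "unrelated", "status": "unaffected"}
               for i in range(5)]
        )
        assert collapse_per_family(carriers) == {
            "n_ms_families": 6, "n_control_subjects": 5,
        }

    def test_single_unrelated_unaffected(self):
        out = collapse_per_family(
            [{"individual": "x", "family": None, "status": "unaffected"}]
        )
        assert out == {"n_ms_families": 0, "n_control_subjects": 1}

    def test_two_affected_same_family_collapse(self):
        out = collapse_per_family(
            [{"individual": "a", "family": "f", "status": "affected"},
             {"individual": "b", "family": "f", "status": "affected"}]
        )
        assert out == {"n_ms_families": 1, "n_control_subjects": 0}

    def test_invalid_status_rejected(self):
        with pytest.raises(ValueError):
            collapse_per_family([{"individual": "a", "family": "f", "status": "?"}])


def _unrelated_cohort(dosage_rows, phenos, gene="G"):
    peds = [
        Pedigree([Individual(f"s{i}", affected="yes" if y else "no")],
                 family_id=f"s{i}")
        for i, y in enumerate(phenos)
    ]
    geno = pd.DataFrame(
        np.asarray(dosage_rows, dtype=float),
        index=[f"{gene}_v{j}" for j in range(len(dosage_rows))],
        columns=[f"s{i}" for i in range(len(phenos))],
    )
    return FamilyCohort(peds, geno, {f"{gene}_v{j}": gene for j in range(len(dosage_rows))})


class TestGeneBurden:
    def test_identical_burden_gives_zero_stat(self):
        cohort = _unrelated_cohort([[1, 1, 1, 1], [0, 0, 0, 0]], [1, 1, 0, 0])
        r = gene_burden_test(cohort, "G")
        assert r.stat == 0.0

    def test_unrelated_case_matches_closed_form(self):
        """With singleton families the statistic must equal the classical
        score statistic computed by an independent direct formula."""
        rng = np.random.default_rng(0)
        n = 60
        phenos = [1] * 25 + [0] * 35
        dosage = rng.integers(0, 3, size=(3, n))
        cohort = _unrelated_cohort(dosage, phenos)
        r = gene_burden_test(cohort, "G", seed=5)
        # oracle: U / sqrt(var_geno * sum c^2), p_hat over all singletons
        y = np.array(phenos, float)
        c = y - y.mean()
        b = dosage.sum(axis=0)
        U = float(c @ b)
        p_hat = dosage.mean(axis=1) / 2.0
        V = float(np.sum(2 * p_hat * (1 - p_hat))) * float(c @ c)
        assert r.stat == pytest.approx(U / math.sqrt(V), abs=1e-9)
        assert r.p == pytest.approx(2 * norm.sf(abs(r.stat)), abs=1e-12)

    def test_sign_convention_cases_enriched_positive(self):
        cohort = _unrelated_cohort(
            [[2, 2, 1, 0, 0, 0], [1, 2, 1, 0, 0, 0]], [1, 1, 1, 0, 0, 0]
        )
        assert gene_burden_test(cohort, "G").stat > 0

    def test_no_variation_flagged_untested(self):
        cohort = _unrelated_cohort([[0, 0, 0, 0], [0, 0, 0, 0]], [1, 1, 0, 0])
        r = gene_burden_test(cohort, "G")
        assert (r.stat, r.p, r.tested) == (0.0, 1.0, False)

    def test_single_variant_gene_rejected(self):
        cohort = _unrelated_cohort([[1, 0, 1, 0]], [1, 1, 0, 0])
        with pytest.raises(ValueError, match=">= 2"):
            gene_burden_test(cohort, "G")

    def test_power_ordering(self):
        """Raising the case-control carrier-frequency gap never lowers the
        mean |stat| (Monte-Carlo grid)."""
        rng = np.random.default_rng(1)
        n_cases, n_ctrl = 40, 40
        mean_stats = []
        for gap in (0.0, 0.15, 0.35):
            stats = []
            for _ in range(60):
                pc, p0 = 0.1 + gap, 0.1
                cases = (rng.random((2, n_cases)) < pc).astype(float)
                ctrls = (rng.random((2, n_ctrl)) < p0).astype(float)
                cohort = _unrelated_cohort(
                    np.hstack([cases, ctrls]), [1] * n_cases + [0] * n_ctrl
                )
                stats.append(abs(gene_burden_test(cohort, "G").stat))
            mean_stats.append(np.mean(stats))
        assert mean_stats[0] <= mean_stats[1] + 0.2 <= mean_stats[2] + 0.2

    def test_kinship_scales_null_variance(self):
        """With affection clustered in one family, the kinship term
        c'(2 Phi)c exceeds c'c, so the family-adjusted statistic shrinks by
        exactly sqrt(c'(2 Phi)c / c'c) relative to the unrelated form."""
        fam = Pedigree(
            [
                Individual("F", sex="male", affected="no"),
                Individual("M", sex="female", affected="yes"),
                Individual("C1", "F", "M", affected="yes"),
                Individual("C2", "F", "M", affected="yes"),
            ],
            family_id="FAM",
        )
        singles = [
            Pedigree([Individual(f"u{i}", affected="no")], family_id=f"u{i}")
            for i in range(4)
        ]
        cols = ["F", "M", "C1", "C2"] + [f"u{i}" for i in range(4)]
        dosage = np.array([[1, 2, 1, 1, 0, 1, 0, 0],
                           [0, 1, 1, 2, 1, 0, 0, 1]], dtype=float)
        geno = pd.DataFrame(dosage, index=["G_v0", "G_v1"], columns=cols)
        related = FamilyCohort([fam] + singles, geno, {"G_v0": "G", "G_v1": "G"})
        freqs = {"G_v0": 0.2, "G_v1": 0.2}
        r_rel = gene_burden_test(related, "G", allele_freqs=freqs)
        phenos = [0, 1, 1, 1, 0, 0, 0, 0]
        unrelated = _unrelated_cohort(dosage, phenos)
        r_unr = gene_burden_test(unrelated, "G", allele_freqs=freqs)
        y = np.asarray(phenos, float)
        c = y - y.mean()
        K2 = related.kinship2.loc[cols, cols].to_numpy()
        ratio = math.sqrt(float(c @ K2 @ c) / float(c @ c))
        assert ratio > 1.0  # clustered affection inflates the null variance
        assert r_rel.stat == pytest.approx(r_unr.stat / ratio, abs=1e-9)


class TestSingletonReport:
    def test_one_variant_gene_descriptive_record(self):
        peds = multiplex_cohort_pedigrees(n_families=2, n_unrelated=2)
        ids = [m.id for p in peds for m in p]
        geno = pd.DataFrame(0.0, index=["G_v0"], columns=ids)
        geno.loc["G_v0", "FAM00_C1"] = 1.0  # affected family member
        geno.loc["G_v0", "FAM00_F"] = 1.0   # unaffected relative, same family
        geno.loc["G_v0", "HC00"] = 1.0      # unrelated control
        cohort = FamilyCohort(peds, geno, {"G_v0": "G"})
        rec = singleton_report(cohort, "G")
        assert rec["n_ms_families"] == 1
        assert rec["n_control_subjects"] == 1

    def test_zero_variant_gene_omitted(self):
        cohort = _unrelated_cohort([[1, 0]], [1, 0], gene="OTHER")
        assert singleton_report(cohort, "MISSING") is None

    def test_controls_only_carrier(self):
        peds = multiplex_cohort_pedigrees(n_families=1, n_unrelated=1)
        ids = [m.id for p in peds for m in p]
        geno = pd.DataFrame(0.0, index=["G_v0"], columns=ids)
        geno.loc["G_v0", "HC00"] = 2.0
        cohort = FamilyCohort(peds, geno, {"G_v0": "G"})
        rec = singleton_report(cohort, "G")
        assert rec["n_ms_families"] == 0
        assert rec["n_control_subjects"] == 1
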