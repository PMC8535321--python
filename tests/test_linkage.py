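import math

import numpy as np
import pandas as pd
import pytest

from pedscan.io import GenotypeTable
from pedscan.linkage import (
    FamilyLinkage,
    call_linkage_regions,
    kong_cox_p,
    multipoint_npl,
    npl_normalize,
    s_all,
)
from pedscan.pedigree import Individual, Pedigree
from conftest import make_genotype_table


@pytest.fixture(scope="module")
def sib_engine(sib_pair):
    return FamilyLinkage(sib_pair)


def _sib_vector(s1_bits, s2_bits):
    """Vector index for sib-pair bits (paternal, maternal per sib)."""
    b = [s1_bits[0], s1_bits[1], s2_bits[0], s2_bits[1]]
    return sum(bit << i for i, bit in enumerate(b))


class TestSAll:
    def test_one_affected_family_rejected(self):
        ped = Pedigree(
            [
                Individual("F", sex="male"), Individual("M", sex="female"),
                Individual("C", "F", "M", affected="yes"),
            ]
        )
        with pytest.raises(ValueError, match="affected"):
            FamilyLinkage(ped)

    def test_sib_pair_ibd2(self, sib_pair, sib_engine):
        # identical meiosis bits -> both alleles shared: (2!+1+1+2!)/4 = 1.5
        v = _sib_vector((0, 0), (0, 0))
        assert s_all(sib_pair, v, engine=sib_engine) == 1.5

    def test_sib_pair_ibd0(self, sib_pair, sib_engine):
        v = _sib_vector((0, 0), (1, 1))
        assert s_all(sib_pair, v, engine=sib_engine) == 1.0

    def test_sib_pair_null_moments(self, sib_pair, sib_engine):
        mu0, sigma0, Z = npl_normalize(sib_pair, engine=sib_engine)
        assert mu0 == pytest.approx(1.25)
        assert sigma0 ** 2 == pytest.approx(0.03125)
        assert Z[_sib_vector((0, 0), (0, 0))] == pytest.approx(math.sqrt(2))


class TestNullCalibration:
    @pytest.mark.parametrize("ped_name", ["sib_pair", "family"])
    def test_z_exactly_standardized(self, ped_name, request):
        """Sum_v P0(v) Z(v) = 0 and Sum_v P0(v) Z(v)^2 = 1 exactly."""
        eng = FamilyLinkage(request.getfixturevalue(ped_name))
        assert abs(eng.Z.mean()) < 1e-9
        assert abs(eng.Z.var() - 1.0) < 1e-9


class TestGenotypeLikelihood:
    def test_all_missing_is_uniform(self, family_engine):
        lik = family_engine.marker_likelihood(
            {i: None for i in family_engine.ped.genotyped_ids}, 0.3
        )
        assert np.allclose(lik, lik[0])

    def test_mendelian_impossibility_zeroes_all_vectors(self):
        ped = Pedigree(
            [
                Individual("F", sex="male"), Individual("M", sex="female"),
                Individual("C1", "F", "M", affected="yes"),
                Individual("C2", "F", "M", affected="yes"),
            ]
        )
        eng = FamilyLinkage(ped)
        lik = eng.marker_likelihood({"F": 0, "M": 0, "C1": 2}, 0.3)
        assert np.all(lik == 0.0)

    def test_informative_marker_supports_compatible_vectors_only(self, sib_engine):
        # F = 1, M = 1, both sibs 2: each sib must receive the alt allele
        # from both parents; compatible vectors get positive likelihood.
        lik = sib_engine.marker_likelihood({"F": 1, "M": 1, "S1": 2, "S2": 2}, 0.5)
        assert lik.max() > 0
        compat = lik > 0
        Z = sib_engine.Z
        # all compatible vectors imply IBD2 between the sibs
        assert np.all(Z[compat] == Z.max())

    def test_packed_path_matches_coloring_reference(self, family_engine):
        rng = np.random.default_rng(11)
        ids = family_engine.ped.genotyped_ids
        for _ in range(10):
            dosages = {
                i: (float(rng.integers(0, 3)) if rng.random() < 0.8 else None)
                for i in ids
            }
            freq = float(rng.uniform(0.05, 0.95))
            fast = family_engine.marker_likelihood(dosages, freq)
            slow = family_engine.marker_likelihood_by_coloring(dosages, freq)
            np.testing.assert_allclose(fast, slow, atol=1e-14)

    def test_invalid_frequency_rejected(self, family_engine):
        with pytest.raises(ValueError):
            family_engine.marker_likelihood({}, 1.0)


class TestKongCox:
    def test_uniform_posterior_is_null(self, family_engine):
        V = family_engine.n_vectors
        res = family_engine.kong_cox(np.full(V, 1.0 / V))
        assert res.exlod == 0.0
        assert res.delta_hat == 0.0
        assert res.p == 0.5

    def test_sib_pair_perfect_ibd2_limit(self, sib_engine):
        """exLOD -> log10 4 = -log10 P0(IBD2) for a perfectly typed sib pair."""
        res = sib_engine.kong_cox(sib_engine.max_sharing_posterior())
        assert res.exlod == pytest.approx(math.log10(4.0), abs=1e-9)

    def test_supremum_identity_by_enumeration(self, family_engine):
        """sup_delta exLOD = -log10 P0(maximal sharing class)."""
        S = family_engine.s_all_vector()
        p0 = (S >= S.max() - 1e-12).mean()
        res = family_engine.kong_cox(family_engine.max_sharing_posterior())
        assert res.exlod == pytest.approx(-math.log10(p0), abs=1e-9)

    def test_p_exlod_consistency(self, family_engine):
        rng = np.random.default_rng(3)
        for _ in range(5):
            w = rng.dirichlet(np.ones(family_engine.n_vectors))
            res = family_engine.kong_cox(w)
            assert res.p == pytest.approx(kong_cox_p(res.exlod))

    def test_complete_information_tail_mildly_anticonservative(self, family_engine):
        """Exact null tail of the statistic for the index family: under
        complete marker information, P0(exLOD > 0.588) - the nominal
        p < 0.05 event - sits a little above 0.05 because the NPL-all Z is
        right-skewed for a single family (normal-approximation p)."""
        eng = family_engine
        thr = 0.5879  # exLOD whose normal-approximation p equals 0.05
        vals = np.unique(np.round(eng.Z, 10))
        tail = 0.0
        for z in vals:
            w = (np.abs(eng.Z - z) < 1e-9).astype(float)
            if eng.kong_cox(w / w.sum()).exlod > thr:
                tail += w.sum() / eng.n_vectors
        assert 0.05 < tail < 0.10
        assert tail == pytest.approx(0.078125, abs=1e-9)

    def test_negative_sharing_evidence_gives_zero(self, sib_engine):
        # posterior concentrated on IBD0: one-sided model reports 0
        w = (sib_engine.Z <= sib_engine.Z.min() + 1e-12).astype(float)
        res = sib_engine.kong_cox(w / w.sum())
        assert res.exlod == 0.0
        assert res.p == 0.5


def _informative_table(engine, n, spacing_cm, af=0.5):
    """Markers typed so every genotyped member is het/hom as in perfect
    IBD2 sharing data for a sib pair."""
    variants = pd.DataFrame(
        {
            "CHROM": "1",
            "POS": 1_000_000 + 1_000_000 * np.arange(n),
            "REF": "A",
            "ALT": "G",
            "AF": af,
            "CM": spacing_cm * np.arange(n, dtype=float),
        }
    )
    calls = pd.DataFrame(
        {"F": [1.0] * n, "M": [1.0] * n, "S1": [2.0] * n, "S2": [2.0] * n}
    )
    return GenotypeTable(variants, calls)


class TestMultipoint:
    def test_single_marker_equals_single_point(self, sib_pair, sib_engine):
        table = _informative_table(sib_engine, 1, 1.0)
        track = multipoint_npl(sib_pair, table, engine=sib_engine)
        lik = sib_engine.marker_likelihood({"F": 1, "M": 1, "S1": 2, "S2": 2}, 0.5)
        direct = sib_engine.kong_cox(lik / lik.sum())
        assert track.EXLOD.iloc[0] == pytest.approx(direct.exlod, abs=1e-12)

    def test_flanking_missing_markers_do_not_change_focal_exlod(
        self, sib_pair, sib_engine
    ):
        table = _informative_table(sib_engine, 3, 5.0)
        table.calls.iloc[0] = np.nan
        table.calls.iloc[2] = np.nan
        track = multipoint_npl(sib_pair, table, engine=sib_engine)
        solo = multipoint_npl(sib_pair, _informative_table(sib_engine, 1, 1.0),
                              engine=sib_engine)
        assert track.EXLOD.iloc[1] == pytest.approx(solo.EXLOD.iloc[0], abs=1e-12)

    def test_tightly_linked_duplicate_marker_collapses(self, sib_pair, sib_engine):
        """Two identical informative markers at theta ~ 0 carry the same
        information as either alone."""
        table = _informative_table(sib_engine, 2, 1e-9)
        track = multipoint_npl(sib_pair, table, engine=sib_engine)
        solo = multipoint_npl(sib_pair, _informative_table(sib_engine, 1, 1.0),
                              engine=sib_engine)
        assert track.EXLOD.iloc[0] == pytest.approx(solo.EXLOD.iloc[0], abs=1e-9)
        assert track.EXLOD.iloc[1] == pytest.approx(solo.EXLOD.iloc[0], abs=1e-9)

    def test_unordered_markers_rejected(self, sib_pair, sib_engine):
        table = _informative_table(sib_engine, 2, 1.0)
        table.variants.loc[0, "POS"] = 9_999_999_999
        with pytest.raises(ValueError, match="ordered"):
            sib_engine.multipoint_posteriors(table)

    def test_sex_chromosomes_excluded_by_default(self, sib_pair, sib_engine):
        table = _informative_table(sib_engine, 2, 1.0)
        table.variants["CHROM"] = ["1", "X"]
        track = multipoint_npl(sib_pair, table, engine=sib_engine)
        assert track.CHROM.tolist() == ["1"]


def _track(lods, positions=None, chrom="1"):
    n = len(lods)
    pos = positions if positions is not None else 100 * (np.arange(n) + 1)
    return pd.DataFrame(
        {
            "CHROM": chrom,
            "POS": pos,
            "REF": "A",
            "ALT": "G",
            "CM": np.arange(n, dtype=float),
            "Z": 0.0,
            "EXLOD": lods,
            "P": [kong_cox_p(l) if l > 0 else 0.5 for l in lods],
        }
    )


class TestRegionCalling:
    def test_all_zero_track_has_no_regions(self):
        assert call_linkage_regions(_track([0.0, 0.0, 0.0])) == []

    def test_peak_and_shore(self):
        track = _track([0.0, 0.3, 1.806, 1.2, 0.0, 0.4],
                       positions=[100, 200, 300, 400, 500, 600])
        regions = call_linkage_regions(track)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end) == (100, 500)
        assert r.peak_positions == (300,)
        assert r.max_exlod == pytest.approx(1.806)

    def test_shore_sharing_peaks_merge(self):
        track = _track([0.2, 1.8, 0.0, 1.8, 0.5],
                       positions=[100, 200, 300, 400, 500])
        regions = call_linkage_regions(track)
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (100, 500)
        assert regions[0].peak_positions == (200, 400)

    def test_chromosome_end_terminates_region(self):
        track = _track([1.8, 0.7, 0.0])
        regions = call_linkage_regions(track)
        assert (regions[0].start, regions[0].end) == (100, 300)

    def test_subpeak_variants_do_not_seed_regions(self):
        # second bump never reaches the track maximum: no second region
        track = _track([0.0, 1.8, 0.0, 0.9, 0.0])
        regions = call_linkage_regions(track)
        assert len(regions) == 1
        assert regions[0].peak_positions == (200,)
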