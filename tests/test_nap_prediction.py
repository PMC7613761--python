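"""The four-filter candidate pipeline and the generalized ESD test."""

import numpy as np
import pandas as pd
import pytest

from napscan import nap_prediction as npred
from napscan.io_formats import (
    DomainHit,
    ModelSource,
    OperonMap,
    QuantTable,
    ValidationError,
)
from napscan.quantification import fractional_abundances
from napscan.synthetic_data import build_default_classification

from _oracles import brute_force_esd

CLS = build_default_classification()
DBD = sorted(CLS.dna_binding_domains)[0]
TFGO = sorted(CLS.tf_domains - CLS.dna_binding_domains)[0]


class TestSizeFilter:
    @pytest.mark.parametrize(
        "length,expected", [(289, True), (290, False), (74, True), (1, True)]
    )
    def test_strict_inequality(self, length, expected):
        assert npred.size_filter(length) is expected

    def test_invalid_length(self):
        with pytest.raises(ValidationError):
            npred.size_filter(0)


class TestDnaBindingFilter:
    def test_zero_score_no_domain_fails(self):
        assert not npred.dna_binding_filter("p1", [], CLS, {"p1": 0.0})

    def test_small_positive_score_passes(self):
        assert npred.dna_binding_filter("p1", [], CLS, {"p1": 0.01})

    def test_domain_overrides_negative_score(self):
        hits = [DomainHit("p1", DBD, ModelSource.PFAM, 1e-8, 30.0)]
        assert npred.dna_binding_filter("p1", hits, CLS, {"p1": -5.0})

    def test_missing_score_no_domain_fails(self):
        assert not npred.dna_binding_filter("p1", [], CLS, {})


class TestEsdOutliers:
    def test_constant_vector_no_outliers(self):
        res = npred.esd_outliers([3.0] * 10, k_max=3)
        assert res.n_outliers == 0
        assert res.flagged == set()

    def test_single_spike_flagged(self):
        res = npred.esd_outliers([1, 2, 3, 4, 5, 100], k_max=2, alpha=0.05)
        assert res.n_outliers == 1
        assert res.flagged == {5}
        # step-1 statistic from the definition: R = (100 - mean) / sd
        x = np.array([1, 2, 3, 4, 5, 100.0])
        expected_r1 = (100 - x.mean()) / x.std(ddof=1)
        assert res.stats[0][0] == pytest.approx(expected_r1)

    def test_alpha_monotone_nesting(self, rng):
        # stricter alpha can only flag a subset of what looser alpha flags
        for _ in range(50):
            n = int(rng.integers(10, 25))
            x = rng.normal(size=n)
            x[: rng.integers(0, 3)] += 10
            strict = npred.esd_outliers(x, k_max=4, alpha=0.01)
            loose = npred.esd_outliers(x, k_max=4, alpha=0.05)
            assert strict.flagged <= loose.flagged

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(100):
            n = int(rng.integers(8, 31))
            x = rng.normal(size=n)
            k = int(rng.integers(1, min(6, n - 2)))
            res = npred.esd_outliers(x, k_max=k)
            n_out, flagged = brute_force_esd(x, k, 0.05)
            assert res.n_outliers == n_out
            assert res.flagged == flagged

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValidationError):
            npred.esd_outliers([1.0, 2.0, 3.0], k_max=2)

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError):
            npred.esd_outliers([1.0, float("nan"), 2.0, 3.0, 4.0, 5.0], k_max=1)


class TestAbundanceOutlierFilter:
    def test_candidate_at_tf_median_excluded(self, rng):
        tf = list(rng.normal(1.0, 0.1, size=50))
        median = float(np.median(tf))
        flagged = npred.abundance_outlier_filter(
            {"cand": median}, tf, log_transform=False
        )
        assert flagged == set()

    def test_six_sigma_spike_included(self, rng):
        tf = list(rng.normal(1.0, 0.1, size=50))
        spike = float(np.mean(tf) + 6 * np.std(tf, ddof=1))
        flagged = npred.abundance_outlier_filter(
            {"cand": spike}, tf, log_transform=False
        )
        assert flagged == {"cand"}

    def test_low_side_extreme_never_returned(self, rng):
        tf = list(rng.normal(1.0, 0.1, size=50))
        low = float(np.mean(tf) - 8 * np.std(tf, ddof=1))
        flagged = npred.abundance_outlier_filter(
            {"cand": low}, tf, log_transform=False
        )
        assert flagged == set()

    def test_leave_one_in_resists_masking(self, rng):
        # two co-candidates of similar extremity must both be found
        tf = list(rng.normal(1.0, 0.1, size=60))
        hi = float(np.mean(tf) + 6 * np.std(tf, ddof=1))
        flagged = npred.abundance_outlier_filter(
            {"c1": hi, "c2": hi * 1.01}, tf, log_transform=False
        )
        assert flagged == {"c1", "c2"}


class TestSingleOperonFilter:
    OM = OperonMap({"op1": ["solo"], "op2": ["a", "b"]})

    def test_singleton_passes(self):
        assert npred.single_operon_filter("solo", self.OM)

    def test_pair_fails(self):
        assert not npred.single_operon_filter("a", self.OM)

    def test_unassigned_fails_with_warning(self):
        with pytest.warns(UserWarning, match="ghost"):
            assert not npred.single_operon_filter("ghost", self.OM)


def build_fixture_proteome(rng, spike_known=False, spike_length=70):
    """One spiked NAP-like protein among TFs and engineered decoys."""
    raws = {}
    hits = []
    lengths = {}
    scores = {}
    operons = {}
    # 60 transcription factors, tight abundance band
    for i in range(60):
        pid = f"tf{i}"
        raws[pid] = float(10 ** rng.normal(2.0, 0.1))
        hits.append(DomainHit(pid, TFGO, ModelSource.PFAM, 1e-9, 40.0))
        lengths[pid] = 300
        scores[pid] = -2.0
        operons[f"op_tf{i}"] = [pid]
    # the spiked candidate: small, DNA-binding, 10x the TF maximum, singleton
    raws["spike"] = max(raws.values()) * 10
    hits.append(DomainHit("spike", DBD, ModelSource.PFAM, 1e-12, 80.0))
    lengths["spike"] = spike_length
    scores["spike"] = 1.0
    operons["op_spike"] = ["spike"]
    # decoys, each failing exactly one filter
    raws["too_long"] = raws["spike"]
    hits.append(DomainHit("too_long", DBD, ModelSource.PFAM, 1e-12, 80.0))
    lengths["too_long"] = 400
    scores["too_long"] = 1.0
    operons["op_long"] = ["too_long"]
    raws["no_dna"] = raws["spike"]
    lengths["no_dna"] = 80
    scores["no_dna"] = -1.0
    operons["op_nodna"] = ["no_dna"]
    raws["in_operon"] = raws["spike"]
    hits.append(DomainHit("in_operon", DBD, ModelSource.PFAM, 1e-12, 80.0))
    lengths["in_operon"] = 80
    scores["in_operon"] = 1.0
    raws["partner"] = 100.0
    lengths["partner"] = 350
    scores["partner"] = -2.0
    operons["op_pair"] = ["in_operon", "partner"]
    raws["low_ab"] = float(10 ** rng.normal(2.0, 0.1))
    hits.append(DomainHit("low_ab", DBD, ModelSource.PFAM, 1e-12, 80.0))
    lengths["low_ab"] = 80
    scores["low_ab"] = 1.0
    operons["op_low"] = ["low_ab"]

    data = pd.DataFrame(
        {
            "protein_id": list(raws),
            "raw_intensity": list(raws.values()),
            "lfq_intensity": float("nan"),
            "aliases": "",
        }
    )
    fp = fractional_abundances(QuantTable("spX", "c", "r1", data), prefer_lfq=False)
    known = {"spike"} if spike_known else set()
    return fp, lengths, hits, scores, OperonMap(operons), known


class TestPredictCandidates:
    def test_recovers_only_the_spike(self, rng):
        fp, lengths, hits, scores, om, known = build_fixture_proteome(rng)
        cands = npred.predict_candidates(fp, lengths, hits, CLS, scores, om, known)
        assert [c.protein_id for c in cands] == ["spike"]
        c = cands[0]
        assert c.rank == 1
        assert all(c.passes.values())

    def test_known_nap_excluded(self, rng):
        fp, lengths, hits, scores, om, known = build_fixture_proteome(
            rng, spike_known=True
        )
        cands = npred.predict_candidates(fp, lengths, hits, CLS, scores, om, known)
        assert cands == []

    def test_oversized_spike_rejected(self, rng):
        fp, lengths, hits, scores, om, known = build_fixture_proteome(
            rng, spike_length=300
        )
        cands = npred.predict_candidates(fp, lengths, hits, CLS, scores, om, known)
        assert cands == []

    def test_relax_operon_recovers_operon_decoy(self, rng):
        fp, lengths, hits, scores, om, known = build_fixture_proteome(rng)
        cands = npred.predict_candidates(
            fp, lengths, hits, CLS, scores, om, known,
            params=npred.PredictionParams(relax_operon=True),
        )
        assert {c.protein_id for c in cands} == {"spike", "in_operon"}

    def test_stable_under_row_permutation(self, rng):
        fp, lengths, hits, scores, om, known = build_fixture_proteome(rng)
        perm = rng.permutation(len(fp.fractions))
        fp_shuffled = type(fp)(
            species_id=fp.species_id,
            condition=fp.condition,
            fractions=fp.fractions.iloc[perm],
            n_detected=fp.n_detected,
            intensity_basis=fp.intensity_basis,
        )
        a = npred.predict_candidates(fp, lengths, hits, CLS, scores, om, known)
        b = npred.predict_candidates(fp_shuffled, lengths, hits, CLS, scores, om, known)
        assert [c.protein_id for c in a] == [c.protein_id for c in b]

    def test_increasing_abundance_keeps_candidate(self, rng):
        fp, lengths, hits, scores, om, known = build_fixture_proteome(rng)
        boosted = fp.fractions.copy()
        boosted["spike"] *= 3
        boosted *= 100.0 / boosted.sum()
        fp_boosted = type(fp)(
            species_id=fp.species_id,
            condition=fp.condition,
            fractions=boosted,
            n_detected=fp.n_detected,
            intensity_basis=fp.intensity_basis,
        )
        cands = npred.predict_candidates(
            fp_boosted, lengths, hits, CLS, scores, om, known
        )
        assert "spike" in {c.protein_id for c in cands}
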