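"""Diversity estimators against closed forms and an independent dual implementation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from memscape.datamodel import AbundanceMatrix, ValidationError
from memscape.diversity import (
    AbundanceVector,
    asymptotic_shannon,
    diversity_table,
    rarefaction_curve,
    tsallis_entropy,
)
from conftest import make_sites

count_vectors = st.lists(st.integers(0, 40), min_size=2, max_size=15).filter(
    lambda c: sum(c) >= 2 and sum(1 for x in c if x > 0) >= 1
)


# ------------------------------------------------------------------ oracle

def chao_jost_shannon_oracle(counts):
    """Independent transcription of the asymptotic Shannon entropy estimator,
    written directly from the published formula with naive loops."""
    counts = [int(c) for c in counts if c > 0]
    n = sum(counts)
    h = 0.0
    for x in counts:
        if 1 <= x <= n - 1:
            h += (x / n) * sum(1.0 / k for k in range(x, n))
    f1 = sum(1 for x in counts if x == 1)
    f2 = sum(1 for x in counts if x == 2)
    if f1 > 0:
        if f2 > 0:
            a = 2 * f2 / ((n - 1) * f1 + 2 * f2)
        else:
            a = 2 / ((n - 1) * (f1 - 1) + 2)
        if a < 1:
            series = sum((1 - a) ** r / r for r in range(1, n))
            h += (f1 / n) * (1 - a) ** (1 - n) * (-np.log(a) - series)
    return np.exp(h)


class TestTsallis:
    def test_uniform_community_q2(self):
        for s in (2, 5, 10):
            v = np.full(s, 7)
            assert tsallis_entropy(v, 2.0) == pytest.approx(1 - 1 / s, abs=1e-12)

    def test_q0_is_richness_minus_one(self):
        v = np.array([4, 1, 9, 2])
        assert tsallis_entropy(v, 0.0) == pytest.approx(3.0, abs=1e-12)

    def test_q_near_one_approaches_shannon(self):
        v = np.array([10, 5, 3, 1, 1])
        shannon = tsallis_entropy(v, 1.0)
        for q in (1 - 1e-6, 1 + 1e-6):
            assert tsallis_entropy(v, q) == pytest.approx(shannon, abs=1e-4)

    def test_negative_q_rejected(self):
        with pytest.raises(ValidationError):
            tsallis_entropy(np.array([1, 2]), -0.5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(counts=count_vectors, q1=st.floats(0, 3), q2=st.floats(0, 3))
    def test_profile_non_increasing_in_q(self, counts, q1, q2):
        lo, hi = sorted([q1, q2])
        assert tsallis_entropy(np.array(counts), lo) >= (
            tsallis_entropy(np.array(counts), hi) - 1e-10
        )


class TestAsymptoticShannon:
    def test_single_species_is_one(self):
        assert asymptotic_shannon(np.array([17])) == pytest.approx(1.0, abs=1e-12)

    def test_no_singletons_gives_plugin_correction_only(self):
        counts = np.array([5, 3, 3, 4])  # f1 = 0: tail term vanishes
        got = asymptotic_shannon(counts)
        assert got == pytest.approx(chao_jost_shannon_oracle(counts), abs=1e-10)
        v = AbundanceVector(counts)
        n = v.n
        expected_h = sum(
            (x / n) * sum(1.0 / k for k in range(x, n)) for x in v.counts
        )
        assert got == pytest.approx(np.exp(expected_h), abs=1e-10)

    def test_toy_vector_matches_oracle(self):
        assert asymptotic_shannon(np.array([4, 2, 1])) == pytest.approx(
            chao_jost_shannon_oracle([4, 2, 1]), abs=1e-10
        )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(counts=count_vectors)
    def test_matches_oracle_everywhere(self, counts):
        assert asymptotic_shannon(np.array(counts)) == pytest.approx(
            chao_jost_shannon_oracle(counts), rel=1e-10
        )

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(counts=count_vectors.filter(lambda c: any(x == 1 for x in c)))
    def test_extrapolation_never_below_plugin(self, counts):
        v = AbundanceVector(np.array(counts))
        plugin = np.exp(-(v.p * np.log(v.p)).sum())
        # finite-sample + unseen-species corrections only add diversity
        assert asymptotic_shannon(v) >= plugin - 1e-9

    def test_sample_of_one_rejected(self):
        with pytest.raises(ValidationError):
            asymptotic_shannon(np.array([1]))


class TestRarefaction:
    def test_full_depth_recovers_observed_richness(self):
        v = np.array([5, 3, 2, 1])
        assert rarefaction_curve(v, [11])[0] == pytest.approx(4.0, abs=1e-10)

    def test_single_draw_sees_one_species(self):
        assert rarefaction_curve(np.array([5, 3]), [1])[0] == pytest.approx(1.0)

    def test_hand_hypergeometric_case(self):
        # counts (3,1), m=2: 1 + (1 - C(3,2)/C(4,2)) = 1.5
        assert rarefaction_curve(np.array([3, 1]), [2])[0] == pytest.approx(1.5, abs=1e-12)

    def test_depth_beyond_sample_rejected(self):
        with pytest.raises(ValidationError):
            rarefaction_curve(np.array([2, 1]), [4])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(counts=count_vectors.filter(lambda c: sum(c) >= 3))
    def test_curve_non_decreasing_and_concave(self, counts):
        v = AbundanceVector(np.array(counts))
        depths = np.arange(1, v.n + 1)
        curve = rarefaction_curve(v, depths)
        diffs = np.diff(curve)
        assert np.all(diffs >= -1e-9)
        assert np.all(np.diff(diffs) <= 1e-9)


class TestDiversityTable:
    def _matrix(self, counts, habitats):
        counts = np.asarray(counts)
        sites = make_sites(
            np.column_stack([np.arange(len(counts)), (np.arange(len(counts)) % 3) * 1.7]),
            habitats=habitats,
        )
        df = pd.DataFrame(
            counts,
            index=pd.Index(sites.site_ids, name="site_id"),
            columns=[f"sp{j}" for j in range(counts.shape[1])],
        )
        return AbundanceMatrix(sites=sites, counts=df)

    def test_one_row_per_site(self):
        a = self._matrix(np.ones((4, 3), dtype=int), ["Crop"] * 2 + ["Oak"] * 2)
        t = diversity_table(a, q=0.5)
        assert len(t["sites"]) == 4
        assert set(t["groups"]["habitat"]) == {"Crop", "Oak"}

    def test_species_label_invariance(self):
        rng = np.random.default_rng(9)
        counts = rng.poisson(4, (6, 20)) + 1
        a = self._matrix(counts, ["Crop", "Edge", "Oak"] * 2)
        perm = rng.permutation(20)
        b = self._matrix(counts[:, perm], ["Crop", "Edge", "Oak"] * 2)
        ta, tb = diversity_table(a)["sites"], diversity_table(b)["sites"]
        assert np.allclose(ta["S_q"], tb["S_q"])
        assert np.allclose(ta["D_AE"], tb["D_AE"])

    def test_seasonal_grouping(self):
        counts = np.random.default_rng(10).poisson(5, (8, 10)) + 1
        a = self._matrix(counts, ["Crop"] * 4 + ["Oak"] * 4)
        meta = pd.DataFrame(
            {"site_id": a.sites.site_ids, "season": ["dry", "wet"] * 4}
        )
        t = diversity_table(a, metadata=meta)
        assert set(t["groups"]["season"]) == {"dry", "wet"}
        assert {"S_q_mean", "S_q_std", "D_AE_mean"} <= set(t["groups"].columns)
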