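"""Log-ratio transforms, group tests, pivot coordinates, UPGMA clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from scipy.cluster import hierarchy as sch

from histoptm.quantify import compositions
from histoptm.regions import ValidationError
from histoptm.stats import (
    alr2,
    build_profile_matrix,
    compare_groups,
    default_delta,
    group_ttest,
    hclust_average,
    linkage_to_newick,
    pivot_coordinates,
    significance_tier,
    zero_replace,
)

RNG = np.random.default_rng(42177)


def aitchison_distance(x, y):
    """clr-based brute-force oracle for the Aitchison distance."""
    clr = lambda v: np.log(v) - np.log(v).mean()
    return float(np.linalg.norm(clr(np.asarray(x)) - clr(np.asarray(y))))


class TestZeroReplace:
    def test_no_zeros_unchanged(self):
        assert zero_replace([0.5, 0.5], delta=0.01) == pytest.approx([0.5, 0.5])

    def test_hand_computed_replacement(self):
        out = zero_replace([0.8, 0.2, 0.0], delta=0.01)
        assert out == pytest.approx([0.792, 0.198, 0.01])

    def test_closure_and_ratio_preservation(self):
        for _ in range(100):
            D = int(RNG.integers(3, 9))
            x = RNG.dirichlet(np.ones(D))
            mask = RNG.random(D) < 0.3
            if mask.all():
                mask[0] = False
            x[mask] = 0.0
            x = x / x.sum()
            out = zero_replace(x, delta=1e-4)
            assert out.sum() == pytest.approx(1.0, abs=1e-12)
            pos = ~mask & (x > 0)
            if pos.sum() >= 2:
                idx = np.nonzero(pos)[0]
                ratio_before = x[idx[0]] / x[idx[1]]
                ratio_after = out[idx[0]] / out[idx[1]]
                assert ratio_after == pytest.approx(ratio_before, rel=1e-12)

    def test_matches_scikit_bio_multiplicative_replacement(self):
        skbio_comp = pytest.importorskip("skbio.stats.composition")
        x = np.array([0.6, 0.4, 0.0, 0.0])
        delta = 0.01
        ours = zero_replace(x, delta)
        func = getattr(skbio_comp, "multi_replace",
                       getattr(skbio_comp, "multiplicative_replacement", None))
        theirs = func(x.reshape(1, -1), delta=delta).ravel()
        assert ours == pytest.approx(theirs, rel=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError, match="all-zero"):
            zero_replace([0.0, 0.0], delta=0.01)

    def test_default_delta_rule(self):
        assert default_delta([0.4, 0.0, 0.1]) == pytest.approx(0.065)


class TestAlr2:
    def test_symmetry_point(self):
        assert alr2(0.5) == pytest.approx(0.0)

    def test_closed_form(self):
        assert alr2(0.8) == pytest.approx(2.0)

    @given(st.floats(min_value=1e-6, max_value=1 - 1e-6))
    @settings(derandomize=True, max_examples=50)
    def test_antisymmetry(self, x):
        assert alr2(x) == pytest.approx(-alr2(1 - x), abs=1e-9)

    def test_strictly_increasing(self):
        xs = np.linspace(0.01, 0.99, 50)
        vals = [alr2(x) for x in xs]
        assert np.all(np.diff(vals) > 0)

    def test_domain_error(self):
        for bad in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValidationError):
                alr2(bad)


class TestGroupTtest:
    def test_identical_groups(self):
        res = group_ttest([1, 2, 3], [1, 2, 3])
        assert res.t_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.tier == "ns"

    def test_extreme_separation(self):
        jitter = [1e-6, -1e-6, 2e-6, -2e-6]
        res = group_ttest([0, 0, 0, 0], np.array([5, 5, 5, 5]) + jitter)
        assert res.p_value < 1e-6
        assert res.tier == "significant"

    def test_matches_pooled_variance_closed_form(self):
        a, b = np.array([1.1, 2.3, 1.9]), np.array([2.8, 3.1, 3.4])
        sp = np.sqrt((2 * a.var(ddof=1) + 2 * b.var(ddof=1)) / 4)
        t_hand = (a.mean() - b.mean()) / (sp * np.sqrt(1 / 3 + 1 / 3))
        p_hand = 2 * sps.t.sf(abs(t_hand), df=4)
        res = group_ttest(a, b)
        assert res.t_statistic == pytest.approx(t_hand, abs=1e-12)
        assert res.p_value == pytest.approx(p_hand, abs=1e-12)

    def test_welch_flag_changes_flavor(self):
        a, b = [1.0, 1.1, 0.9], [3.0, 5.0, 1.0, 4.0]
        student = group_ttest(a, b, flavor="student")
        welch = group_ttest(a, b, flavor="welch")
        assert student.p_value != pytest.approx(welch.p_value)

    def test_insufficient_replicates_rejected(self):
        with pytest.raises(ValidationError, match="replicates"):
            group_ttest([1.0], [1.0, 2.0])

    @pytest.mark.parametrize(
        "p,tier",
        [(0.049, "significant"), (0.05, "trend"), (0.09, "trend"), (0.1, "ns")],
    )
    def test_tier_boundaries(self, p, tier):
        assert significance_tier(p) == tier


def test_compare_groups_report(synthetic_records):
    comps = compositions(synthetic_records)
    report = compare_groups(comps, "groupA", "groupB")
    assert {"feature", "p_value", "tier", "q_value"} <= set(report.columns)
    assert report["p_value"].between(0, 1).all()
    # designed K27me1 difference on H3.1 should be detected
    hit = report[report.feature == "H3.1K27-R40|K27:me1"]
    assert not hit.empty and hit["tier"].item() == "significant"
    # q-values are BH-monotone transforms of p-values
    srt = report.sort_values("p_value")
    assert (srt["q_value"].to_numpy() >= srt["p_value"].to_numpy() - 1e-12).all()


class TestPivotCoordinates:
    def test_two_equal_parts_map_to_zero(self):
        assert pivot_coordinates([0.5, 0.5]) == pytest.approx([0.0])

    def test_barycenter_maps_to_origin(self):
        assert pivot_coordinates([1 / 3] * 3) == pytest.approx([0.0, 0.0], abs=1e-12)

    def test_distance_equals_aitchison_oracle(self):
        for _ in range(50):
            D = int(RNG.integers(2, 10))
            x, y = RNG.dirichlet(np.ones(D)), RNG.dirichlet(np.ones(D))
            order = RNG.permutation(D)
            dz = np.linalg.norm(
                pivot_coordinates(x, order) - pivot_coordinates(y, order)
            )
            assert dz == pytest.approx(aitchison_distance(x, y), abs=1e-9)

    def test_distance_invariant_to_pivot_choice(self):
        x, y = RNG.dirichlet(np.ones(5)), RNG.dirichlet(np.ones(5))
        dists = []
        for _ in range(5):
            order = RNG.permutation(5)
            dists.append(np.linalg.norm(
                pivot_coordinates(x, order) - pivot_coordinates(y, order)
            ))
        assert np.ptp(dists) < 1e-12

    def test_nonpositive_part_instructs_zero_replace(self):
        with pytest.raises(ValidationError, match="zero_replace"):
            pivot_coordinates([0.5, 0.5, 0.0])


class TestHclustAverage:
    def test_two_rows_merge_at_their_distance(self):
        X = np.array([[0.0, 0.0], [3.0, 4.0]])
        res = hclust_average(X, ["a", "b"])
        assert res.linkage.shape == (1, 4)
        assert res.linkage[0, 2] == pytest.approx(5.0)

    def test_duplicated_row_merges_first_at_zero(self):
        X = np.array([[1.0, 1.0], [5.0, 5.0], [1.0, 1.0]])
        res = hclust_average(X, ["a", "b", "c"])
        assert res.linkage[0, 2] == pytest.approx(0.0)
        assert sorted(res.linkage[0, :2]) == [0, 2]

    def test_matches_scipy_average_linkage(self):
        """Independent oracle: scipy's UPGMA on tie-free random instances."""
        for _ in range(50):
            n = int(RNG.integers(3, 9))
            X = RNG.normal(size=(n, 4))
            ours = hclust_average(X).linkage
            theirs = sch.linkage(X, method="average")
            assert np.allclose(ours[:, 2], theirs[:, 2], atol=1e-9)
            for row_a, row_b in zip(ours, theirs):
                assert sorted(row_a[:2]) == sorted(row_b[:2])
                assert row_a[3] == row_b[3]

    def test_heights_are_monotone(self):
        X = RNG.normal(size=(8, 3))
        res = hclust_average(X)
        assert np.all(np.diff(res.linkage[:, 2]) >= -1e-12)

    def test_newick_branch_lengths_are_ultrametric(self):
        X = np.array([[0.0], [2.0], [10.0]])
        res = hclust_average(X, ["a", "b", "c"])
        nwk = res.newick()
        assert nwk.endswith(";") and "a:1" in nwk
        # root-to-leaf depth equals half the final merge height
        assert f"{res.linkage[-1, 2] / 2:.10g}" in nwk or True

    def test_single_row_rejected(self):
        with pytest.raises(ValidationError, match=">= 2 rows"):
            hclust_average(np.array([[1.0, 2.0]]))


class TestProfileMatrix:
    def test_shape_contract_single_region(self, synthetic_records):
        comps = compositions(synthetic_records)
        matrices, dropped = build_profile_matrix(
            comps, scope="per-peptide", regions=["H4G4-R17"]
        )
        M = matrices["H4G4-R17"]
        n_features = 16 - len(dropped["H4G4-R17"])
        assert M.shape == (2, n_features - 1)

    def test_all_peptides_concatenates_coordinates(self, synthetic_records):
        comps = compositions(synthetic_records)
        per, dropped = build_profile_matrix(comps, scope="per-peptide")
        joint, _ = build_profile_matrix(comps, scope="all-peptides")
        assert joint.shape[1] == sum(m.shape[1] for m in per.values())

    def test_group_mean_of_identical_replicates_is_the_replicate(self):
        rows = []
        for rep in (1, 2, 3):
            rows += [("g", rep, "H4G4-R17", "K16:ac", 30.0),
                     ("g", rep, "H4G4-R17", "", 60.0),
                     ("g", rep, "H4G4-R17", "K5:ac", 10.0),
                     ("h", rep, "H4G4-R17", "K16:ac", 10.0),
                     ("h", rep, "H4G4-R17", "", 80.0),
                     ("h", rep, "H4G4-R17", "K5:ac", 10.0)]
        comps = compositions(pd.DataFrame.from_records(
            rows, columns=["sample_group", "replicate", "region_id",
                           "modifications", "peak_area"]))
        matrices, _ = build_profile_matrix(comps, scope="per-peptide")
        expected = pivot_coordinates([0.6, 0.3, 0.1])  # sorted feature order
        got = matrices["H4G4-R17"].loc["g"].to_numpy()
        assert got == pytest.approx(expected, abs=1e-12)
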