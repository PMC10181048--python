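import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import spearmanr

from siig import (
    WARM_BARLEY,
    DirectionSpec,
    DistanceResult,
    TraitMatrix,
    compute_siig,
    derive_gfp,
    distances,
    ideal_profiles,
    load_fixture,
    normalize,
    siig_scores,
    table4_trait_matrix,
)
from conftest import naive_siig, random_positive_matrix


# ---------------------------------------------------------------- normalize
class TestNormalize:
    def test_three_four_five_triangle(self):
        tm = TraitMatrix.from_arrays(["a", "b"], ["t"], [[3.0], [4.0]])
        r = normalize(tm)
        assert np.allclose(r.values.ravel(), [0.6, 0.8])

    @pytest.mark.parametrize("n", [2, 5, 17])
    def test_constant_column_gives_uniform(self, n):
        tm = TraitMatrix.from_arrays(
            [f"g{i}" for i in range(n)], ["t"], [[7.5]] * n
        )
        r = normalize(tm)
        assert np.allclose(r.values, 1.0 / np.sqrt(n))

    def test_unit_column_norms(self, two_trait_matrix):
        r = normalize(two_trait_matrix)
        sq = (r.values**2).sum(axis=0)
        assert np.allclose(sq, 1.0, atol=1e-9)

    def test_fixture_yld_column_against_direct_summation(self):
        tm = table4_trait_matrix()
        raw = tm.data["YLD"]
        # independent oracle: plain sum over the printed column
        norm = sum(v * v for v in raw.tolist()) ** 0.5
        r = normalize(tm)
        assert r.data.loc["86", "YLD"] == pytest.approx(4466.0 / norm, abs=1e-12)

    def test_zero_column_error_names_trait(self):
        tm = TraitMatrix.from_arrays(["a", "b"], ["ok", "zero"], [[1, 0], [2, 0]])
        with pytest.raises(ValueError, match="zero"):
            normalize(tm)

    def test_nonfinite_cell_error_names_coordinates(self):
        with pytest.raises(ValueError, match="g2.*t1|t1.*g2"):
            TraitMatrix.from_arrays(["g1", "g2"], ["t1"], [[1.0], [np.nan]])

    def test_negative_values_warn_not_error(self):
        with pytest.warns(UserWarning, match="negative"):
            TraitMatrix.from_arrays(["a", "b"], ["t"], [[-1.0], [2.0]])


# ----------------------------------------------------------- ideal_profiles
class TestIdealProfiles:
    def test_benefit_and_cost_orientation(self):
        tm = TraitMatrix.from_arrays(["a", "b"], ["t"], [[3.0], [4.0]])
        r = normalize(tm)
        up = ideal_profiles(r, DirectionSpec({"t": "benefit"}))
        assert up.r_plus["t"] == pytest.approx(0.8)
        assert up.r_minus["t"] == pytest.approx(0.6)
        down = ideal_profiles(r, DirectionSpec({"t": "cost"}))
        assert down.r_plus["t"] == pytest.approx(0.6)
        assert down.r_minus["t"] == pytest.approx(0.8)

    def test_fixture_extrema_by_exhaustive_scan(self):
        tm = table4_trait_matrix()
        r = normalize(tm)
        prof = ideal_profiles(r, WARM_BARLEY)
        benefit = {"GFP", "TKW", "YLD"}
        for trait in tm.trait_names:
            col = sorted(r.data[trait].tolist())  # brute-force extrema
            lo, hi = col[0], col[-1]
            if trait in benefit:
                assert prof.r_plus[trait] == hi and prof.r_minus[trait] == lo
            else:
                assert prof.r_plus[trait] == lo and prof.r_minus[trait] == hi

    def test_profiles_are_attained_values(self, two_trait_matrix, mixed_directions):
        r = normalize(two_trait_matrix)
        prof = ideal_profiles(r, mixed_directions)
        for trait in two_trait_matrix.trait_names:
            col = r.data[trait].tolist()
            assert prof.r_plus[trait] in col
            assert prof.r_minus[trait] in col

    def test_missing_direction_is_an_error(self, two_trait_matrix):
        r = normalize(two_trait_matrix)
        with pytest.raises(KeyError, match="t2"):
            ideal_profiles(r, DirectionSpec({"t1": "benefit"}))

    def test_extra_direction_warns(self, two_trait_matrix, mixed_directions):
        r = normalize(two_trait_matrix)
        spec = DirectionSpec({"t1": "max", "t2": "min", "ghost": "max"})
        with pytest.warns(UserWarning, match="ghost"):
            ideal_profiles(r, spec)


# ---------------------------------------------------------------- distances
class TestDistances:
    def test_ideal_row_has_zero_dplus(self):
        tm = TraitMatrix.from_arrays(
            ["best", "worst"], ["t1", "t2"], [[4.0, 9.0], [3.0, 1.0]]
        )
        spec = DirectionSpec({"t1": "benefit", "t2": "benefit"})
        r = normalize(tm)
        d = distances(r, ideal_profiles(r, spec))
        assert d.d_plus["best"] == 0.0
        assert d.d_minus["worst"] == 0.0

    def test_single_benefit_trait_two_points(self):
        tm = TraitMatrix.from_arrays(["g1", "g2"], ["t"], [[3.0], [4.0]])
        r = normalize(tm)
        d = distances(r, ideal_profiles(r, DirectionSpec({"t": "max"})))
        assert d.d_plus["g1"] == pytest.approx(0.2)
        assert d.d_minus["g1"] == pytest.approx(0.0)

    def test_random_matrix_matches_elementwise_loop(self):
        rng = np.random.default_rng(7)
        tm = random_positive_matrix(rng, 3, 2)
        spec = DirectionSpec({"t0": "benefit", "t1": "cost"})
        r = normalize(tm)
        prof = ideal_profiles(r, spec)
        d = distances(r, prof)
        for i, g in enumerate(tm.genotype_ids):
            dp = sum(
                (r.values[i, j] - prof.r_plus.iloc[j]) ** 2 for j in range(2)
            ) ** 0.5
            dm = sum(
                (r.values[i, j] - prof.r_minus.iloc[j]) ** 2 for j in range(2)
            ) ** 0.5
            assert d.d_plus[g] == pytest.approx(dp, abs=1e-12)
            assert d.d_minus[g] == pytest.approx(dm, abs=1e-12)

    def test_axis_mismatch_is_an_error(self, two_trait_matrix, mixed_directions):
        r = normalize(two_trait_matrix)
        prof = ideal_profiles(r, mixed_directions)
        shuffled = type(prof)(
            r_plus=prof.r_plus.iloc[::-1], r_minus=prof.r_minus.iloc[::-1]
        )
        with pytest.raises(ValueError, match="disagree"):
            distances(r, shuffled)


# -------------------------------------------------------------- siig_scores
class TestSiigScores:
    def _dist(self, d_plus, d_minus):
        idx = pd.Index([f"g{i}" for i in range(len(d_plus))], name="genotype")
        return DistanceResult(
            d_plus=pd.Series(d_plus, index=idx), d_minus=pd.Series(d_minus, index=idx)
        )

    def test_ideal_midpoint_antiideal(self):
        res = siig_scores(self._dist([0.0, 0.3, 0.5], [0.5, 0.3, 0.0]))
        assert res.siig.tolist() == pytest.approx([1.0, 0.5, 0.0])
        assert res.rank.tolist() == [1, 2, 3]

    def test_degenerate_all_identical_scores_half_with_warning(self):
        with pytest.warns(UserWarning, match="0.5"):
            res = siig_scores(self._dist([0.0, 0.0], [0.0, 0.0]))
        assert res.siig.tolist() == [0.5, 0.5]

    def test_ordinal_ties_keep_input_order(self):
        res = siig_scores(self._dist([0.2, 0.2, 0.1], [0.2, 0.2, 0.3]))
        assert res.rank.tolist() == [2, 3, 1]

    def test_average_ranks_for_ties(self):
        res = siig_scores(
            self._dist([0.2, 0.2, 0.1], [0.2, 0.2, 0.3]), rank_method="average"
        )
        assert res.rank.tolist() == pytest.approx([2.5, 2.5, 1.0])


# ------------------------------------------------------------- compute_siig
class TestComputeSiig:
    def test_two_point_single_trait(self):
        tm = TraitMatrix.from_arrays(["lo", "hi"], ["t"], [[3.0], [4.0]])
        res = compute_siig(tm, DirectionSpec({"t": "benefit"}))
        assert res.siig["lo"] == pytest.approx(0.0)
        assert res.siig["hi"] == pytest.approx(1.0)

    def test_dominant_genotype_scores_one(self):
        rng = np.random.default_rng(11)
        tm = random_positive_matrix(rng, 8, 3)
        data = tm.data.copy()
        data.loc["g0", ["t0", "t1"]] = data[["t0", "t1"]].max() + 1
        data.loc["g0", "t2"] = data["t2"].min() / 2
        spec = DirectionSpec({"t0": "max", "t1": "max", "t2": "min"})
        res = compute_siig(TraitMatrix(data), spec)
        assert res.siig["g0"] == pytest.approx(1.0)
        assert res.rank["g0"] == 1

    def test_matches_chained_stages(self, two_trait_matrix, mixed_directions):
        direct = compute_siig(two_trait_matrix, mixed_directions)
        r = normalize(two_trait_matrix)
        chained = siig_scores(distances(r, ideal_profiles(r, mixed_directions)))
        pd.testing.assert_frame_equal(direct.table, chained.table)

    def test_fixture_recomputation_tracks_printed_index(self):
        """Recomputing from the printed trait means must reproduce the
        published ranking: genotype 86 first with SIIG near 0.726, and
        near-perfect rank agreement overall (the printed inputs are
        rounded, so exact equality is not expected)."""
        res = compute_siig(table4_trait_matrix(), WARM_BARLEY)
        assert res.siig["86"] == pytest.approx(0.726, abs=0.05)
        assert res.rank["86"] == 1
        printed = load_fixture("table4")["SIIG"]
        rho = spearmanr(res.siig.to_numpy(), printed.to_numpy()).statistic
        assert rho >= 0.95


# --------------------------------------------------------------- derive_gfp
class TestDeriveGfp:
    def test_fixture_rows(self):
        gfp = derive_gfp([101.0, 99.0], [134.0, 138.0], ["86", "56"])
        assert gfp["86"] == 33.0
        assert gfp["56"] == 39.0

    def test_zero_filling_period_allowed(self):
        assert derive_gfp([100.0], [100.0]).iloc[0] == 0.0

    def test_negative_result_names_genotype(self):
        with pytest.raises(ValueError, match="g2"):
            derive_gfp([100.0, 120.0], [130.0, 110.0], ["g1", "g2"])

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            derive_gfp([1.0], [1.0, 2.0])


# --------------------------------------------------------------- properties
positive_matrices = st.integers(2, 6).flatmap(
    lambda n: st.integers(1, 4).flatmap(
        lambda m: st.lists(
            st.lists(
                st.floats(0.1, 100.0, allow_nan=False, allow_infinity=False),
                min_size=m,
                max_size=m,
            ),
            min_size=n,
            max_size=n,
        )
    )
)


def _spec_for(m, benefit_flags):
    return DirectionSpec(
        {f"t{j}": ("benefit" if b else "cost") for j, b in zip(range(m), benefit_flags)}
    )


@given(values=positive_matrices, seed=st.integers(0, 2**16))
def test_siig_bounded_in_unit_interval(values, seed):
    m = len(values[0])
    flags = np.random.default_rng(seed).integers(0, 2, m).astype(bool)
    tm = TraitMatrix.from_arrays(
        [f"g{i}" for i in range(len(values))], [f"t{j}" for j in range(m)], values
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = compute_siig(tm, _spec_for(m, flags))
    assert ((res.siig >= 0) & (res.siig <= 1)).all()
    assert sorted(res.rank.tolist()) == list(range(1, len(values) + 1))


@given(values=positive_matrices, scale=st.floats(1e-3, 1e3), col=st.integers(0, 3))
def test_per_trait_scale_invariance(values, scale, col):
    m = len(values[0])
    tm = TraitMatrix.from_arrays(
        [f"g{i}" for i in range(len(values))], [f"t{j}" for j in range(m)], values
    )
    scaled = tm.data.copy()
    scaled.iloc[:, col % m] *= scale
    spec = _spec_for(m, [True] * m)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a = compute_siig(tm, spec).siig
        b = compute_siig(TraitMatrix(scaled), spec).siig
    assert np.allclose(a, b, atol=1e-12)


@given(values=positive_matrices, seed=st.integers(0, 2**16))
def test_permutation_equivariance(values, seed):
    n, m = len(values), len(values[0])
    tm = TraitMatrix.from_arrays(
        [f"g{i}" for i in range(n)], [f"t{j}" for j in range(m)], values
    )
    perm = np.random.default_rng(seed).permutation(n)
    permuted = TraitMatrix(tm.data.iloc[perm])
    spec = _spec_for(m, [True] * m)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a = compute_siig(tm, spec).siig
        b = compute_siig(permuted, spec).siig
    assert np.allclose(a.reindex(b.index), b, atol=1e-12)


@given(values=positive_matrices, seed=st.integers(0, 2**16))
def test_direction_flip_maps_score_to_complement(values, seed):
    m = len(values[0])
    flags = np.random.default_rng(seed).integers(0, 2, m).astype(bool)
    tm = TraitMatrix.from_arrays(
        [f"g{i}" for i in range(len(values))], [f"t{j}" for j in range(m)], values
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a = compute_siig(tm, _spec_for(m, flags)).siig
        b = compute_siig(tm, _spec_for(m, ~flags)).siig
    assert np.allclose(a, 1.0 - b, atol=1e-12)


def test_directed_extremes_score_zero_and_one():
    rng = np.random.default_rng(3)
    tm = random_positive_matrix(rng, 6, 4)
    data = tm.data.copy()
    data.loc["g0"] = data.max() + 1.0  # dominant under all-benefit
    data.loc["g1"] = data.min().where(data.min() / 2 > 0, 0.01) / 2
    spec = _spec_for(4, [True] * 4)
    res = compute_siig(TraitMatrix(data), spec)
    assert res.siig["g0"] == pytest.approx(1.0)
    assert res.siig["g1"] == pytest.approx(0.0)


def test_pipeline_equals_naive_loop_on_exhaustive_small_matrices():
    """Exhaustive grid of small-integer matrices up to 4 x 3 against the
    pure-Python loop reference, all direction patterns."""
    grids = [(2, 1), (3, 2), (4, 3)]
    entries = [1.0, 2.0, 5.0]
    rng = np.random.default_rng(0)
    for n, m in grids:
        for _ in range(40):  # random draws from the small-integer grid
            values = rng.choice(entries, size=(n, m))
            for flags in itertools.product([True, False], repeat=m):
                tm = TraitMatrix.from_arrays(
                    [f"g{i}" for i in range(n)], [f"t{j}" for j in range(m)], values
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    got = compute_siig(tm, _spec_for(m, flags)).siig.tolist()
                want = naive_siig(values.tolist(), list(flags))
                assert got == pytest.approx(want, abs=1e-12)
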