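"""Tolerance-based set algebra: examples, invariants, oracle agreement."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import oracles
from micard import (
    InputError,
    Ion,
    IonMatrix,
    MatchTolerance,
    RtWindow,
    ShortfallWarning,
    common_ions,
    difference_set,
    filter_rt_window,
    ions_match,
    subtract_blank,
    top_n_by_intensity,
)
from micard.ops import has_match, match_report, rank_by_intensity

TOL = MatchTolerance()


def matrix(*triples, **meta):
    return IonMatrix(ions=tuple(Ion(*t) for t in triples), **meta)


class TestIonsMatch:
    def test_marker_coordinates_match(self):
        # the two printed m/z readings of the same PR marker ion differ by 0.01 Da
        assert ions_match(Ion(13.71, 845.50, 1), Ion(13.71, 845.49, 2), TOL)

    def test_reflexive(self):
        ion = Ion(5.0, 400.0, 10)
        assert ions_match(ion, ion, TOL)

    def test_rt_just_outside(self):
        assert not ions_match(Ion(5.00, 400.0, 1), Ion(5.21, 400.0, 1), TOL)

    @given(
        st.floats(0, 30, allow_nan=False),
        st.floats(100, 1000, allow_nan=False),
        st.floats(0, 30, allow_nan=False),
        st.floats(100, 1000, allow_nan=False),
    )
    def test_symmetric_and_intensity_blind(self, t1, m1, t2, m2):
        a, b = Ion(t1, m1, 1.0), Ion(t2, m2, 1e9)
        assert ions_match(a, b, TOL) == ions_match(b, a, TOL)

    def test_not_transitive(self):
        a, b, c = Ion(5.0, 400.000, 1), Ion(5.0, 400.009, 1), Ion(5.0, 400.018, 1)
        assert ions_match(a, b, TOL) and ions_match(b, c, TOL)
        assert not ions_match(a, c, TOL)


class TestFilterRtWindow:
    def test_closed_interval_boundaries(self):
        m = matrix((0.5, 100, 1), (1.0, 100, 1), (33.0, 200, 1), (35.0, 300, 1))
        out = filter_rt_window(m, RtWindow())
        assert [i.t_r for i in out.ions] == [1.0, 33.0]

    def test_empty_and_identity(self):
        empty = matrix()
        assert len(filter_rt_window(empty)) == 0
        inside = matrix((5, 100, 1), (10, 200, 1))
        assert filter_rt_window(inside).ions == inside.ions

    def test_idempotent(self):
        m = matrix((0.5, 100, 1), (5, 200, 1), (34, 300, 1))
        once = filter_rt_window(m)
        assert filter_rt_window(once).ions == once.ions


class TestSubtractBlank:
    def test_within_tolerance_removed(self):
        sample = matrix((5.00, 400.00, 10))
        blank = matrix((5.10, 400.005, 3))
        assert len(subtract_blank(sample, blank, TOL)) == 0

    def test_empty_blank_is_noop(self):
        sample = matrix((5, 400, 10), (6, 500, 20))
        assert subtract_blank(sample, matrix(), TOL).ions == sample.ions

    def test_partial_subtraction_matches_bruteforce(self):
        sample = matrix((5, 400, 10), (6, 500, 20), (7, 600, 30))
        blank = matrix((6.05, 500.004, 1))
        out = subtract_blank(sample, blank, TOL)
        assert out.ions == oracles.subtract_bf(sample, blank, TOL).ions
        assert len(out) == 2

    def test_idempotent_and_blank_unchanged(self):
        sample = matrix((5, 400, 10), (6, 500, 20))
        blank = matrix((5.01, 400.001, 1))
        once = subtract_blank(sample, blank, TOL)
        assert subtract_blank(once, blank, TOL).ions == once.ions
        assert len(blank) == 1


class TestDifferenceSet:
    def test_self_difference_empty(self):
        m = matrix((5, 400, 10), (6, 500, 20))
        assert len(difference_set(m, m, TOL)) == 0

    def test_difference_with_empty_is_identity(self):
        m = matrix((5, 400, 10))
        assert difference_set(m, matrix(), TOL).ions == m.ions

    def test_recovers_planted_specific_ions(self):
        shared = [(5, 400, 10), (10, 600, 20)]
        own_specific = [(7, 700, 5), (12, 800, 9)]
        other_specific = [(3, 300, 4)]
        own = matrix(*(shared + own_specific))
        other = matrix(*(shared + other_specific))
        out = difference_set(own, other, TOL)
        assert {(i.t_r, i.mz) for i in out.ions} == {(7, 700), (12, 800)}
        assert out.ions == oracles.subtract_bf(own, other, TOL).ions


class TestCommonIons:
    def test_requires_batches(self):
        with pytest.raises(InputError):
            common_ions([], TOL)

    def test_single_batch_is_itself(self):
        m = matrix((5, 400, 10), (6, 500, 20), material="GR")
        assert common_ions([m], TOL).ions == m.ions

    def test_disjoint_batches_empty(self):
        a = matrix((5, 400, 10))
        b = matrix((5, 400.02, 10))
        assert len(common_ions([a, b], TOL)) == 0

    def test_jittered_copies_recover_template(self):
        rng = np.random.default_rng(42)
        template = matrix(
            *[
                (float(t), float(m), float(i))
                for t, m, i in zip(
                    rng.uniform(1, 33, 50),
                    np.sort(rng.uniform(100, 1200, 50)),
                    rng.uniform(10, 1e5, 50),
                )
            ]
        )
        batches = []
        for _ in range(10):
            jit = [
                Ion(
                    i.t_r + rng.uniform(-0.05, 0.05),
                    i.mz + rng.uniform(-0.003, 0.003),
                    i.intensity,
                )
                for i in template.ions
            ]
            batches.append(IonMatrix(ions=tuple(jit)))
        out = common_ions(batches, TOL)
        assert len(out) == 50
        # each consensus ion sits within the jitter radius of one template ion
        for c in out.ions:
            assert any(
                abs(c.t_r - t.t_r) <= 0.05 and abs(c.mz - t.mz) <= 0.003
                for t in template.ions
            )
        assert out.ions == oracles.common_ions_bf(batches, TOL).ions

    def test_output_not_larger_than_reference(self):
        a = matrix((5, 400, 1), (6, 500, 1))
        b = matrix((5.0, 400.001, 1), (6.0, 500.001, 1), (7, 600, 1))
        assert len(common_ions([a, b], TOL)) <= len(a)

    def test_reference_by_batch_id(self):
        a = matrix((5, 400, 2), batch_id="x")
        b = matrix((5.01, 400.001, 4), batch_id="y")
        out_x = common_ions([a, b], TOL, reference="x")
        out_y = common_ions([a, b], TOL, reference="y")
        assert out_x.ions == out_y.ions  # means over the same pair
        with pytest.raises(InputError):
            common_ions([a, b], TOL, reference="z")


class TestTopN:
    def test_selection_property(self):
        rng = np.random.default_rng(3)
        m = IonMatrix.from_arrays(
            rng.uniform(1, 33, 150), rng.uniform(100, 1200, 150), rng.uniform(1, 1e6, 150)
        )
        out = top_n_by_intensity(m, 100)
        kept = sorted(i.intensity for i in out.ions)
        excluded = sorted(
            i.intensity for i in m.ions if i not in set(out.ions)
        )
        assert len(out) == 100
        assert kept[0] >= excluded[-1]

    def test_shortfall_warns(self):
        m = matrix(*[(float(k), 100.0 + k, float(k)) for k in range(1, 81)])
        with pytest.warns(ShortfallWarning):
            out = top_n_by_intensity(m, 100)
        assert len(out) == 80

    def test_tie_broken_by_lower_mz(self):
        m = matrix((5, 500, 10), (5, 400, 10))
        assert rank_by_intensity(top_n_by_intensity(m, 1))[0].mz == 400


class TestWindowedSearchAgainstBruteForce:
    """The accelerated matcher must agree exactly with the quadratic scan."""

    @given(st.integers(0, 2**32 - 1))
    def test_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n_a, n_b = rng.integers(0, 120, 2)
        base_tr = rng.uniform(0, 35, max(n_a, n_b, 1))
        base_mz = rng.uniform(100, 300, max(n_a, n_b, 1))  # dense mz → many matches

        def make(n):
            idx = rng.integers(0, len(base_tr), n)
            return IonMatrix.from_arrays(
                np.abs(base_tr[idx] + rng.normal(0, 0.1, n)),
                np.abs(base_mz[idx] + rng.normal(0, 0.005, n)) + 1e-6,
                rng.uniform(1, 100, n),
            )

        a, b = make(n_a), make(n_b)
        np.testing.assert_array_equal(
            has_match(a, b, TOL), oracles.has_match_bf(a, b, TOL)
        )
        assert match_report(a, b, TOL).pairs == oracles.pairs_bf(a, b, TOL)
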