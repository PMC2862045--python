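import numpy as np
import pytest

from tdaracne.fixtures import make_gaussian_pair
from tdaracne.mi import (
    DegenerateProfileError,
    DelayedMIEngine,
    MIParams,
    delayed_mi,
    influence,
    kde2d,
    mutual_information,
)
from tdaracne.preprocess import copula_transform, copula_transform_matrix


def ranks_of(x):
    return copula_transform(np.asarray(x))


class TestKde2d:
    def test_masses_sum_to_one(self, rng):
        x = ranks_of(rng.random(50))
        y = ranks_of(rng.random(50))
        joint, meta = kde2d(x, y)
        assert joint.shape == (100, 100)
        assert (joint >= 0).all()
        assert abs(joint.sum() - 1.0) < 1e-6
        assert meta["hx"] > 0 and meta["hy"] > 0

    def test_perfect_dependence_concentrates_on_diagonal(self, rng):
        x = ranks_of(rng.random(200))
        joint, _ = kde2d(x, x)
        g = joint.shape[0]
        band = np.abs(np.subtract.outer(np.arange(g), np.arange(g))) <= 10
        # the +-10-cell band holds ~20% of the area; perfect dependence
        # must concentrate far more mass there than an independent pair
        assert joint[band].sum() > 0.5
        indep, _ = kde2d(ranks_of(rng.random(200)), ranks_of(rng.random(200)))
        assert joint[band].sum() > 2 * indep[band].sum()

    def test_independent_uniforms_approximate_flat_density(self):
        r = np.random.default_rng(0)
        joint, _ = kde2d(ranks_of(r.random(2000)), ranks_of(r.random(2000)))
        flat = 1.0 / joint.size
        assert np.abs(joint - flat).max() < 5 * flat

    def test_constant_input_raises_degenerate_error(self):
        with pytest.raises(DegenerateProfileError):
            kde2d(np.full(10, 0.5), ranks_of(np.arange(10.0)))

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            kde2d([0.1, 0.2, 0.3], [0.3, 0.2, 0.1])


class TestMutualInformation:
    def test_symmetric_at_zero_delay(self, rng):
        # symmetric up to summation order of the transposed grid
        x = ranks_of(rng.random(40))
        y = ranks_of(rng.random(40))
        assert mutual_information(x, y) == pytest.approx(mutual_information(y, x), abs=1e-12)

    def test_independent_uniforms_near_zero(self):
        r = np.random.default_rng(3)
        mi = mutual_information(ranks_of(r.random(2000)), ranks_of(r.random(2000)))
        assert 0.0 <= mi < 0.05

    @pytest.mark.parametrize("rho", [0.0, 0.3, 0.6, 0.9])
    def test_gaussian_closed_form_oracle(self, rho):
        x, y, expected = make_gaussian_pair(rho, 2000, seed=1)
        mi = mutual_information(ranks_of(x), ranks_of(y))
        assert abs(mi - expected) <= 0.1

    def test_self_information_dominates(self, rng):
        x = ranks_of(rng.random(60))
        y = ranks_of(rng.random(60))
        assert mutual_information(x, x) >= mutual_information(x, y)

    def test_nonnegative_on_random_pairs(self, rng):
        for _ in range(10):
            mi = mutual_information(ranks_of(rng.random(30)), ranks_of(rng.random(30)))
            assert mi >= 0.0


class TestDelayedMI:
    def test_zero_delay_reduces_to_symmetric_mi(self, rng):
        a = ranks_of(rng.random(30))
        b = ranks_of(rng.random(30))
        assert delayed_mi(a, b, 0) == pytest.approx(delayed_mi(b, a, 0), abs=1e-12)
        assert delayed_mi(a, b, 0) == mutual_information(a, b)

    def test_shifted_copy_attains_self_mi_at_its_lag(self, rng):
        a = rng.random(50)
        b = np.roll(a, 1)  # b(t) = a(t-1)
        ra, rb = ranks_of(a), ranks_of(b)
        per = [delayed_mi(ra, rb, k) for k in range(1, 4)]
        assert np.argmax(per) == 0
        # at kappa=1 the truncated pair is rank-identical: MI equals the
        # self-MI of the truncated source ranks
        self_mi = mutual_information(ra[:-1], ra[:-1])
        assert per[0] > 3 * max(per[1], per[2]) or per[0] == pytest.approx(self_mi, rel=0.2)

    def test_white_noise_pair_near_zero_at_any_delay(self):
        r = np.random.default_rng(11)
        a, b = ranks_of(r.random(500)), ranks_of(r.random(500))
        for k in range(4):
            assert delayed_mi(a, b, k) < 0.25  # independence level at n=500

    def test_too_short_overlap_rejected(self):
        a = ranks_of(np.arange(6.0))
        with pytest.raises(ValueError):
            delayed_mi(a, a, 3)


class TestInfluence:
    def test_shifted_copy_best_delay_is_one(self, rng):
        a = rng.random(50)
        b = np.roll(a, 1)
        _, best, _ = influence(ranks_of(a), ranks_of(b))
        assert best == 1

    def test_monotone_in_max_delay(self, rng):
        a, b = ranks_of(rng.random(40)), ranks_of(rng.random(40))
        v1, _, _ = influence(a, b, MIParams(max_delay=1))
        v3, _, _ = influence(a, b, MIParams(max_delay=3))
        assert v3 >= v1

    def test_asymmetric_in_general(self, rng):
        a = rng.random(50)
        b = np.roll(a, 1)
        fwd, _, _ = influence(ranks_of(a), ranks_of(b))
        rev, _, _ = influence(ranks_of(b), ranks_of(a))
        assert fwd > rev


class TestDelayedMIEngine:
    def test_matches_functional_api(self, rng):
        vals = rng.random((4, 30))
        ranks = copula_transform_matrix(vals)
        engine = DelayedMIEngine(ranks)
        for (i, j) in [(0, 1), (2, 3), (1, 2)]:
            for k in (1, 2, 3):
                direct = delayed_mi(ranks[i], ranks[j], k)
                assert engine.delayed_mi(i, j, k) == pytest.approx(direct, abs=1e-10)

    def test_series_too_short_for_max_delay_rejected(self, rng):
        with pytest.raises(ValueError):
            DelayedMIEngine(copula_transform_matrix(rng.random((2, 6))), MIParams(max_delay=3))


class TestMIParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            MIParams(grid_size=8)
        with pytest.raises(ValueError):
            MIParams(max_delay=0)
        with pytest.raises(ValueError):
            MIParams(bandwidth_method="nope")
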