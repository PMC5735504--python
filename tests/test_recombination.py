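import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from tsplink.errors import FormatError, ParameterError, ValidationError
from tsplink.genotypes import CALL_A, CALL_B, CALL_H, MISSING
from tsplink.recombination import (
    apply_cutoff,
    f2_pair_loglik,
    read_rf_matrix,
    rf_backcross,
    rf_f2_em,
    rf_homozygous,
    write_rf_matrix,
)
from tsplink.simulate import SimParams, make_true_map, simulate_population

from conftest import geno, rf_from_matrix

A, B, H, M = CALL_A, CALL_B, CALL_H, MISSING


def midpoint_oracle(x, y):
    """Midpoint of the attainable rf range, by enumerating every resolution
    of the missing calls as match or mismatch."""
    pairs = list(zip(x, y))
    fractions = []
    n_missing = sum(1 for a, b in pairs if a == M or b == M)
    for combo in itertools.product([0, 1], repeat=n_missing):
        it = iter(combo)
        d = 0
        for a, b in pairs:
            if a == M or b == M:
                d += next(it)
            elif a != b:
                d += 1
        fractions.append(d / len(pairs))
    return (min(fractions) + max(fractions)) / 2


class TestHomozygousRf:
    def test_direct_mismatch_count(self):
        r = rf_homozygous(geno([[A, A, B, B], [A, B, B, B]]))
        assert r.rf[0, 1] == pytest.approx(0.25)
        assert r.support[0, 1] == 4

    def test_missing_midpoint(self):
        r = rf_homozygous(geno([[A, A, B, B], [A, M, B, B]]))
        # attainable range [0, 0.25] -> midpoint 0.125
        assert r.rf[0, 1] == pytest.approx(0.125)
        assert r.support[0, 1] == 3

    def test_identical_markers(self):
        r = rf_homozygous(geno([[A, B, B, A], [A, B, B, A]]))
        assert r.rf[0, 1] == 0.0

    def test_rejects_het_calls(self):
        with pytest.raises(ValidationError):
            rf_homozygous(geno([[A, H], [A, B]]))

    @pytest.mark.parametrize("seed", range(8))
    def test_midpoint_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.choice([A, B, M], size=8, p=[0.4, 0.4, 0.2])
        y = rng.choice([A, B, M], size=8, p=[0.4, 0.4, 0.2])
        r = rf_homozygous(geno([x, y]))
        expected = min(midpoint_oracle(x, y), 0.5)
        assert r.rf[0, 1] == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(5))
    def test_no_missing_equals_recount(self, seed):
        rng = np.random.default_rng(100 + seed)
        calls = rng.choice([A, B], size=(6, 20))
        r = rf_homozygous(geno(calls))
        for i in range(6):
            for j in range(i + 1, 6):
                direct = min(np.mean(calls[i] != calls[j]), 0.5)
                assert r.rf[i, j] == pytest.approx(direct)

    def test_midpoint_strictly_between_extremes(self):
        # d and u both nonzero: rf strictly between the all-same and
        # all-different resolutions
        x = [A, A, B, B, A, M]
        y = [A, B, B, B, M, A]
        r = rf_homozygous(geno([x, y]))
        lo = 1 / 6  # both missings resolve as matches
        hi = 3 / 6  # both resolve as mismatches
        assert lo < r.rf[0, 1] < hi


class TestBackcrossRf:
    def test_direct_count(self):
        r = rf_backcross(geno([[A, A, H, H], [A, H, H, H]], cross_type="bc"))
        assert r.rf[0, 1] == pytest.approx(0.25)

    def test_identity(self):
        r = rf_backcross(geno([[A, H, A], [A, H, A]], cross_type="bc"))
        assert r.rf[0, 1] == 0.0

    def test_clamped_at_half(self):
        r = rf_backcross(geno([[A, H], [H, A]], cross_type="bc"))
        assert r.rf[0, 1] == 0.5


class TestF2Rf:
    def test_cosegregating_pair_near_zero(self):
        calls = np.array([[A, H, B, H, A, B, H, A], [A, H, B, H, A, B, H, A]])
        r = rf_f2_em(geno(calls, cross_type="f2"))
        assert r.rf[0, 1] < 1e-4

    def test_unlinked_pair_near_half(self):
        sp = SimParams(n=10000, m=2, k=2, lengths=[1.0, 1.0],
                       cross_type="f2", seed=5)
        tm = make_true_map(sp)
        g = simulate_population(tm, sp)
        r = rf_f2_em(g)
        assert r.rf[0, 1] == pytest.approx(0.5, abs=0.02)

    def test_em_matches_grid_search(self):
        # fixed joint table; the EM optimum must agree with brute-force
        # likelihood maximisation over a fine rf grid
        table = np.array([[30, 10, 2], [8, 40, 9], [1, 12, 28]])
        calls_x, calls_y = [], []
        for i in range(3):
            for j in range(3):
                calls_x += [i] * table[i, j]
                calls_y += [j] * table[i, j]
        code = {0: A, 1: H, 2: B}
        g = geno([[code[v] for v in calls_x], [code[v] for v in calls_y]],
                 cross_type="f2")
        r = rf_f2_em(g, tol=1e-9)
        grid = np.arange(0.0, 0.5001, 0.001)
        liks = [f2_pair_loglik(table, v) for v in grid]
        assert abs(r.rf[0, 1] - grid[int(np.argmax(liks))]) <= 0.001

    @pytest.mark.parametrize("d_cm", [5.2, 25.5, 80.0])
    def test_recovers_simulated_rf(self, d_cm):
        # two markers at a spacing whose Haldane rf is r_true; EM at n=1000
        # must land within 3 SE (two informative meioses per individual)
        r_true = 0.5 * (1 - np.exp(-d_cm / 50))
        sp = SimParams(n=1000, m=2, k=1, lengths=[d_cm], cross_type="f2",
                       seed=int(d_cm * 10))
        g = simulate_population(make_true_map(sp), sp)
        r = rf_f2_em(g)
        se = np.sqrt(r_true * (1 - r_true) / (2 * 1000))
        assert abs(r.rf[0, 1] - r_true) < 3 * se


class TestCutoff:
    def test_inflation_boundary(self):
        m = rf_from_matrix([[0, 0.45, 0.40], [0.45, 0, 0.10], [0.40, 0.10, 0]])
        out = apply_cutoff(m, 0.4)
        assert out.rf[0, 1] == 0.5  # strictly above -> inflated
        assert out.rf[0, 2] == 0.40  # at the cutoff -> untouched
        assert out.rf[1, 2] == 0.10

    def test_idempotent_and_monotone(self):
        rng = np.random.default_rng(0)
        raw = rng.uniform(0, 0.5, size=(10, 10))
        raw = np.triu(raw, 1)
        raw = raw + raw.T
        m = rf_from_matrix(raw)
        once = apply_cutoff(m, 0.4)
        twice = apply_cutoff(once, 0.4)
        assert np.array_equal(once.rf, twice.rf)
        assert np.all(once.rf >= m.rf - 1e-15)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        hnp.arrays(np.float64, (6, 6), elements=st.floats(0.0, 0.5)),
        st.floats(0.05, 0.5),
    )
    def test_cutoff_algebra_property(self, raw, cutoff):
        raw = np.triu(raw, 1)
        m = rf_from_matrix(raw + raw.T)
        once = apply_cutoff(m, cutoff)
        assert np.array_equal(once.rf, apply_cutoff(once, cutoff).rf)
        assert np.all(once.rf >= m.rf)
        # inflated entries are exactly 0.5, everything else untouched
        off = ~np.eye(6, dtype=bool)
        changed = once.rf != m.rf
        assert np.all(once.rf[changed & off] == 0.5)
        untouched = m.rf[~changed & off]
        assert np.all((untouched <= cutoff) | (untouched == 0.5))

    @pytest.mark.parametrize("bad", [0.0, -0.1, 0.6])
    def test_bad_cutoff(self, bad):
        m = rf_from_matrix([[0.0, 0.1], [0.1, 0.0]])
        with pytest.raises(ParameterError):
            apply_cutoff(m, bad)


class TestRfIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(2)
        raw = np.triu(rng.uniform(0, 0.5, (5, 5)), 1)
        m = rf_from_matrix(raw + raw.T)
        path = tmp_path / "rf.csv"
        write_rf_matrix(m, path)
        m2 = read_rf_matrix(path)
        assert m2.marker_names == m.marker_names
        assert np.allclose(m2.rf, m.rf, atol=1e-12)

    def test_non_square_rejected(self, tmp_path):
        p = tmp_path / "rf.csv"
        p.write_text(",a,b,c,d\na,0,0.1,0.2,0.3\nb,0.1,0,0.1,0.2\nc,0.2,0.1,0,0.1\n")
        with pytest.raises(FormatError):
            read_rf_matrix(p)

    def test_out_of_range_rejected(self, tmp_path):
        p = tmp_path / "rf.csv"
        p.write_text(",a,b\na,0,0.7\nb,0.7,0\n")
        with pytest.raises(ValidationError):
            read_rf_matrix(p)

    def test_asymmetric_rejected(self, tmp_path):
        p = tmp_path / "rf.csv"
        p.write_text(",a,b\na,0,0.2\nb,0.3,0\n")
        with pytest.raises(ValidationError, match="asymmetric"):
            read_rf_matrix(p)
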