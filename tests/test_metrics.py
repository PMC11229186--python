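"""Dice/DVO/DCC/DCA metrics against brute-force oracles and identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pocketseg import (
    GeometryError,
    dca,
    dcc,
    dice_coefficient,
    dice_loss,
    dvo,
    success_rate,
)
from pocketseg.metrics import EvalRecord, dice_loss_tensor, write_report
from pocketseg.nn.engine import Tensor


# ---------------------------------------------------------------- brute force
def brute_dice(x, y):
    xs = {tuple(i) for i in np.argwhere(x)}
    ys = {tuple(i) for i in np.argwhere(y)}
    if not xs and not ys:
        return 1.0
    return 2 * len(xs & ys) / (len(xs) + len(ys))


def brute_jaccard(x, y):
    xs = {tuple(i) for i in np.argwhere(x)}
    ys = {tuple(i) for i in np.argwhere(y)}
    if not xs | ys:
        return 1.0
    return len(xs & ys) / len(xs | ys)


class TestDiceCoefficient:
    def test_identical_nonempty(self):
        x = np.zeros((4, 4, 4), bool)
        x[1:3, 1:3, 1] = True
        assert dice_coefficient(x, x) == 1.0

    def test_disjoint(self):
        x = np.zeros((4, 4, 4), bool)
        y = np.zeros((4, 4, 4), bool)
        x[0, 0, 0] = True
        y[3, 3, 3] = True
        assert dice_coefficient(x, y) == 0.0

    def test_half_overlap(self):
        x = np.zeros((4, 4, 4), bool)
        y = np.zeros((4, 4, 4), bool)
        x[0, 0, 0] = x[0, 0, 1] = True
        y[0, 0, 1] = y[0, 0, 2] = True
        assert dice_coefficient(x, y) == 0.5

    def test_both_empty_is_one(self):
        z = np.zeros((3, 3, 3), bool)
        assert dice_coefficient(z, z) == 1.0

    def test_shape_mismatch_raises(self):
        with pytest.raises(GeometryError):
            dice_coefficient(np.zeros((3, 3, 3)), np.zeros((4, 4, 4)))


class TestDiceLoss:
    def test_perfect_binary_prediction_is_zero(self):
        t = np.zeros((5, 5, 5))
        t[2, 2, 2] = t[2, 2, 3] = 1
        for eps in (1e-9, 1e-6, 1e-2):
            assert dice_loss(t, t, epsilon=eps) == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_prediction(self):
        t = np.zeros((5, 5, 5))
        t[:2, 0, 0] = 1  # k = 2
        eps = 1e-3
        assert dice_loss(np.zeros_like(t), t, eps) == pytest.approx(1 - eps / (2 + eps))

    def test_both_empty_is_zero(self):
        z = np.zeros((4, 4, 4))
        assert dice_loss(z, z) == pytest.approx(0.0)

    def test_epsilon_limit_recovers_dice(self, rng):
        y = (rng.random((6, 6, 6)) > 0.6).astype(float)
        t = (rng.random((6, 6, 6)) > 0.6).astype(float)
        loss = dice_loss(y, t, epsilon=1e-9)
        assert 1 - loss == pytest.approx(dice_coefficient(y, t), abs=1e-6)

    def test_in_unit_interval(self, rng):
        for _ in range(20):
            y = rng.random((4, 4, 4))
            t = (rng.random((4, 4, 4)) > 0.5).astype(float)
            assert 0.0 <= dice_loss(y, t) < 1.0

    def test_tensor_version_matches_scalar(self, rng):
        y = rng.random((2, 4, 4, 4, 1)).astype(np.float32)
        t = (rng.random((2, 4, 4, 4, 1)) > 0.5).astype(np.float32)
        got = dice_loss_tensor(Tensor(y), t, 1e-6).item()
        expected = np.mean([dice_loss(y[i, ..., 0], t[i, ..., 0], 1e-6) for i in range(2)])
        assert got == pytest.approx(expected, abs=1e-5)


class TestDistances:
    def test_dcc_zero_and_pythagoras(self):
        assert dcc((0, 0, 0), (0, 0, 0)) == 0.0
        assert dcc((0, 0, 0), (3, 4, 0)) == pytest.approx(5.0)

    def test_dcc_symmetric(self, rng):
        a, b = rng.normal(size=3), rng.normal(size=3)
        assert dcc(a, b) == pytest.approx(dcc(b, a))

    def test_dca_minimum(self):
        center = np.zeros(3)
        atoms = [(2, 0, 0), (0, 6, 0), (0, 0, 9)]
        assert dca(center, atoms) == pytest.approx(2.0)

    def test_dca_coincident_atom(self):
        assert dca((1, 1, 1), [(1, 1, 1), (9, 9, 9)]) == 0.0

    def test_dca_single_atom_equals_dcc(self, rng):
        c, a = rng.normal(size=3), rng.normal(size=3)
        assert dca(c, [a]) == pytest.approx(dcc(c, a))

    def test_dca_empty_ligand_raises(self):
        with pytest.raises(ValueError):
            dca((0, 0, 0), [])


class TestDVO:
    def test_identical_and_disjoint(self):
        x = np.zeros((4, 4, 4), bool)
        x[1, 1, 1] = True
        y = np.zeros((4, 4, 4), bool)
        y[2, 2, 2] = True
        assert dvo(x, x) == 1.0
        assert dvo(x, y) == 0.0

    def test_two_thirds_overlap(self):
        x = np.zeros((4, 4, 4), bool)
        y = np.zeros((4, 4, 4), bool)
        x[0, 0, :3] = True  # |pred| = 3
        y[0, 0, 1:4] = True  # |true| = 3, overlap 2, union 4
        assert dvo(x, y) == pytest.approx(0.5)

    @given(st.integers(0, 2**30 - 1))
    @settings(max_examples=30, deadline=None)
    def test_jaccard_le_dice(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.random((4, 4, 4)) > 0.5
        y = rng.random((4, 4, 4)) > 0.5
        j, d = dvo(x, y), dice_coefficient(x, y)
        assert j <= d + 1e-12
        if 0 < j < 1:
            assert j < d


class TestSuccessRate:
    def test_direct_count(self):
        s = success_rate([1, 2, 3, 5], threshold=4)
        assert (s.n_total, s.n_success) == (4, 3)
        assert s.success_rate == pytest.approx(0.75)

    def test_all_below_and_above(self):
        assert success_rate([0.1, 1, 3.9]).success_rate == 1.0
        assert success_rate([4.1, 8, 100]).success_rate == 0.0

    def test_boundary_inclusive_by_default(self):
        assert success_rate([4.0]).success_rate == 1.0
        assert success_rate([4.0], inclusive=False).success_rate == 0.0

    def test_monotone_in_threshold(self, rng):
        d = rng.uniform(0, 10, size=50)
        rates = [success_rate(d, threshold=t).success_rate for t in np.linspace(0, 10, 21)]
        assert all(a <= b for a, b in zip(rates, rates[1:]))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            success_rate([])


class TestOracleEquivalence:
    @given(st.integers(0, 2**30 - 1))
    @settings(max_examples=50, deadline=None)
    def test_overlap_metrics_match_set_arithmetic(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(2, 6, size=3))
        x = rng.random(shape) > rng.uniform(0.3, 0.9)
        y = rng.random(shape) > rng.uniform(0.3, 0.9)
        assert dice_coefficient(x, y) == pytest.approx(brute_dice(x, y), abs=1e-12)
        assert dvo(x, y) == pytest.approx(brute_jaccard(x, y), abs=1e-12)


class TestReport:
    def test_report_columns_and_summary(self, tmp_path):
        records = [
            EvalRecord(pocket_id="a", dcc=1.0, dca=0.5, dvo=0.8),
            EvalRecord(pocket_id="b", dcc=6.0, dca=5.0),
        ]
        path = tmp_path / "eval.tsv"
        frame = write_report(records, path)
        text = path.read_text()
        for col in ("pocket_id", "dcc", "dca", "dvo", "dcc_success", "dca_success"):
            assert col in text
        assert frame["dcc_success"].tolist() == [True, False]
        assert "# dcc_success_rate\t0.5" in text
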