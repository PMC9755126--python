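"""Validation metric panel against independent brute-force oracles."""

import math

import numpy as np
import pytest

from smilescw.cw_model import CorrelationWeightTable, QsarModel
from smilescw.dataset_io import CALIBRATION, INVISIBLE_TRAIN, TRAIN, Compound, Dataset
from smilescw.monte_carlo import OptimizerConfig, iic
from smilescw.smiles_attributes import AttributeProfile
from smilescw.validation import (
    DECREASE,
    INCREASE,
    UNDEFINED,
    ccc,
    classify_promoters,
    f_stat,
    mae,
    pearson_r,
    q2_loo,
    qf1,
    qf2,
    qf3,
    r2,
    rm2_metrics,
    s_err,
    y_randomization,
)

# ----------------------------------------------------------------------
# brute-force oracle implementations: plain-Python re-statements of the
# printed formulas, independent of the library code paths


def _bf_r2(obs, pred):
    ybar = sum(obs) / len(obs)
    return 1 - sum((o - p) ** 2 for o, p in zip(obs, pred)) / sum((o - ybar) ** 2 for o in obs)


def _bf_qf1(obs, pred, train_mean):
    return 1 - sum((p - o) ** 2 for o, p in zip(obs, pred)) / sum(
        (o - train_mean) ** 2 for o in obs
    )


def _bf_qf3(obs, pred, train):
    tbar = sum(train) / len(train)
    num = sum((p - o) ** 2 for o, p in zip(obs, pred)) / len(obs)
    den = sum((t - tbar) ** 2 for t in train) / len(train)
    return 1 - num / den


def _bf_ccc(obs, pred):
    xb = sum(obs) / len(obs)
    yb = sum(pred) / len(pred)
    num = 2 * sum((x - xb) * (y - yb) for x, y in zip(obs, pred))
    den = (
        sum((x - xb) ** 2 for x in obs)
        + sum((y - yb) ** 2 for y in pred)
        + len(obs) * (xb - yb) ** 2
    )
    return num / den


def _bf_iic(obs, pred):
    deltas = [o - p for o, p in zip(obs, pred)]
    neg = [abs(d) for d in deltas if d < 0]
    pos = [abs(d) for d in deltas if d >= 0]
    mneg = sum(neg) / len(neg) if neg else 0.0
    mpos = sum(pos) / len(pos) if pos else 0.0
    lo, hi = min(mneg, mpos), max(mneg, mpos)
    ratio = 1.0 if hi == 0 else (0.0 if lo == 0 else lo / hi)
    n = len(obs)
    xb, yb = sum(obs) / n, sum(pred) / n
    num = sum((x - xb) * (y - yb) for x, y in zip(obs, pred))
    den = math.sqrt(sum((x - xb) ** 2 for x in obs) * sum((y - yb) ** 2 for y in pred))
    return (num / den) * ratio


def _bf_rm2(obs, pred):
    def rsq(x, y):
        n = len(x)
        xb, yb = sum(x) / n, sum(y) / n
        num = sum((a - xb) * (b - yb) for a, b in zip(x, y))
        den = math.sqrt(sum((a - xb) ** 2 for a in x) * sum((b - yb) ** 2 for b in y))
        return (num / den) ** 2

    def r0sq(y, x):
        k = sum(a * b for a, b in zip(y, x)) / sum(b * b for b in x)
        yb = sum(y) / len(y)
        return 1 - sum((a - k * b) ** 2 for a, b in zip(y, x)) / sum((a - yb) ** 2 for a in y)

    r = rsq(obs, pred)
    fwd = r * (1 - math.sqrt(max(0.0, r - r0sq(obs, pred))))
    rev = r * (1 - math.sqrt(max(0.0, r - r0sq(pred, obs))))
    return fwd, rev


def _bf_q2_loo(x, y):
    n = len(x)
    press = 0.0
    for i in range(n):
        xs = [x[j] for j in range(n) if j != i]
        ys = [y[j] for j in range(n) if j != i]
        xb, yb = sum(xs) / (n - 1), sum(ys) / (n - 1)
        sxx = sum((a - xb) ** 2 for a in xs)
        c1 = sum((a - xb) * (b - yb) for a, b in zip(xs, ys)) / sxx
        c0 = yb - c1 * xb
        press += (y[i] - (c0 + c1 * x[i])) ** 2
    ybar = sum(y) / n
    return 1 - press / sum((v - ybar) ** 2 for v in y)


def _random_vectors(rng, n_points):
    obs = rng.normal(loc=6.0, scale=1.2, size=n_points)
    pred = obs * rng.uniform(0.6, 1.4) + rng.normal(scale=0.5, size=n_points) + rng.uniform(-1, 1)
    return obs, pred


def test_metric_suite_matches_bruteforce_oracles(rng):
    """Every printed formula agrees with an independent evaluation to 1e-12."""
    for _ in range(100):
        n = int(rng.integers(5, 30))
        obs, pred = _random_vectors(rng, n)
        train = rng.normal(loc=6.0, scale=1.0, size=int(rng.integers(5, 30)))
        tm = float(train.mean())
        assert r2(obs, pred) == pytest.approx(_bf_r2(obs, pred), abs=1e-12)
        assert qf1(obs, pred, tm) == pytest.approx(_bf_qf1(obs, pred, tm), abs=1e-12)
        assert qf2(obs, pred) == pytest.approx(_bf_r2(obs, pred), abs=1e-12)
        assert qf3(obs, pred, train) == pytest.approx(_bf_qf3(obs, pred, train), abs=1e-12)
        assert ccc(obs, pred) == pytest.approx(_bf_ccc(obs, pred), abs=1e-12)
        assert mae(obs, pred) == pytest.approx(
            sum(abs(o - p) for o, p in zip(obs, pred)) / n, abs=1e-12
        )
        assert iic(obs, pred) == pytest.approx(_bf_iic(obs, pred), abs=1e-12)
        fwd, rev = _bf_rm2(obs, pred)
        rm = rm2_metrics(obs, pred)
        assert rm["rm2"] == pytest.approx(fwd, abs=1e-12)
        assert rm["mean_rm2"] == pytest.approx(0.5 * (fwd + rev), abs=1e-12)
        assert rm["delta_rm2"] == pytest.approx(abs(fwd - rev), abs=1e-12)
        assert q2_loo(pred, obs) == pytest.approx(_bf_q2_loo(pred, obs), abs=1e-10)


def test_perfect_prediction_limits():
    obs = np.array([4.1, 5.2, 6.3, 7.4, 8.5])
    train = np.array([4.0, 6.0, 8.0])
    assert r2(obs, obs) == 1.0
    assert qf1(obs, obs, train.mean()) == 1.0
    assert qf2(obs, obs) == 1.0
    assert qf3(obs, obs, train) == 1.0
    assert ccc(obs, obs) == 1.0
    assert mae(obs, obs) == 0.0
    assert iic(obs, obs) == pytest.approx(1.0)
    rm = rm2_metrics(obs, obs)
    assert rm["rm2"] == pytest.approx(1.0)
    assert rm["delta_rm2"] == pytest.approx(0.0, abs=1e-12)
    assert rm["delta_rm2_scaled"] == pytest.approx(0.0, abs=1e-12)


def test_qf1_hand_example():
    obs = [1.0, 2.0, 3.0, 4.0]
    pred = [1.5, 1.5, 3.5, 3.5]
    assert qf1(obs, pred, 2.5) == pytest.approx(1 - 1.0 / 5.0)


def test_ccc_anticorrelated_hand_example():
    assert ccc([1.0, 2.0, 3.0], [3.0, 2.0, 1.0]) == pytest.approx(-1.0)


def test_f_and_s_statistics():
    # F = R^2 (n-2) / (1-R^2); s uses n-2 residual dof
    assert f_stat(0.8, 102) == pytest.approx(0.8 * 100 / 0.2)
    obs = np.array([1.0, 2, 3, 4])
    pred = np.array([1.5, 1.5, 3.5, 3.5])
    assert s_err(obs, pred) == pytest.approx(math.sqrt(1.0 / 2.0))
    assert f_stat(1.0, 10) == math.inf


def test_zero_variance_rejected():
    from smilescw.validation import UndefinedMetricError

    with pytest.raises(UndefinedMetricError):
        r2(np.ones(5), np.arange(5.0))


class TestYRandomization:
    def test_crp2_closed_form(self):
        # R^2=0.8, mean Rr^2=0.1 -> CRp2 = sqrt(0.8)*sqrt(0.7)
        assert math.sqrt(0.8) * math.sqrt(0.8 - 0.1) == pytest.approx(0.7483, abs=1e-4)

    def test_crp2_equals_r2_when_rr2_zero(self):
        r_sq = 0.77
        assert math.sqrt(r_sq) * math.sqrt(r_sq - 0.0) == pytest.approx(r_sq)

    def test_scrambling_degrades_fit_and_crp2_stays_high(self, small_panel, fast_config):
        labelled, profiles, _ = small_panel
        from smilescw.monte_carlo import build_model, optimize
        from smilescw.validation import r2 as _r2

        table, _ = optimize(labelled, profiles, fast_config)
        model = build_model(labelled, profiles, table, fast_config)
        train = [c for c in labelled.compounds if c.set_label == TRAIN]
        obs = np.array([c.endpoint for c in train])
        pred = np.array([model.predict_one(profiles[c.id]) for c in train])
        real_r2 = pearson_r(obs, pred) ** 2
        mean_rr2, crp2, rr2s = y_randomization(
            labelled, profiles, fast_config, n_shuffles=3, real_model=model
        )
        assert len(rr2s) == 3
        assert mean_rr2 < real_r2  # scrambling destroys the planted signal
        assert crp2 == pytest.approx(
            math.sqrt(real_r2) * math.sqrt(max(0.0, real_r2 - mean_rr2)), abs=1e-9
        )


class TestPromoters:
    def _model(self, weights):
        table = CorrelationWeightTable(weights=weights, T=1)
        return QsarModel(cw_table=table, T_star=1, N_star=15, c0=0.0, c1=1.0)

    def _dataset(self):
        comps = [
            Compound("t1", "cccc", 5.0, TRAIN),
            Compound("i1", "cccc", 5.5, INVISIBLE_TRAIN),
            Compound("c1", "cccc", 6.0, CALIBRATION),
        ]
        ds = Dataset(comps)
        from smilescw.smiles_attributes import profile_dataset

        return ds, profile_dataset(ds)

    def test_sign_consistency_classification(self):
        ds, profiles = self._dataset()
        key = "c…c…c…"
        probes = [
            self._model({key: 0.29321}),
            self._model({key: 0.31987}),
            self._model({key: 0.17186}),
        ]
        records = classify_promoters(probes, ds, profiles)
        rec = next(r for r in records if r.key == key)
        assert rec.classification == INCREASE
        assert (rec.n_train, rec.n_inv_train, rec.n_cal) == (1, 1, 1)

        probes_neg = [self._model({key: w}) for w in (-0.0558, -0.3626, -0.0620)]
        assert (
            next(r for r in classify_promoters(probes_neg, ds, profiles) if r.key == key)
        ).classification == DECREASE

        probes_mixed = [self._model({key: w}) for w in (0.5, -0.5, 0.1)]
        assert (
            next(r for r in classify_promoters(probes_mixed, ds, profiles) if r.key == key)
        ).classification == UNDEFINED

    def test_records_sorted_by_mean_cw_magnitude(self):
        ds, profiles = self._dataset()
        weights = {"c…c…c…": 0.1, "Cmax.0": 2.0}
        probes = [self._model(dict(weights)) for _ in range(3)]
        records = classify_promoters(probes, ds, profiles)
        assert records[0].key == "Cmax.0"

    def test_requires_two_probes(self):
        ds, profiles = self._dataset()
        with pytest.raises(ValueError):
            classify_promoters([self._model({"c…c…c…": 1.0})], ds, profiles)
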