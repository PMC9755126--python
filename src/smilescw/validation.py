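"""Validation metrics, Y-randomization and promoter interpretation.

Implements the full internal/external validation panel used for
correlation-weight QSAR models: determination coefficient R², leave-one-out
Q², the external predictivity coefficients Q²F1/Q²F2/Q²F3, Lin's
concordance correlation coefficient (CCC), MAE, the Roy rm² family
(plain, reversed, mean, delta, and min-max-scaled variants), the F
statistic and residual standard error of the one-variable fit, and the
Y-randomization statistic CRp² = R·sqrt(R² − mean Rr²).

Mechanistic interpretation classifies each attribute by the sign of its
correlation weight across independent optimization probes: consistently
positive → promoter of endpoint increase, consistently negative →
promoter of decrease, mixed signs → undefined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cw_model import QsarModel, compute_dcw
from .dataset_io import (
    CALIBRATION,
    INVISIBLE_TRAIN,
    TRAIN,
    VALIDATION,
    Compound,
    Dataset,
)
from .monte_carlo import OptimizerConfig, build_model, iic, optimize
from .applicability_domain import DefectTable
from .smiles_attributes import AttributeProfile

__all__ = [
    "UndefinedMetricError",
    "SetMetrics",
    "MetricsReport",
    "PromoterRecord",
    "r2",
    "q2_loo",
    "qf1",
    "qf2",
    "qf3",
    "ccc",
    "mae",
    "rm2_metrics",
    "f_stat",
    "s_err",
    "pearson_r",
    "evaluate_sets",
    "y_randomization",
    "classify_promoters",
    "write_promoter_report",
]

INCREASE = "INCREASE"
DECREASE = "DECREASE"
UNDEFINED = "UNDEFINED"


class UndefinedMetricError(ValueError):
    """Raised when a metric's denominator is degenerate (zero variance)."""


def _check(obs, pred) -> tuple[np.ndarray, np.ndarray]:
    o = np.asarray(obs, dtype=float)
    p = np.asarray(pred, dtype=float)
    if o.shape != p.shape or o.ndim != 1:
        raise ValueError("observed and predicted must be 1-D of equal length")
    if o.size < 3:
        raise ValueError("need at least 3 points")
    return o, p


def pearson_r(obs, pred) -> float:
    o, p = _check(obs, pred)
    so = o - o.mean()
    sp = p - p.mean()
    den = math.sqrt(float(np.dot(so, so)) * float(np.dot(sp, sp)))
    if den == 0.0:
        raise UndefinedMetricError("zero variance; correlation undefined")
    return float(np.dot(so, sp) / den)


def r2(obs, pred) -> float:
    """Determination coefficient 1 − Σ(Yobs−Yprd)² / Σ(Yobs−Ȳ)²."""
    o, p = _check(obs, pred)
    sst = float(np.sum((o - o.mean()) ** 2))
    if sst == 0.0:
        raise UndefinedMetricError("zero variance in observed values")
    return 1.0 - float(np.sum((o - p) ** 2)) / sst


def qf1(obs_test, pred_test, train_mean: float) -> float:
    """External Q²F1: residual sum scaled by spread around the training mean."""
    o, p = _check(obs_test, pred_test)
    den = float(np.sum((o - train_mean) ** 2))
    if den == 0.0:
        raise UndefinedMetricError("test observations identical to training mean")
    return 1.0 - float(np.sum((p - o) ** 2)) / den


def qf2(obs_test, pred_test) -> float:
    """External Q²F2: residual sum scaled by spread around the test mean."""
    return r2(obs_test, pred_test)


def qf3(obs_test, pred_test, train_obs) -> float:
    """External Q²F3: per-point residual MS over training variance."""
    o, p = _check(obs_test, pred_test)
    t = np.asarray(train_obs, dtype=float)
    den = float(np.sum((t - t.mean()) ** 2)) / t.size
    if den == 0.0:
        raise UndefinedMetricError("zero variance in training observations")
    return 1.0 - (float(np.sum((p - o) ** 2)) / o.size) / den


def ccc(obs, pred) -> float:
    """Lin's concordance correlation coefficient."""
    o, p = _check(obs, pred)
    om, pm = o.mean(), p.mean()
    so, sp = o - om, p - pm
    den = float(np.dot(so, so)) + float(np.dot(sp, sp)) + o.size * (om - pm) ** 2
    if den == 0.0:
        raise UndefinedMetricError("degenerate CCC denominator")
    return 2.0 * float(np.dot(so, sp)) / den


def mae(obs, pred) -> float:
    o, p = _check(obs, pred)
    return float(np.mean(np.abs(o - p)))


def _r0_squared(y: np.ndarray, x: np.ndarray) -> float:
    """Through-origin determination of y on x (Roy convention)."""
    sxx = float(np.dot(x, x))
    if sxx == 0.0:
        raise UndefinedMetricError("through-origin slope undefined")
    k = float(np.dot(y, x)) / sxx
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        raise UndefinedMetricError("zero variance in observed values")
    return 1.0 - float(np.sum((y - k * x) ** 2)) / sst


def _rm2_pair(y: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """(rm², reversed rm²) from obs y and pred x."""
    rsq = pearson_r(y, x) ** 2
    fwd = rsq * (1.0 - math.sqrt(max(0.0, rsq - _r0_squared(y, x))))
    rev = rsq * (1.0 - math.sqrt(max(0.0, rsq - _r0_squared(x, y))))
    return fwd, rev


def rm2_metrics(obs, pred) -> dict[str, float]:
    """Roy rm² family.

    ``rm2`` uses the observed-vs-predicted through-origin fit; ``rm2_rev``
    swaps the roles; ``mean_rm2``/``delta_rm2`` are their average and
    absolute difference. The ``*_scaled`` variants first min-max scale both
    vectors to [0, 1] jointly over observed values (the modified-rm²
    convention).
    """
    o, p = _check(obs, pred)
    fwd, rev = _rm2_pair(o, p)
    span = o.max() - o.min()
    if span == 0.0:
        raise UndefinedMetricError("zero endpoint range; scaling undefined")
    os = (o - o.min()) / span
    ps = (p - o.min()) / span
    fwd_s, rev_s = _rm2_pair(os, ps)
    return {
        "rm2": fwd,
        "rm2_rev": rev,
        "mean_rm2": 0.5 * (fwd + rev),
        "delta_rm2": abs(fwd - rev),
        "mean_rm2_scaled": 0.5 * (fwd_s + rev_s),
        "delta_rm2_scaled": abs(fwd_s - rev_s),
    }


def f_stat(r_squared: float, n: int) -> float:
    """F statistic of the one-variable model: R²(n−2)/(1−R²)."""
    if not 0.0 <= r_squared < 1.0:
        if r_squared == 1.0:
            return math.inf
        raise ValueError("R² must lie in [0, 1]")
    return r_squared * (n - 2) / (1.0 - r_squared)


def s_err(obs, pred, n_params: int = 2) -> float:
    """Residual standard error with n − n_params denominator."""
    o, p = _check(obs, pred)
    if o.size <= n_params:
        raise ValueError("too few points for the residual degrees of freedom")
    return math.sqrt(float(np.sum((o - p) ** 2)) / (o.size - n_params))


def q2_loo(dcw, obs) -> float:
    """Leave-one-out Q² of the univariate fit, weights frozen.

    Only the intercept and slope are refit per fold; the closed form via
    hat values h_i = 1/n + (x_i − x̄)²/Sxx gives the exact LOO residuals
    e_i/(1 − h_i).
    """
    x = np.asarray(dcw, dtype=float)
    y = np.asarray(obs, dtype=float)
    if x.shape != y.shape or x.size < 4:
        raise ValueError("need at least 4 equally long points for LOO")
    xc = x - x.mean()
    sxx = float(np.dot(xc, xc))
    if sxx == 0.0:
        raise UndefinedMetricError("zero variance in DCW")
    c1 = float(np.dot(xc, y - y.mean())) / sxx
    c0 = float(y.mean() - c1 * x.mean())
    resid = y - (c0 + c1 * x)
    h = 1.0 / x.size + xc**2 / sxx
    press = float(np.sum((resid / (1.0 - h)) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / sst


# ----------------------------------------------------------------------
# report assembly


@dataclass
class SetMetrics:
    n: int
    r2: float
    ccc: float
    iic: float
    q2: float
    s: float
    mae: float
    f: float
    qf1: float | None = None
    qf2: float | None = None
    qf3: float | None = None
    rm2: float | None = None
    mean_rm2: float | None = None
    delta_rm2: float | None = None
    mean_rm2_scaled: float | None = None
    delta_rm2_scaled: float | None = None


@dataclass
class MetricsReport:
    per_set: dict[str, SetMetrics]
    crp2: float | None = None
    mean_rr2: float | None = None

    def to_dict(self) -> dict:
        out = {
            label: {k: v for k, v in vars(m).items() if v is not None}
            for label, m in self.per_set.items()
        }
        if self.crp2 is not None:
            out["y_randomization"] = {"crp2": self.crp2, "mean_rr2": self.mean_rr2}
        return out


def evaluate_sets(
    dataset: Dataset,
    profiles: Mapping[str, AttributeProfile],
    model: QsarModel,
) -> MetricsReport:
    """Per-set metric panel for a calibrated model.

    Internal metrics (R², CCC, IIC, Q², s, MAE, F) are reported for all
    four sets; the external panel (Q²F1–3, rm² family) additionally for
    the calibration and validation sets, referenced to the training set.
    """
    by_label: dict[str, list[Compound]] = {}
    for c in dataset.compounds:
        if c.set_label:
            by_label.setdefault(c.set_label, []).append(c)
    train = by_label.get(TRAIN, [])
    if not train:
        raise ValueError("dataset has no training compounds")
    y_train = np.array([c.endpoint for c in train])
    per_set: dict[str, SetMetrics] = {}
    for label in (TRAIN, INVISIBLE_TRAIN, CALIBRATION, VALIDATION):
        comps = by_label.get(label)
        if not comps:
            continue
        obs = np.array([c.endpoint for c in comps])
        dcw = np.array([model.dcw(profiles[c.id]) for c in comps])
        pred = model.c0 + model.c1 * dcw
        rsq = r2(obs, pred)
        m = SetMetrics(
            n=len(comps),
            r2=rsq,
            ccc=ccc(obs, pred),
            iic=iic(obs, pred),
            q2=q2_loo(dcw, obs),
            s=s_err(obs, pred),
            mae=mae(obs, pred),
            f=f_stat(max(0.0, rsq), len(comps)),
        )
        if label in (CALIBRATION, VALIDATION):
            rm = rm2_metrics(obs, pred)
            m = replace(
                m,
                qf1=qf1(obs, pred, float(y_train.mean())),
                qf2=qf2(obs, pred),
                qf3=qf3(obs, pred, y_train),
                rm2=rm["rm2"],
                mean_rm2=rm["mean_rm2"],
                delta_rm2=rm["delta_rm2"],
                mean_rm2_scaled=rm["mean_rm2_scaled"],
                delta_rm2_scaled=rm["delta_rm2_scaled"],
            )
        per_set[label] = m
    return MetricsReport(per_set=per_set)


def y_randomization(
    dataset: Dataset,
    profiles: Mapping[str, AttributeProfile],
    config: OptimizerConfig,
    n_shuffles: int = 10,
    *,
    real_model: QsarModel | None = None,
) -> tuple[float, float, list[float]]:
    """Y-scrambling robustness test.

    Endpoints of the training + invisible-training compounds are shuffled
    (seeded), the full Monte Carlo optimization is re-run per shuffle, and
    the randomized training R² (Rr²) is recorded. Returns
    (mean Rr², CRp², list of Rr²) with CRp² = R·sqrt(R² − mean Rr²)
    computed from the real model's training R².
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if real_model is None:
        table, _ = optimize(dataset, profiles, config)
        real_model = build_model(dataset, profiles, table, config)
    train = [c for c in dataset.compounds if c.set_label == TRAIN]
    obs = np.array([c.endpoint for c in train])
    pred = np.array([real_model.predict_one(profiles[c.id]) for c in train])
    r = pearson_r(obs, pred)
    rsq = r**2

    pool_idx = [
        i
        for i, c in enumerate(dataset.compounds)
        if c.set_label in (TRAIN, INVISIBLE_TRAIN)
    ]
    rng = np.random.default_rng(config.seed + 104729)  # offset stream for shuffles
    rr2_values: list[float] = []
    for shuffle_i in range(n_shuffles):
        perm = rng.permutation(len(pool_idx))
        compounds = list(dataset.compounds)
        pool = [compounds[i] for i in pool_idx]
        for slot, src in zip(pool_idx, perm):
            c = compounds[slot]
            compounds[slot] = Compound(c.id, c.smiles, pool[src].endpoint, c.set_label)
        shuffled = Dataset(compounds=compounds, name=f"{dataset.name}-yrand{shuffle_i}")
        cfg = replace(config, seed=config.seed + 1000 + shuffle_i)
        table, _ = optimize(shuffled, profiles, cfg)
        model = build_model(shuffled, profiles, table, cfg)
        s_train = [c for c in shuffled.compounds if c.set_label == TRAIN]
        o = np.array([c.endpoint for c in s_train])
        p = np.array([model.predict_one(profiles[c.id]) for c in s_train])
        rr2_values.append(pearson_r(o, p) ** 2)

    mean_rr2 = float(np.mean(rr2_values))
    crp2 = abs(r) * math.sqrt(max(0.0, rsq - mean_rr2))
    return mean_rr2, crp2, rr2_values


# ----------------------------------------------------------------------
# promoter interpretation


@dataclass(frozen=True)
class PromoterRecord:
    key: str
    cws: tuple[float, ...]
    n_train: int
    n_inv_train: int
    n_cal: int
    defect: float
    classification: str

    @property
    def mean_cw(self) -> float:
        return float(np.mean(self.cws))


def classify_promoters(
    probe_models: Sequence[QsarModel],
    dataset: Dataset,
    profiles: Mapping[str, AttributeProfile],
    defect_table: DefectTable | None = None,
) -> list[PromoterRecord]:
    """Classify attributes by CW sign consistency across probes.

    An attribute active in every probe is a promoter of increase if all
    its CWs are positive, of decrease if all are negative, and undefined
    otherwise. Records are sorted by |mean CW| descending.
    """
    if len(probe_models) < 2:
        raise ValueError("need at least 2 probes to classify promoters")
    common = set(probe_models[0].cw_table.weights) - set(probe_models[0].cw_table.rare_keys)
    for m in probe_models[1:]:
        common &= set(m.cw_table.weights) - set(m.cw_table.rare_keys)

    def set_count(label: str, key: str) -> int:
        return sum(
            1
            for c in dataset.compounds
            if c.set_label == label and key in profiles[c.id].all_keys()
        )

    records = []
    for key in sorted(common):
        cws = tuple(m.cw_table.cw(key) for m in probe_models)
        if all(w > 0 for w in cws):
            cls = INCREASE
        elif all(w < 0 for w in cws):
            cls = DECREASE
        else:
            cls = UNDEFINED
        defect = (
            defect_table.attribute_defects.get(key, 1.0) if defect_table else float("nan")
        )
        records.append(
            PromoterRecord(
                key=key,
                cws=cws,
                n_train=set_count(TRAIN, key),
                n_inv_train=set_count(INVISIBLE_TRAIN, key),
                n_cal=set_count(CALIBRATION, key),
                defect=defect,
                classification=cls,
            )
        )
    records.sort(key=lambda r: (-abs(r.mean_cw), r.key))
    return records


def write_promoter_report(records: Sequence[PromoterRecord], path: str | Path) -> Path:
    """TSV mirroring the usual promoter table layout."""
    rows = []
    for r in records:
        row = {"key": r.key, "classification": r.classification}
        for i, w in enumerate(r.cws, start=1):
            row[f"cw_probe{i}"] = w
        row.update(
            {"NT": r.n_train, "NiT": r.n_inv_train, "NC": r.n_cal, "defect": r.defect}
        )
        rows.append(row)
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.5g")
    return path
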