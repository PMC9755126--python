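"""Monte Carlo optimization of correlation weights.

The weights are trained by maximizing a *balance of correlations* target.
With R_tr and R_itr the Pearson correlations between observed and
predicted endpoint on the training and invisible-training sets,

    TF  = R_tr + R_itr − |R_tr − R_itr| · dR_weight
    TFm = TF + IIC_cal · IIC_weight

where IIC_cal is the index of ideality of correlation on the calibration
set: the calibration Pearson correlation shrunk by the asymmetry of the
mean absolute errors of the negative- and positive-residual classes,

    IIC = R_cal · min(−MAE, +MAE) / max(−MAE, +MAE),   Δ = observed − predicted.

Optimization is a coordinate-wise greedy hill climb: active attributes are
visited in a seeded random order each epoch, a uniform perturbation of the
attribute's CW is proposed, the univariate model is refit on the training
set, and the move is kept only if TFm strictly increases. Rare attributes
(training occurrence < T) stay frozen at CW = 0. Everything is driven by
one integer seed, so runs are exactly reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .cw_model import (
    CorrelationWeightTable,
    QsarModel,
    attribute_counts,
    compute_dcw,
    fit_univariate,
)
from .dataset_io import CALIBRATION, INVISIBLE_TRAIN, TRAIN, Dataset
from .smiles_attributes import AttributeProfile

__all__ = [
    "OptimizerConfig",
    "TargetState",
    "iic",
    "target_function",
    "optimize",
    "build_model",
    "run_probes",
    "grid_search_TN",
]

logger = logging.getLogger(__name__)

# cap on how far an accepted move may be repeated within one visit
_MAX_RIDE = 50
# paired proposals per epoch, as a multiple of the active-attribute count
_PAIR_FACTOR = 2


@dataclass(frozen=True)
class OptimizerConfig:
    """Knobs of the Monte Carlo search.

    ``iic_weight`` and ``dr_weight`` are the empirical constants of the
    modified target function (defaults 0.2 and 0.1). Weights start from a
    seeded uniform(init_low, init_high) draw — small but positive, which
    pins the optimizer to the positively-correlated solution of the
    otherwise sign-symmetric target while keeping the initial descriptor
    close to zero — and proposals are uniform on ±``step``. The half-width
    must be large enough that a weight can cross zero within N epochs, or
    promoters of decrease would be unreachable.
    """

    T: int = 1
    n_epochs: int = 15
    iic_weight: float = 0.2
    dr_weight: float = 0.1
    init_low: float = 0.0
    init_high: float = 0.2
    step: float = 0.5
    seed: int = 0
    n_probes: int = 3
    use_bond: bool = True

    def __post_init__(self) -> None:
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")
        if self.iic_weight < 0 or self.dr_weight < 0:
            raise ValueError("iic_weight and dr_weight must be >= 0")
        if self.init_low > self.init_high:
            raise ValueError("init_low must be <= init_high")
        if self.step <= 0:
            raise ValueError("step must be > 0")


@dataclass(frozen=True)
class TargetState:
    R_training: float
    R_invTraining: float
    IIC_cal: float
    TF: float
    TFm: float


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    n = x.size
    sx, sy = x.sum(), y.sum()
    den = (n * np.dot(x, x) - sx * sx) * (n * np.dot(y, y) - sy * sy)
    if den <= 0.0:
        return 0.0
    r = (n * np.dot(x, y) - sx * sy) / math.sqrt(den)
    return float(min(1.0, max(-1.0, r)))


def iic(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Index of ideality of correlation.

    Residuals Δ = observed − predicted are split by sign; each class's MAE
    uses its own count as denominator. Degenerate cases: both class MAEs
    zero (perfect model) → ratio 1, so IIC = R; exactly one class empty or
    zero (systematic one-sided error) → IIC = 0. A negative calibration
    correlation propagates its sign (no clamping).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be 1-D and equally long")
    if obs.size < 2:
        raise ValueError("need at least 2 points")
    delta = obs - pred
    neg = np.abs(delta[delta < 0])
    pos = np.abs(delta[delta >= 0])
    mae_neg = float(neg.mean()) if neg.size else 0.0
    mae_pos = float(pos.mean()) if pos.size else 0.0
    lo, hi = min(mae_neg, mae_pos), max(mae_neg, mae_pos)
    if hi == 0.0:
        ratio = 1.0
    elif lo == 0.0:
        ratio = 0.0
    else:
        ratio = lo / hi
    return _pearson(obs, pred) * ratio


def target_function(
    r_training: float,
    r_inv_training: float,
    iic_cal: float,
    config: OptimizerConfig,
) -> TargetState:
    """Assemble TF and TFm from the three set-level statistics."""
    tf = r_training + r_inv_training - abs(r_training - r_inv_training) * config.dr_weight
    return TargetState(
        R_training=r_training,
        R_invTraining=r_inv_training,
        IIC_cal=iic_cal,
        TF=tf,
        TFm=tf + iic_cal * config.iic_weight,
    )


# ----------------------------------------------------------------------
# internal optimizer machinery


class _SetState:
    """Endpoint vector, DCW vector and running sums for one subset."""

    def __init__(self, y: np.ndarray):
        self.y = y
        self.n = y.size
        self.sy = float(y.sum())
        self.syy = float(np.dot(y, y))
        self.dcw = np.zeros(self.n)
        self.sx = 0.0
        self.sxx = 0.0
        self.sxy = 0.0

    def reset_dcw(self, dcw: np.ndarray) -> None:
        self.dcw = dcw
        self.sx = float(dcw.sum())
        self.sxx = float(np.dot(dcw, dcw))
        self.sxy = float(np.dot(dcw, self.y))

    def shifted_sums(self, idx: np.ndarray, d: np.ndarray) -> tuple[float, float, float]:
        if idx.size == 0:
            return self.sx, self.sxx, self.sxy
        x = self.dcw[idx]
        return (
            self.sx + float(d.sum()),
            self.sxx + float(np.dot(2.0 * x + d, d)),
            self.sxy + float(np.dot(d, self.y[idx])),
        )

    def commit(self, idx: np.ndarray, d: np.ndarray, sums: tuple[float, float, float]) -> None:
        if idx.size:
            self.dcw[idx] += d
        self.sx, self.sxx, self.sxy = sums

    @staticmethod
    def pearson_from(n: int, sx: float, sxx: float, sxy: float, sy: float, syy: float) -> float:
        den = (n * sxx - sx * sx) * (n * syy - sy * sy)
        if den <= 0.0:
            return 0.0
        return float(min(1.0, max(-1.0, (n * sxy - sx * sy) / math.sqrt(den))))


def _postings(
    profiles: list[AttributeProfile], attr_index: Mapping[str, int], use_bond: bool
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per attribute: (molecule indices, per-molecule occurrence counts)."""
    buckets: list[tuple[list[int], list[float]]] = [([], []) for _ in attr_index]
    for j, prof in enumerate(profiles):
        for key, cnt in prof.local.items():
            a = attr_index.get(key)
            if a is not None:
                buckets[a][0].append(j)
                buckets[a][1].append(float(cnt))
        for key in prof.globals_:
            if not use_bond and key.startswith("BOND:"):
                continue
            a = attr_index.get(key)
            if a is not None:
                buckets[a][0].append(j)
                buckets[a][1].append(1.0)
    return [
        (np.asarray(ix, dtype=np.intp), np.asarray(ct, dtype=float))
        for ix, ct in buckets
    ]


def _subset(dataset: Dataset, profiles: Mapping[str, AttributeProfile], label: str):
    comps = [c for c in dataset.compounds if c.set_label == label]
    y = np.array([c.endpoint for c in comps], dtype=float)
    profs = [profiles[c.id] for c in comps]
    return y, profs


def optimize(
    dataset: Dataset,
    profiles: Mapping[str, AttributeProfile],
    config: OptimizerConfig,
) -> tuple[CorrelationWeightTable, list[float]]:
    """Greedy stochastic ascent of TFm over the active correlation weights.

    Returns the optimized weight table and the trajectory of accepted TFm
    values (non-decreasing by construction, starting at the initial state).
    """
    y_tr, prof_tr = _subset(dataset, profiles, TRAIN)
    y_it, prof_it = _subset(dataset, profiles, INVISIBLE_TRAIN)
    y_cal, prof_cal = _subset(dataset, profiles, CALIBRATION)
    if y_tr.size == 0 or y_it.size == 0 or y_cal.size == 0:
        raise ValueError("training, invisible-training and calibration sets must be non-empty")

    counts = attribute_counts(prof_tr, use_bond=config.use_bond)
    active = sorted(k for k, c in counts.items() if c >= config.T)
    rare = frozenset(k for k, c in counts.items() if c < config.T)
    if not active:
        raise ValueError(f"no active attributes at T={config.T}")
    attr_index = {k: a for a, k in enumerate(active)}

    posts = {
        "tr": _postings(prof_tr, attr_index, config.use_bond),
        "it": _postings(prof_it, attr_index, config.use_bond),
        "cal": _postings(prof_cal, attr_index, config.use_bond),
    }
    states = {"tr": _SetState(y_tr), "it": _SetState(y_it), "cal": _SetState(y_cal)}

    rng = np.random.default_rng(config.seed)
    cw = rng.uniform(config.init_low, config.init_high, size=len(active))

    # initial DCW vectors
    for name, profs in (("tr", prof_tr), ("it", prof_it), ("cal", prof_cal)):
        dcw = np.zeros(len(profs))
        for a, (idx, cnt) in enumerate(posts[name]):
            if idx.size:
                np.add.at(dcw, idx, cw[a] * cnt)
        states[name].reset_dcw(dcw)

    def _delta_vec(name: str, moves: tuple[tuple[int, float], ...]) -> np.ndarray:
        vec = np.zeros(states[name].n)
        for a, delta in moves:
            idx, cnt = posts[name][a]
            if idx.size:
                vec[idx] += delta * cnt
        return vec

    def evaluate(moves: tuple[tuple[int, float], ...]):
        """TFm (and per-set training sums) with the given (attr, delta) shifts."""
        sums = {}
        for name in ("tr", "it"):
            st = states[name]
            if moves:
                t = _delta_vec(name, moves)
                sums[name] = (
                    st.sx + float(t.sum()),
                    st.sxx + float(np.dot(2.0 * st.dcw + t, t)),
                    st.sxy + float(np.dot(t, st.y)),
                )
            else:
                sums[name] = (st.sx, st.sxx, st.sxy)
        st = states["tr"]
        sx, sxx, sxy = sums["tr"]
        r_tr = _SetState.pearson_from(st.n, sx, sxx, sxy, st.sy, st.syy)
        sti = states["it"]
        r_it = _SetState.pearson_from(sti.n, *sums["it"], sti.sy, sti.syy)
        # refit c0, c1 on training from the same sums
        var = st.n * sxx - sx * sx
        if var <= 0.0:
            c1, c0 = 0.0, st.sy / st.n
        else:
            c1 = (st.n * sxy - sx * st.sy) / var
            c0 = (st.sy - c1 * sx) / st.n
        stc = states["cal"]
        dcw_cal = stc.dcw + _delta_vec("cal", moves) if moves else stc.dcw
        iic_cal = iic(stc.y, c0 + c1 * dcw_cal)
        return target_function(r_tr, r_it, iic_cal, config), sums

    state0, _ = evaluate(())
    tfm = state0.TFm
    trajectory = [tfm]
    accepted = 0

    def commit(moves: tuple[tuple[int, float], ...], sums) -> None:
        for name in ("tr", "it", "cal"):
            st = states[name]
            st.dcw = st.dcw + _delta_vec(name, moves)
            if name in sums:
                st.sx, st.sxx, st.sxy = sums[name]
            else:
                st.sx = float(st.dcw.sum())
                st.sxx = float(np.dot(st.dcw, st.dcw))
                st.sxy = float(np.dot(st.dcw, st.y))
        for a, delta in moves:
            cw[a] += delta

    n_active = len(active)
    for _epoch in range(config.n_epochs):
        # phase 1: coordinate sweep with multi-scale probing — the target's
        # min/max ratio term has kinks that single-scale moves cannot follow
        for a in rng.permutation(n_active):
            a = int(a)
            base = rng.uniform(-config.step, config.step)
            move = None
            for scale in (1.0, -1.0, 0.25, -0.25, 0.0625, -0.0625):
                probe = ((a, base * scale),)
                cand, sums = evaluate(probe)
                if cand.TFm > tfm:
                    move = probe
                    break
            if move is None:
                continue
            commit(move, sums)
            tfm = cand.TFm
            accepted += 1
            # ride the accepted direction while it keeps improving
            for _ in range(_MAX_RIDE):
                cand, sums = evaluate(move)
                if cand.TFm <= tfm:
                    break
                commit(move, sums)
                tfm = cand.TFm
                accepted += 1
            trajectory.append(tfm)
        # phase 2: paired moves, which can walk along ridges where every
        # single-coordinate direction is downhill
        if n_active >= 2:
            for _ in range(_PAIR_FACTOR * n_active):
                a, b = rng.choice(n_active, size=2, replace=False)
                probe = (
                    (int(a), rng.uniform(-config.step, config.step)),
                    (int(b), rng.uniform(-config.step, config.step)),
                )
                cand, sums = evaluate(probe)
                if cand.TFm <= tfm:
                    continue
                commit(probe, sums)
                tfm = cand.TFm
                accepted += 1
                for _ in range(_MAX_RIDE):
                    cand, sums = evaluate(probe)
                    if cand.TFm <= tfm:
                        break
                    commit(probe, sums)
                    tfm = cand.TFm
                    accepted += 1
                trajectory.append(tfm)

    logger.info(
        "optimize: %d active attributes, %d epochs, %d accepted moves, TFm %.4f -> %.4f",
        len(active), config.n_epochs, accepted, trajectory[0], tfm,
    )
    weights = {key: float(cw[attr_index[key]]) for key in active}
    weights.update({key: 0.0 for key in rare})
    return CorrelationWeightTable(weights=weights, rare_keys=rare, T=config.T), trajectory


def build_model(
    dataset: Dataset,
    profiles: Mapping[str, AttributeProfile],
    table: CorrelationWeightTable,
    config: OptimizerConfig,
    seed: int | None = None,
) -> QsarModel:
    """Fit the univariate endpoint model on the training set."""
    comps = [c for c in dataset.compounds if c.set_label == TRAIN]
    dcw = np.array(
        [compute_dcw(profiles[c.id], table, use_bond=config.use_bond) for c in comps]
    )
    y = np.array([c.endpoint for c in comps])
    c0, c1 = fit_univariate(dcw, y)
    return QsarModel(
        cw_table=table,
        T_star=config.T,
        N_star=config.n_epochs,
        c0=c0,
        c1=c1,
        probe_seed=config.seed if seed is None else seed,
        use_bond=config.use_bond,
    )


def run_probes(
    dataset: Dataset,
    profiles: Mapping[str, AttributeProfile],
    config: OptimizerConfig,
) -> list[QsarModel]:
    """Independent optimization probes; probe i uses seed = base seed + i."""
    if config.n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    models = []
    for i in range(config.n_probes):
        probe_cfg = replace(config, seed=config.seed + i)
        table, _ = optimize(dataset, profiles, probe_cfg)
        models.append(build_model(dataset, profiles, table, probe_cfg))
    return models


def grid_search_TN(
    dataset: Dataset,
    profiles: Mapping[str, AttributeProfile],
    T_values: Sequence[int] = (1, 2, 3, 4, 5),
    N_values: Sequence[int] = (5, 10, 15, 20, 30),
    config: OptimizerConfig = OptimizerConfig(),
) -> tuple[int, int]:
    """Pick (T*, N*) maximizing calibration-set R² of the fitted model.

    Candidates are scanned in increasing (T, N) order and a candidate must
    strictly beat the incumbent, so ties go to smaller T, then smaller N.
    """
    if not T_values or not N_values:
        raise ValueError("T and N candidate ranges must be non-empty")
    cal = [c for c in dataset.compounds if c.set_label == CALIBRATION]
    y_cal = np.array([c.endpoint for c in cal])
    best: tuple[int, int] | None = None
    best_r2 = -np.inf
    for T in sorted(set(T_values)):
        for N in sorted(set(N_values)):
            cfg = replace(config, T=int(T), n_epochs=int(N))
            table, _ = optimize(dataset, profiles, cfg)
            model = build_model(dataset, profiles, table, cfg)
            pred = np.array([model.predict_one(profiles[c.id]) for c in cal])
            r2 = _pearson(y_cal, pred) ** 2
            if r2 > best_r2:
                best_r2 = r2
                best = (int(T), int(N))
    assert best is not None
    return best
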