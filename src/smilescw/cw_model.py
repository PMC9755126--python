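"""Correlation-weight table, the DCW descriptor and the univariate model.

Every SMILES attribute carries a numeric correlation weight CW. The
descriptor of correlation weights of a molecule is

    DCW = Σ_occurrences CW(local triple) + Σ CW(global key),

local triples counted per occurrence, each global key once. Attributes
seen fewer than T times in the training set are *rare*: their CW is fixed
at 0 and they never enter the optimization. The endpoint model is the
one-variable least-squares fit

    pIC50 = c0 + c1 · DCW(T*, N*),

with T* the rarity threshold and N* the number of Monte Carlo epochs used
to produce the weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .smiles_attributes import AttributeProfile

__all__ = [
    "DegenerateFitError",
    "CorrelationWeightTable",
    "QsarModel",
    "classify_rare",
    "attribute_counts",
    "compute_dcw",
    "fit_univariate",
    "predict",
    "save_model",
    "load_model",
]


class DegenerateFitError(ValueError):
    """Raised when the univariate fit is undefined (zero descriptor variance)."""


def attribute_counts(
    profiles: Iterable[AttributeProfile], *, use_bond: bool = True
) -> dict[str, int]:
    """Number of molecules containing each attribute at least once."""
    counts: dict[str, int] = {}
    for prof in profiles:
        for key in prof.all_keys():
            if not use_bond and key.startswith("BOND:"):
                continue
            counts[key] = counts.get(key, 0) + 1
    return counts


def classify_rare(
    training_profiles: Iterable[AttributeProfile], T: int, *, use_bond: bool = True
) -> set[str]:
    """Attributes occurring in fewer than T training molecules are rare."""
    profiles = list(training_profiles)
    if not profiles:
        raise ValueError("training profile list is empty")
    if T < 1:
        raise ValueError(f"threshold T must be >= 1, got {T}")
    counts = attribute_counts(profiles, use_bond=use_bond)
    return {key for key, cnt in counts.items() if cnt < T}


@dataclass
class CorrelationWeightTable:
    """Attribute key → CW mapping; rare keys are pinned at zero."""

    weights: dict[str, float]
    rare_keys: frozenset[str] = frozenset()
    T: int = 1

    def __post_init__(self) -> None:
        for key in self.rare_keys:
            if self.weights.get(key, 0.0) != 0.0:
                raise ValueError(f"rare key {key!r} must have CW = 0")

    def cw(self, key: str) -> float:
        if key in self.rare_keys:
            return 0.0
        return self.weights.get(key, 0.0)


def compute_dcw(
    profile: AttributeProfile,
    table: CorrelationWeightTable,
    *,
    use_bond: bool = True,
) -> float:
    """DCW of one molecule: per-occurrence local sum + one term per global.

    Keys absent from the table (e.g. attributes appearing only outside the
    training set) contribute 0.
    """
    total = 0.0
    for key, count in profile.local.items():
        total += count * table.cw(key)
    for key in profile.globals_:
        if not use_bond and key.startswith("BOND:"):
            continue
        total += table.cw(key)
    return total


def fit_univariate(dcw: np.ndarray, endpoints: np.ndarray) -> tuple[float, float]:
    """Ordinary least squares of endpoint on DCW → (intercept, slope)."""
    x = np.asarray(dcw, dtype=float)
    y = np.asarray(endpoints, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("dcw and endpoints must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points to fit")
    xm = x.mean()
    sxx = float(np.sum((x - xm) ** 2))
    if sxx <= 0.0:
        raise DegenerateFitError("zero variance in DCW values; fit is undefined")
    ym = y.mean()
    c1 = float(np.sum((x - xm) * (y - ym)) / sxx)
    c0 = float(ym - c1 * xm)
    return c0, c1


@dataclass
class QsarModel:
    """A calibrated one-variable correlation-weight model."""

    cw_table: CorrelationWeightTable
    T_star: int
    N_star: int
    c0: float
    c1: float
    probe_seed: int = 0
    use_bond: bool = True

    def __post_init__(self) -> None:
        if not np.isfinite(self.c1):
            raise ValueError("slope c1 must be finite")
        if self.T_star < 1 or self.N_star < 1:
            raise ValueError("T_star and N_star must be >= 1")

    def dcw(self, profile: AttributeProfile) -> float:
        return compute_dcw(profile, self.cw_table, use_bond=self.use_bond)

    def predict_one(self, profile: AttributeProfile) -> float:
        return self.c0 + self.c1 * self.dcw(profile)


def predict(model: QsarModel, profile: AttributeProfile) -> float:
    """Endpoint prediction c0 + c1 · DCW for one molecule."""
    return model.predict_one(profile)


def save_model(model: QsarModel, prefix: str | Path) -> tuple[Path, Path]:
    """Serialize a model as ``<prefix>.json`` + ``<prefix>.weights.tsv``.

    The weight table is a flat, sorted key→CW TSV so models diff cleanly
    and reload bit-exactly (weights stored via ``float.hex``).
    """
    prefix = Path(prefix)
    meta = {
        "T": model.T_star,
        "N": model.N_star,
        "c0": model.c0,
        "c1": model.c1,
        "seed": model.probe_seed,
        "use_bond": model.use_bond,
        "rare_keys": sorted(model.cw_table.rare_keys),
    }
    json_path = prefix.with_suffix(".json")
    tsv_path = prefix.parent / (prefix.name + ".weights.tsv")
    json_path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    with open(tsv_path, "w") as fh:
        fh.write("key\tcw\tcw_hex\n")
        for key in sorted(model.cw_table.weights):
            w = model.cw_table.weights[key]
            fh.write(f"{key}\t{w!r}\t{float(w).hex()}\n")
    return json_path, tsv_path


def load_model(prefix: str | Path) -> QsarModel:
    """Reload a model saved by :func:`save_model`."""
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    weights: dict[str, float] = {}
    tsv_path = prefix.parent / (prefix.name + ".weights.tsv")
    with open(tsv_path) as fh:
        next(fh)  # header
        for line in fh:
            key, _repr, hexval = line.rstrip("\n").split("\t")
            weights[key] = float.fromhex(hexval)
    table = CorrelationWeightTable(
        weights=weights, rare_keys=frozenset(meta["rare_keys"]), T=meta["T"]
    )
    return QsarModel(
        cw_table=table,
        T_star=meta["T"],
        N_star=meta["N"],
        c0=meta["c0"],
        c1=meta["c1"],
        probe_seed=meta["seed"],
        use_bond=meta["use_bond"],
    )
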