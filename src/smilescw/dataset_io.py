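"""Reading/writing compound tables and four-set split generation.

A dataset is a table of (id, SMILES, endpoint) rows, the endpoint being a
pIC50 value (−log10 IC50 in mol/L, stored as-is: higher = more potent).
Model development uses four disjoint subsets — training, invisible
training, calibration and validation — assigned here by a seeded random
permutation with largest-remainder rounding of the requested proportions.
A split column already present in the input file always takes precedence
over generated assignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TRAIN",
    "INVISIBLE_TRAIN",
    "CALIBRATION",
    "VALIDATION",
    "SET_LABELS",
    "DatasetError",
    "Compound",
    "Dataset",
    "SplitAssignment",
    "read_dataset",
    "make_split",
    "apply_split",
    "write_predictions",
]

TRAIN = "TRAIN"
INVISIBLE_TRAIN = "INVISIBLE_TRAIN"
CALIBRATION = "CALIBRATION"
VALIDATION = "VALIDATION"
SET_LABELS = (TRAIN, INVISIBLE_TRAIN, CALIBRATION, VALIDATION)

_LABEL_ALIASES = {
    "TRAIN": TRAIN,
    "TRAINING": TRAIN,
    "T": TRAIN,
    "TRN": TRAIN,
    "INVISIBLE_TRAIN": INVISIBLE_TRAIN,
    "INVISIBLE_TRAINING": INVISIBLE_TRAIN,
    "INVISIBLE TRAINING": INVISIBLE_TRAIN,
    "INVTRAIN": INVISIBLE_TRAIN,
    "INV_TRAIN": INVISIBLE_TRAIN,
    "IT": INVISIBLE_TRAIN,
    "ITRN": INVISIBLE_TRAIN,
    "CALIBRATION": CALIBRATION,
    "CAL": CALIBRATION,
    "CLB": CALIBRATION,
    "C": CALIBRATION,
    "VALIDATION": VALIDATION,
    "VALID": VALIDATION,
    "VAL": VALIDATION,
    "TEST": VALIDATION,
    "V": VALIDATION,
}


class DatasetError(ValueError):
    """Raised on malformed compound tables or split configuration."""


def normalize_label(raw: str) -> str:
    key = str(raw).strip().upper().replace("-", "_")
    try:
        return _LABEL_ALIASES[key]
    except KeyError:
        raise DatasetError(f"unrecognized set label {raw!r}") from None


@dataclass(frozen=True)
class Compound:
    id: str
    smiles: str
    endpoint: float
    set_label: str | None = None

    def __post_init__(self) -> None:
        if not self.smiles:
            raise DatasetError(f"compound {self.id!r}: empty SMILES")
        if not np.isfinite(self.endpoint):
            raise DatasetError(f"compound {self.id!r}: non-finite endpoint")


@dataclass
class Dataset:
    compounds: list[Compound]
    name: str = "dataset"

    def __post_init__(self) -> None:
        if not self.compounds:
            raise DatasetError("dataset must contain at least one compound")
        ids = [c.id for c in self.compounds]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise DatasetError(f"duplicate compound id {dup!r}")

    def __len__(self) -> int:
        return len(self.compounds)

    def ids(self) -> list[str]:
        return [c.id for c in self.compounds]

    def endpoints(self) -> np.ndarray:
        return np.array([c.endpoint for c in self.compounds], dtype=float)

    def subset_ids(self, label: str) -> list[str]:
        return [c.id for c in self.compounds if c.set_label == label]

    def has_labels(self) -> bool:
        return all(c.set_label is not None for c in self.compounds)


@dataclass(frozen=True)
class SplitAssignment:
    """id → set label mapping produced by one seeded random split."""

    labels: Mapping[str, str]
    seed: int
    proportions: tuple[float, float, float, float]

    def sizes(self) -> dict[str, int]:
        out = {lab: 0 for lab in SET_LABELS}
        for lab in self.labels.values():
            out[lab] += 1
        return out


def read_dataset(
    path: str | Path,
    *,
    smiles_col: str = "smiles",
    endpoint_col: str = "endpoint",
    id_col: str | None = "id",
    set_col: str | None = "set",
    sep: str | None = None,
    name: str | None = None,
) -> Dataset:
    """Read a delimited compound table.

    The delimiter defaults to tab for ``.tsv`` paths and comma otherwise.
    ``id_col`` and ``set_col`` are used when present; missing ids are
    synthesized as the 1-based row number.
    """
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"no such file: {path}")
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in (smiles_col, endpoint_col):
        if col not in df.columns:
            raise DatasetError(f"missing required column {col!r} in {path}")
    has_id = id_col is not None and id_col in df.columns
    has_set = set_col is not None and set_col in df.columns
    compounds = []
    for row_idx, row in enumerate(df.itertuples(index=False), start=1):
        rec = dict(zip(df.columns, row))
        raw_endpoint = rec[endpoint_col]
        try:
            endpoint = float(raw_endpoint)
        except (TypeError, ValueError):
            raise DatasetError(
                f"row {row_idx}: unparseable endpoint {raw_endpoint!r}"
            ) from None
        if not np.isfinite(endpoint):
            raise DatasetError(f"row {row_idx}: non-finite endpoint {raw_endpoint!r}")
        cid = str(rec[id_col]) if has_id else str(row_idx)
        label = None
        if has_set and isinstance(rec[set_col], str) and rec[set_col].strip():
            label = normalize_label(rec[set_col])
        compounds.append(
            Compound(id=cid, smiles=str(rec[smiles_col]), endpoint=endpoint, set_label=label)
        )
    return Dataset(compounds=compounds, name=name or path.stem)


def _largest_remainder_sizes(n: int, proportions: Sequence[float]) -> list[int]:
    raw = [p * n for p in proportions]
    sizes = [int(np.floor(r)) for r in raw]
    remainder = n - sum(sizes)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - sizes[i]), i))
    for i in order[:remainder]:
        sizes[i] += 1
    return sizes


def make_split(
    dataset: Dataset,
    proportions: Sequence[float] = (0.34, 0.35, 0.15, 0.16),
    seed: int = 0,
) -> SplitAssignment:
    """Randomly assign every compound to one of the four sets.

    Set sizes come from largest-remainder rounding of proportion×n and the
    assignment is a seeded permutation, so equal seeds give identical
    splits.
    """
    props = tuple(float(p) for p in proportions)
    if len(props) != 4:
        raise DatasetError("exactly four proportions are required")
    if any(p < 0 for p in props) or abs(sum(props) - 1.0) > 1e-9:
        raise DatasetError(f"proportions must be non-negative and sum to 1, got {props}")
    n = len(dataset)
    if n < 4:
        raise DatasetError("dataset must contain at least 4 compounds to split")
    sizes = _largest_remainder_sizes(n, props)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    ids = dataset.ids()
    labels: dict[str, str] = {}
    pos = 0
    for label, size in zip(SET_LABELS, sizes):
        for k in order[pos : pos + size]:
            labels[ids[k]] = label
        pos += size
    return SplitAssignment(labels=labels, seed=seed, proportions=props)


def apply_split(dataset: Dataset, split: SplitAssignment) -> Dataset:
    """Return a new dataset whose compounds carry the split's labels."""
    compounds = [
        Compound(c.id, c.smiles, c.endpoint, split.labels[c.id])
        for c in dataset.compounds
    ]
    return Dataset(compounds=compounds, name=dataset.name)


def write_predictions(
    dataset: Dataset,
    predicted: Mapping[str, float],
    in_ad: Mapping[str, bool],
    path: str | Path,
) -> Path:
    """Write the per-compound prediction table (CSV).

    Columns: id, smiles, set, observed, predicted, in_AD — one row per
    compound, mirroring the usual supplementary layout of these models.
    """
    missing = [c.id for c in dataset.compounds if c.id not in predicted]
    if missing:
        raise DatasetError(f"missing predictions for ids: {missing[:5]}")
    rows = [
        {
            "id": c.id,
            "smiles": c.smiles,
            "set": c.set_label or "",
            "observed": c.endpoint,
            "predicted": predicted[c.id],
            "in_AD": bool(in_ad.get(c.id, True)),
        }
        for c in dataset.compounds
    ]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")
    return path
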