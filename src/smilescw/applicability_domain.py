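"""Applicability domain by statistical defect of SMILES attributes.

Each active attribute gets a *statistical defect* measuring how differently
it is distributed between the training and calibration sets:

    defect(A) = |P_trn(A) − P_cal(A)| / (N_trn(A) + N_cal(A))   if A occurs in training
    defect(A) = 1                                                otherwise

with P the fraction of a set's molecules containing A and N the number of
molecules containing it. A molecule's defect is the sum over its distinct
attributes (active ones by the formula above, plus a full defect of 1 for
every attribute never seen in training), and a prediction is considered
reliable — inside the applicability domain — iff

    defect(molecule) < 2 × mean defect over the training set.

The inequality is strict; as a convention, a zero-defect molecule is
always in-domain even when the training mean is zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .cw_model import attribute_counts
from .dataset_io import CALIBRATION, INVISIBLE_TRAIN, TRAIN, Dataset
from .smiles_attributes import AttributeProfile

__all__ = [
    "DefectTable",
    "attribute_defect",
    "molecule_defect",
    "in_domain",
    "build_defect_table",
    "ad_coverage",
    "write_defect_report",
]


def attribute_defect(n_trn: int, p_trn: float, n_cal: int, p_cal: float) -> float:
    """Statistical defect of one attribute.

    An attribute absent from the training set has defect exactly 1, no
    matter how often it appears elsewhere.
    """
    if n_trn < 0 or n_cal < 0:
        raise ValueError("counts must be >= 0")
    if not (0.0 <= p_trn <= 1.0 and 0.0 <= p_cal <= 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    if n_trn == 0:
        return 1.0
    return abs(p_trn - p_cal) / (n_trn + n_cal)


@dataclass
class DefectTable:
    """Per-attribute and per-molecule defects plus the training mean."""

    attribute_defects: dict[str, float]
    molecule_defects: dict[str, float]
    mean_training_defect: float
    active_keys: frozenset[str]
    counts_trn: dict[str, int]
    counts_cal: dict[str, int]
    n_trn_molecules: int = 0
    n_cal_molecules: int = 0


def molecule_defect(
    profile: AttributeProfile,
    attribute_defects: Mapping[str, float],
    active_keys: frozenset[str],
) -> float:
    """Sum of defects over the molecule's distinct relevant attributes.

    Relevant = active (training occurrence ≥ T) or never seen in training
    (those carry the full defect of 1). Rare-but-seen attributes are not
    part of the model and do not contribute. Multiplicity does not
    multiply a defect: each distinct attribute counts once.
    """
    total = 0.0
    for key in profile.all_keys():
        d = attribute_defects.get(key)
        if d is None:
            total += 1.0  # never seen in training
        elif key in active_keys:
            total += d
    return total


def in_domain(defect: float, mean_training_defect: float) -> bool:
    """Strict inequality defect < 2 × mean training defect; 0 is always in."""
    if defect < 0 or mean_training_defect < 0:
        raise ValueError("defects must be >= 0")
    if defect == 0.0:
        return True
    return defect < 2.0 * mean_training_defect


def build_defect_table(
    dataset: Dataset,
    profiles: Mapping[str, AttributeProfile],
    *,
    T: int = 1,
    use_bond: bool = True,
    pool_invisible: bool = False,
) -> DefectTable:
    """Defect table from the dataset's training vs calibration attribute spread.

    ``pool_invisible`` merges the invisible-training set into the training
    side of the probability estimates (off by default).
    """
    train_labels = {TRAIN, INVISIBLE_TRAIN} if pool_invisible else {TRAIN}
    prof_trn = [profiles[c.id] for c in dataset.compounds if c.set_label in train_labels]
    prof_cal = [profiles[c.id] for c in dataset.compounds if c.set_label == CALIBRATION]
    if not prof_trn or not prof_cal:
        raise ValueError("training and calibration sets must be non-empty")
    counts_trn = attribute_counts(prof_trn, use_bond=use_bond)
    counts_cal = attribute_counts(prof_cal, use_bond=use_bond)
    n_trn_set, n_cal_set = len(prof_trn), len(prof_cal)
    active = frozenset(k for k, c in counts_trn.items() if c >= T)

    attr_defects: dict[str, float] = {}
    for key, n_trn in counts_trn.items():
        n_cal = counts_cal.get(key, 0)
        attr_defects[key] = attribute_defect(
            n_trn, n_trn / n_trn_set, n_cal, n_cal / n_cal_set
        )

    mol_defects = {
        c.id: molecule_defect(profiles[c.id], attr_defects, active)
        for c in dataset.compounds
    }
    trn_ids = [c.id for c in dataset.compounds if c.set_label in train_labels]
    mean_trn = sum(mol_defects[i] for i in trn_ids) / len(trn_ids)
    return DefectTable(
        attribute_defects=attr_defects,
        molecule_defects=mol_defects,
        mean_training_defect=mean_trn,
        active_keys=active,
        counts_trn=counts_trn,
        counts_cal=counts_cal,
        n_trn_molecules=n_trn_set,
        n_cal_molecules=n_cal_set,
    )


def ad_coverage(dataset: Dataset, table: DefectTable) -> dict[str, float]:
    """Percentage of in-domain compounds, per set and overall."""
    flags = {
        c.id: in_domain(table.molecule_defects[c.id], table.mean_training_defect)
        for c in dataset.compounds
    }
    out: dict[str, float] = {}
    labels = sorted({c.set_label for c in dataset.compounds if c.set_label})
    for label in labels:
        members = [c.id for c in dataset.compounds if c.set_label == label]
        out[label] = 100.0 * sum(flags[i] for i in members) / len(members)
    out["OVERALL"] = 100.0 * sum(flags.values()) / len(flags)
    return out


def write_defect_report(table: DefectTable, path: str | Path) -> Path:
    """TSV of key, N_TRN, N_CAL, P_TRN, P_CAL, defect for every attribute."""
    rows = []
    n_trn_mols = table.n_trn_molecules
    n_cal_mols = table.n_cal_molecules
    for key in sorted(table.attribute_defects):
        n_trn = table.counts_trn.get(key, 0)
        n_cal = table.counts_cal.get(key, 0)
        rows.append(
            {
                "key": key,
                "N_TRN": n_trn,
                "N_CAL": n_cal,
                "P_TRN": n_trn / n_trn_mols if n_trn_mols else 0.0,
                "P_CAL": n_cal / n_cal_mols if n_cal_mols else 0.0,
                "defect": table.attribute_defects[key],
            }
        )
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path
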