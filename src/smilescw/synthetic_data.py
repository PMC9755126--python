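"""Synthetic congeneric SMILES series with a planted attribute→endpoint signal.

Real panels for this kind of model are *derivative series*: hundreds of
compounds sharing a backbone and differing by substituents. The generator
emulates exactly that. Each molecule is a backbone of ten positions; at
position k an optional substituent fragment (nitrile, gem-difluoro, ether,
amine, carboxyl, thioether, chloromethyl, vinyl, hydrazine, glycol-like —
all inside the small grammar C,c,N,n,O,o,S,F,Cl,Br,=,#,digits,parentheses)
is attached independently with probability ``branch_prob``. Up to three
aromatic rings are spliced in, an optional terminal halogen is appended
and backbone carbons may be swapped for heteroatoms. Every string is valid
by construction: rings are balanced, branches closed, no chemistry engine
involved.

The endpoint is linear in structure plus Gaussian noise:

    y_i = c0_true + c1_true · (Σ_k w_k · I_k(i) + Σ 0.2·rings) + N(0, noise_sd²),

where I_k indicates fragment k. Each fragment weight is realized as a
correlation weight on the fragment's *marker triple* — the local attribute
most specific to it — so the planted truth lives in exactly the feature
space the model searches. Because one substituent event creates several
perfectly co-occurring triples, only the summed weight of such a
collinearity class is identifiable; :func:`ground_truth` therefore reports,
per planted marker, the class of attributes carrying that fragment's
signal, and recovery is judged on the class aggregate.

Defaults mirror a realistic kinase-inhibition panel: 306 molecules, pIC50
rescaled to span 4.03–9.37, noise 0.4 log units (typical reproducibility of
heterogeneous IC50 assays).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .dataset_io import Compound, Dataset
from .smiles_attributes import build_profile

__all__ = [
    "FRAGMENTS",
    "GeneratorConfig",
    "GroundTruth",
    "generate_smiles",
    "generate_endpoints",
    "ground_truth",
    "generate_dataset",
]

# substituent fragments; mutually distinct token content so each carries
# identifiable marker triples
FRAGMENTS = (
    "C#N",
    "C(F)F",
    "OO",
    "N(C)C",
    "C(=O)O",
    "SC",
    "CCl",
    "C=C",
    "NN",
    "OCC",
)

# planted fragment weights: mixed signs so both promoter directions exist
_PLANT_WEIGHTS = (0.8, -0.5, 0.6, 0.7, -0.4, 0.5, 0.9, -0.3, 0.4, -0.6)
_RING_WEIGHT = 0.2  # per ring, on the Cmax.k global keys


@dataclass(frozen=True)
class GeneratorConfig:
    n_molecules: int = 306
    max_chain: int = 12
    ring_prob: float = 0.5
    branch_prob: float = 0.45
    halo_prob: float = 0.30
    hetero_prob: float = 0.20
    true_weights: Mapping[str, float] | None = None
    c0_true: float = 5.0
    c1_true: float = 1.0
    noise_sd: float = 0.4
    endpoint_range: tuple[float, float] | None = (4.03, 9.37)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_molecules < 4:
            raise ValueError("n_molecules must be >= 4")
        for name in ("ring_prob", "branch_prob", "halo_prob", "hetero_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Planted signal of one generated panel.

    ``weights`` maps each marker attribute (and the ring-count globals) to
    its planted weight; ``classes`` maps each marker to the attributes that
    co-occur with its fragment (|correlation| ≥ 0.95 with the fragment
    indicator) — the identifiable unit for sign-recovery checks.
    """

    weights: dict[str, float]
    classes: dict[str, list[str]]
    indicators: np.ndarray  # molecules × fragments


def _generate(config: GeneratorConfig) -> tuple[list[str], np.ndarray, np.ndarray]:
    rng = np.random.default_rng(config.seed)
    n_sites = min(len(FRAGMENTS), max(4, config.max_chain - 2))
    smiles: list[str] = []
    indicators = np.zeros((config.n_molecules, n_sites))
    n_rings = np.zeros(config.n_molecules, dtype=int)
    for i in range(config.n_molecules):
        parts: list[str] = []
        for k in range(n_sites):
            if rng.random() < config.branch_prob:
                indicators[i, k] = 1.0
                parts.append(f"C({FRAGMENTS[k]})")
            else:
                # plain-carbon filler: heteroatoms enter only through
                # fragments and aza-rings, keeping fragment signals crisp
                parts.append("C")
        rings = sum(rng.random() < config.ring_prob for _ in range(3))
        n_rings[i] = rings
        for lab in range(1, rings + 1):
            aza = rng.random() < config.hetero_prob
            ring = f"c{lab}ccncc{lab}" if aza else f"c{lab}ccccc{lab}"
            parts.insert(int(rng.integers(len(parts) + 1)), ring)
        if rng.random() < config.halo_prob:
            parts.append(str(rng.choice(["F", "Br"])))
        smiles.append("".join(parts))
    return smiles, indicators, n_rings


def generate_smiles(config: GeneratorConfig) -> list[str]:
    """Seeded list of grammar-valid SMILES strings."""
    return _generate(config)[0]


def ground_truth(config: GeneratorConfig) -> GroundTruth:
    """Planted weights and their identifiable attribute classes."""
    smiles, indicators, _ = _generate(config)
    if config.true_weights is not None:
        return GroundTruth(
            weights=dict(config.true_weights),
            classes={k: [k] for k in config.true_weights},
            indicators=indicators,
        )
    profiles = [build_profile(s) for s in smiles]
    keys = sorted({k for p in profiles for k in p.local})
    counts = np.array([[p.local.get(k, 0) for p in profiles] for k in keys], float)
    sd = counts.std(axis=1)
    weights: dict[str, float] = {}
    classes: dict[str, list[str]] = {}
    for k in range(indicators.shape[1]):
        ind = indicators[:, k]
        if ind.std() == 0:
            continue
        ic = ind - ind.mean()
        denom = np.sqrt(np.dot(ic, ic)) * sd * np.sqrt(len(profiles))
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.where(denom > 0, (counts - counts.mean(axis=1, keepdims=True)) @ ic / denom, 0.0)
        members = [keys[j] for j in np.flatnonzero(np.abs(corr) >= 0.95)]
        if not members:
            continue
        # marker: the most fragment-specific attribute
        marker = keys[int(np.argmax(np.abs(corr)))]
        weights[marker] = _PLANT_WEIGHTS[k % len(_PLANT_WEIGHTS)]
        classes[marker] = members
    # ring count contributes through the Cmax.k global keys
    for p in profiles:
        for key in p.globals_:
            if key.startswith("Cmax."):
                weights.setdefault(key, _RING_WEIGHT * int(key.split(".")[1]))
    return GroundTruth(weights=weights, classes=classes, indicators=indicators)


def _signal(smiles: list[str], weights: Mapping[str, float]) -> np.ndarray:
    out = np.zeros(len(smiles))
    for i, s in enumerate(smiles):
        prof = build_profile(s)
        total = 0.0
        for key, cnt in prof.local.items():
            total += cnt * weights.get(key, 0.0)
        for key in prof.globals_:
            total += weights.get(key, 0.0)
        out[i] = total
    return out


def generate_endpoints(
    smiles: list[str],
    config: GeneratorConfig,
    weights: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Planted linear endpoints with Gaussian noise, optionally rescaled.

    When ``endpoint_range`` is set the noisy endpoints are affinely mapped
    so their min and max hit the interval ends exactly; the map is affine,
    so a noise-free panel remains an exact linear function of the planted
    descriptor.
    """
    if weights is None:
        weights = ground_truth(config).weights
    rng = np.random.default_rng(config.seed + 1)
    y = config.c0_true + config.c1_true * _signal(smiles, weights)
    if config.noise_sd > 0:
        y = y + rng.normal(0.0, config.noise_sd, size=len(smiles))
    if config.endpoint_range is not None:
        lo, hi = config.endpoint_range
        span = y.max() - y.min()
        if span > 0:
            y = lo + (y - y.min()) * (hi - lo) / span
        else:
            y = np.full_like(y, 0.5 * (lo + hi))
    return y


def generate_dataset(
    config: GeneratorConfig, name: str = "synthetic"
) -> tuple[Dataset, GroundTruth]:
    """Full synthetic panel: (dataset, planted ground truth)."""
    truth = ground_truth(config)
    smiles = generate_smiles(config)
    y = generate_endpoints(smiles, config, truth.weights)
    compounds = [
        Compound(id=f"M{i+1:04d}", smiles=s, endpoint=float(v))
        for i, (s, v) in enumerate(zip(smiles, y))
    ]
    return Dataset(compounds=compounds, name=name), truth
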