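"""DCW computation, rare-attribute handling and the univariate fit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from smilescw.cw_model import (
    CorrelationWeightTable,
    DegenerateFitError,
    classify_rare,
    compute_dcw,
    fit_univariate,
    load_model,
    predict,
    save_model,
)
from smilescw.monte_carlo import OptimizerConfig, build_model
from smilescw.smiles_attributes import AttributeProfile, build_profile


def _profile(local, globals_=()):
    return AttributeProfile(local=dict(local), globals_=frozenset(globals_))


def test_dcw_is_zero_for_zero_table():
    table = CorrelationWeightTable(weights={"a…b…c…": 0.0}, T=1)
    assert compute_dcw(_profile({"a…b…c…": 5}), table) == 0.0


def test_dcw_counts_local_occurrences_and_globals_once():
    table = CorrelationWeightTable(weights={"x…x…x…": 0.5, "Cmax.2": 1.5}, T=1)
    prof = _profile({"x…x…x…": 2}, {"Cmax.2"})
    assert compute_dcw(prof, table) == pytest.approx(2 * 0.5 + 1.5)


def test_unknown_and_rare_keys_contribute_nothing():
    table = CorrelationWeightTable(
        weights={"x…x…x…": 1.0, "r…r…r…": 0.0}, rare_keys=frozenset({"r…r…r…"}), T=2
    )
    with_extra = _profile({"x…x…x…": 1, "unseen": 7, "r…r…r…": 3})
    without = _profile({"x…x…x…": 1})
    assert compute_dcw(with_extra, table) == compute_dcw(without, table)


@given(
    st.dictionaries(
        st.sampled_from([f"k{i}" for i in range(12)]),
        st.integers(1, 5),
        max_size=8,
    ),
    st.integers(0, 100),
)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_dcw_additivity_matches_bruteforce(local, wseed):
    rng = np.random.default_rng(wseed)
    weights = {f"k{i}": float(w) for i, w in enumerate(rng.normal(size=12))}
    table = CorrelationWeightTable(weights=weights, T=1)
    prof = _profile(local)
    batch = compute_dcw(prof, table)
    # brute force: accumulate one occurrence at a time
    incremental = 0.0
    for key, count in local.items():
        for _ in range(count):
            incremental += weights[key]
    assert batch == pytest.approx(incremental, abs=1e-12)


def test_classify_rare_by_molecule_count():
    profs = [
        _profile({"common": 1}),
        _profile({"common": 3, "scarce": 1}),
        _profile({"common": 2}),
    ]
    assert classify_rare(profs, T=1) == set()
    assert classify_rare(profs, T=2) == {"scarce"}
    assert "common" in classify_rare(profs, T=4)
    with pytest.raises(ValueError):
        classify_rare([], T=1)


def test_fit_univariate_exact_line():
    c0, c1 = fit_univariate(np.array([0.0, 1.0, 2.0]), np.array([1.0, 3.0, 5.0]))
    assert (c0, c1) == pytest.approx((1.0, 2.0))


def test_fit_univariate_hand_ols():
    # x=(1,2,3,4), y=(2,2,4,4): slope = Sxy/Sxx = 4/5, intercept = 3 - 0.8*2.5
    c0, c1 = fit_univariate(np.array([1.0, 2, 3, 4]), np.array([2.0, 2, 4, 4]))
    assert c1 == pytest.approx(0.8)
    assert c0 == pytest.approx(1.0)


def test_fit_univariate_rejects_constant_descriptor():
    with pytest.raises(DegenerateFitError):
        fit_univariate(np.ones(5), np.arange(5.0))


def test_predict_is_affine_in_dcw():
    table = CorrelationWeightTable(weights={"x…x…x…": 2.0}, T=1)
    from smilescw.cw_model import QsarModel

    m = QsarModel(cw_table=table, T_star=1, N_star=15, c0=3.0, c1=0.5)
    assert predict(m, _profile({"x…x…x…": 4})) == pytest.approx(3.0 + 0.5 * 8.0)
    assert predict(m, _profile({})) == pytest.approx(3.0)


def test_noise_free_planted_table_recovers_exactly():
    """With the generator's own weights as CW table, the fit is perfect."""
    from smilescw.dataset_io import apply_split, make_split
    from smilescw.smiles_attributes import profile_dataset
    from smilescw.synthetic_data import GeneratorConfig, generate_dataset
    from smilescw.validation import r2

    ds, truth = generate_dataset(GeneratorConfig(n_molecules=60, noise_sd=0.0, seed=4))
    lab = apply_split(ds, make_split(ds, seed=1))
    profiles = profile_dataset(lab)
    table = CorrelationWeightTable(weights=dict(truth.weights), T=1)
    dcw = np.array([compute_dcw(profiles[c.id], table) for c in lab.compounds])
    y = lab.endpoints()
    c0, c1 = fit_univariate(dcw, y)
    pred = c0 + c1 * dcw
    assert r2(y, pred) == pytest.approx(1.0, abs=1e-9)


def test_model_serialization_roundtrip(tmp_path):
    from smilescw.cw_model import QsarModel

    table = CorrelationWeightTable(
        weights={"a…b…c…": 0.123456789012345, "Cmax.1": -2.5, "zero": 0.0},
        rare_keys=frozenset({"zero"}),
        T=1,
    )
    model = QsarModel(cw_table=table, T_star=1, N_star=15, c0=3.6679, c1=0.2889, probe_seed=7)
    save_model(model, tmp_path / "m")
    back = load_model(tmp_path / "m")
    assert back.cw_table.weights == table.weights  # bit-exact via float.hex
    assert back.cw_table.rare_keys == table.rare_keys
    assert (back.c0, back.c1, back.T_star, back.N_star) == (3.6679, 0.2889, 1, 15)
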