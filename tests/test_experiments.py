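"""Setup builders, configuration enumeration and result serialization."""

import numpy as np
import pandas as pd
import pytest

from spnlearn.experiments import (
    FIG3_CONFIG_D1,
    FIG3_CONFIG_D2,
    InputConfiguration,
    build_clustered_setup,
    build_distributed_setup,
    default_exc_params,
    default_protocol,
    enumerate_clustered_configurations,
    plateau_onset_sizes,
    quadratic_argmax,
    write_results,
)
from spnlearn.task import run_training


def test_enumeration_counts():
    configs = enumerate_clustered_configurations()
    assert len(configs) == 31
    groups = [c.group for c in configs]
    assert groups.count("le3") == 18
    assert groups.count("four") == 13
    # no duplicates; all four features represented in every configuration
    assert len({(c.dendrite1, c.dendrite2) for c in configs}) == 31
    for c in configs:
        assert set(c.dendrite1) | set(c.dendrite2) == {"red", "yellow", "strawberry", "banana"}
        assert c.is_valid()


def test_invalid_configuration_rejected():
    bad = InputConfiguration(("red", "banana"), ("yellow", "strawberry"))
    assert not bad.is_valid()
    with pytest.raises(ValueError):
        build_clustered_setup(bad, calibrate=False)


def test_clustered_setup_counts(calibrated_model):
    m = calibrated_model  # Fig-3-style three-feature configuration
    feats = np.array([s.feature for s in m.exc_synapses])
    clus = np.array([s.cluster if s.cluster is not None else -1 for s in m.exc_synapses])
    assert np.sum(clus == 0) == 15 and np.sum(clus == 1) == 15
    assert np.sum(feats == "unspecific") == 108
    assert len(m.inh_synapses) == 0
    # initial weights within the 0.25 +/- 0.05 band
    assert np.all(m.w >= 0.2 - 1e-12) and np.all(m.w <= 0.3 + 1e-12)


def test_clustered_setup_with_inhibition():
    m = build_clustered_setup(with_inhibition=True, calibrate=False, seed=3)
    feats = np.array([s.feature for s in m.exc_synapses])
    assert np.sum(feats == "unspecific") == 144
    assert len(m.inh_synapses) == 8  # one per feature per host dendrite
    w_inh = np.array([s.w_inh for s in m.inh_synapses])
    assert np.all((w_inh > 0.05e-3) & (w_inh < 0.15e-3))  # 0.1 +/- 0.01 nS


def test_distributed_setup_counts():
    m = build_distributed_setup(with_inhibition=True, calibrate=False, seed=1)
    feats = np.array([s.feature for s in m.exc_synapses])
    assert len(m.exc_synapses) == 200
    for f in ("red", "yellow", "banana", "strawberry", "unspecific"):
        assert np.sum(feats == f) == 40
    assert len(m.inh_synapses) == 60
    assert m.spillover_mode == "branch"
    m2 = build_distributed_setup(with_inhibition=True, calibrate=False, seed=2)
    assert not np.array_equal(m.spine_comp, m2.spine_comp)  # placements differ
    assert len(m2.exc_synapses) == 200                       # counts do not


def test_plasticity_off_leaves_weights_flat(model_weights_guard):
    m = model_weights_guard
    w0 = m.w.copy()
    res = run_training(m, default_protocol(n_stimuli=24),
                       exc_params=default_exc_params(),
                       plasticity_exc=False, plasticity_inh=False, seed=5)
    assert np.array_equal(res.weights, w0)


def test_forced_basal_dopamine_freezes_excitatory_weights(model_weights_guard):
    m = model_weights_guard
    w0 = m.w.copy()
    res = run_training(m, default_protocol(n_stimuli=24),
                       exc_params=default_exc_params(),
                       plasticity_inh=False, seed=5, forced_dopamine=0)
    assert np.array_equal(res.weights, w0)


def test_training_replay_is_deterministic(model_weights_guard):
    m = model_weights_guard
    w0 = m.w.copy()
    r1 = run_training(m, default_protocol(n_stimuli=24),
                      exc_params=default_exc_params(), plasticity_inh=False, seed=9)
    w1 = m.w.copy()
    m.w[:] = w0
    r2 = run_training(m, default_protocol(n_stimuli=24),
                      exc_params=default_exc_params(), plasticity_inh=False, seed=9)
    assert np.array_equal(w1, m.w)
    assert [rec.spiked for rec in r1.records] == [rec.spiked for rec in r2.records]
    assert [rec.dopamine for rec in r1.records] == [rec.dopamine for rec in r2.records]


def test_quadratic_argmax():
    # fit coefficients for -(x-3)^2 + 5
    assert quadratic_argmax(np.array([-1.0, 6.0, -4.0])) == pytest.approx(3.0)
    assert np.isnan(quadratic_argmax(np.array([1.0, 0.0, 0.0])))


def test_plateau_onset_table():
    df = pd.DataFrame({
        "weight": [0.25] * 4 + [0.4] * 4,
        "size": [6, 7, 8, 9, 4, 5, 6, 7],
        "triggered": [False, False, True, True, False, True, True, True],
    })
    onsets = plateau_onset_sizes(df)
    assert onsets == {0.25: 8, 0.4: 5}


def test_write_results_round_trip(tmp_path):
    df = pd.DataFrame({"a": [1, 2], "b": [0.5, 0.25]})
    manifest = write_results({"table": df, "meta": {"x": 1}}, tmp_path,
                             metadata={"seed": 0})
    back = pd.read_csv(tmp_path / "table.csv")
    pd.testing.assert_frame_equal(back, df)
    assert (tmp_path / "manifest.json").exists()
    # the manifest records every plasticity and protocol parameter in use
    import json
    with open(tmp_path / "manifest.json") as fh:
        man = json.load(fh)
    for key in ("eta_ltp", "theta_ltp0", "beta_ltp", "eta_ltd", "theta_ltd",
                "eta_s_ltp", "eta_s_ltd", "beta_mp"):
        assert key in man["parameters"]["excitatory_plasticity"]
    for key in ("beta_inh", "eta_act_active", "w_inh_max", "eta_inh_high",
                "eta_inh_low", "c"):
        assert key in man["parameters"]["inhibitory_plasticity"]
    assert man["parameters"]["protocol"]["inter_stimulus_interval"] == 800.0


def test_placement_table_schema(calibrated_model):
    from spnlearn.experiments import placement_table
    df = placement_table(calibrated_model)
    assert set(df.columns) == {"synapse", "kind", "compartment", "distance_um",
                               "feature", "cluster", "weight"}
    exc = df[df.kind == "excitatory"]
    assert len(exc) == len(calibrated_model.exc_synapses)
    assert (exc.distance_um > 0).all()
    assert exc[exc.feature != "unspecific"].cluster.notna().all()
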