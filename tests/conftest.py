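import numpy as np
import pytest

from rhythmkit import FeatureSpec, GroupTruth, SimulationSpec

ZT = (2.0, 6.0, 10.0, 14.0, 18.0, 22.0)


def make_series(mesor, amplitude, acrophase_h, timepoints=ZT, n_per_tp=2,
                noise_sd=0.0, period_h=24.0, rng=None):
    """(times, values) arrays from the cosinor model, optional Gaussian noise."""
    t = np.repeat(np.asarray(timepoints, dtype=float), n_per_tp)
    y = mesor + amplitude * np.cos(2 * np.pi * (t - acrophase_h) / period_h)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=t.size)
    return t, y


def one_group_spec(mesor, amplitude, acrophase_h, noise_sd, n_per_cell,
                   group="wt", name="f"):
    return SimulationSpec(
        features=(FeatureSpec(name, {group: GroupTruth(mesor, amplitude, acrophase_h)},
                              noise_sd=noise_sd),),
        n_per_cell=n_per_cell,
    )


def two_group_spec(truth_a, truth_b, noise_sd, n_per_cell, name="f"):
    return SimulationSpec(
        features=(FeatureSpec(name, {"a": GroupTruth(*truth_a), "b": GroupTruth(*truth_b)},
                              noise_sd=noise_sd),),
        n_per_cell=n_per_cell,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
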