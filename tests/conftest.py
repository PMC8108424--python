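import numpy as np
import pytest

from ppdbs import features as feat
from ppdbs import preprocess as prep
from ppdbs.simulate import SimConfig, synthesize_session


def quiet_config(**overrides) -> SimConfig:
    """Noise-free, background-free session config for exactness tests."""
    base = dict(
        seed=0,
        noise_sd=0.0,
        beta_amp_per_channel=(0.0, 0.0),
        rest_duration=0.0,
    )
    base.update(overrides)
    return SimConfig(**base)


def run_refractory(cfg: SimConfig) -> dict:
    """Full simulate -> fold -> template -> subtract -> PPR chain."""
    rec, truth = synthesize_session(cfg)
    reref = prep.rereference(rec, "bipolar_rings")
    epochs = prep.extract_epochs(reref, channel=reref.channels[0].label)
    composites = prep.fold_polarity(epochs)
    template = prep.build_template(composites)
    tests = [
        prep.subtract_template(c, template)
        for c in composites
        if c.pulse_role == "test" and c.isi < 20.0
    ]
    profile = feat.ppr_curve(tests, template, component="r1")
    arp = feat.estimate_arp(profile)
    rrp = feat.estimate_rrp(profile)
    return {
        "recording": rec,
        "truth": truth,
        "template": template,
        "composites": composites,
        "tests": tests,
        "profile": profile,
        "arp": arp,
        "rrp": rrp,
    }


def grid_step(isis: np.ndarray, value: float) -> float:
    """Local ISI grid spacing at ``value``."""
    i = int(np.clip(np.searchsorted(isis, value), 1, len(isis) - 1))
    return float(isis[i] - isis[i - 1])


@pytest.fixture(scope="session")
def noisefree_run() -> dict:
    """Shared noise-free pipeline run (no facilitation-driven hastening)."""
    return run_refractory(quiet_config(seed=3, hasten_per_gain=0.0))


@pytest.fixture(scope="session")
def default_snr_run() -> dict:
    """Shared pipeline run at default SNR."""
    return run_refractory(SimConfig(seed=0, rest_duration=0.0))
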