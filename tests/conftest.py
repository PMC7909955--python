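import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mbcs import Connectome, GeneratorConfig, generate

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def _fs(*items):
    return frozenset(items)


@pytest.fixture(scope="session")
def toy_connectome() -> Connectome:
    """Hand-built 9-neuron circuit covering every super-class and motif."""
    neurons = pd.DataFrame([
        # id, super_class, cell_type, subtype, modality, glomerulus, dend, axon
        ("P1", "PN", "uPN_DA1", None, "olfactory", "DA1", _fs(), _fs("CA")),
        ("P2", "PN", "uPN_VP3", None, "thermo_hygro", "VP3", _fs(), _fs("CA")),
        ("P3", "PN", "VPN_ME", None, "visual", "ME1", _fs(), _fs("vACA")),
        ("K1", "KC", "KCgm", None, None, None, _fs("CA"), _fs("g1", "g5")),
        ("K2", "KC", "KCgd", None, None, None, _fs("vACA"), _fs("g1")),
        ("M1", "MBON", "MBON01", None, None, None, _fs("g1"), _fs()),
        ("M2", "MBON", "MBON14", None, None, None, _fs("a3"), _fs()),
        ("D1", "DAN", "PAM01", None, None, None, _fs(), _fs("g1")),
        ("D2", "DAN", "PPL106", None, None, None, _fs(), _fs("a3")),
    ], columns=["neuron_id", "super_class", "cell_type", "subtype", "modality",
                "glomerulus", "compartments_dendrite", "compartments_axon"])
    edges = pd.DataFrame([
        ("P1", "K1", 6, "dendrite"),
        ("P2", "K1", 2, "dendrite"),
        ("P1", "K2", 1, "dendrite"),
        ("P3", "K2", 9, "dendrite"),
        ("K1", "M1", 10, "dendrite"),
        ("K2", "M1", 5, "dendrite"),
        ("K1", "M2", 8, "dendrite"),
        ("M1", "D1", 7, "dendrite"),   # same-compartment feedback (g1)
        ("M1", "D2", 6, "dendrite"),   # cross-compartment feedback onto D2
        ("M2", "D2", 6, "dendrite"),   # same-compartment feedback (a3)
        ("M1", "D1", 3, "axon"),       # axo-axonal synapses, same pair
    ], columns=["pre_id", "post_id", "weight", "post_site_class"])
    return Connectome(neurons.set_index("neuron_id"), edges)


@pytest.fixture(scope="session")
def default_result():
    """One default-condition synthetic connectome, reused across tests."""
    return generate(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def small_null_config():
    """Scaled-down null-settings generator used by calibration checks."""
    return dict(n_glomeruli=12, n_thermo_channels=2, n_visual_channels=2, n_kc=60)
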