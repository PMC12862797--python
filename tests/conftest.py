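import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from hydrashell.trajectory import Frame, Selection, Topology, Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_water_topology(n_waters: int, extra_elements=()):
    """Topology of n complete waters (O,H,H) plus optional extra atoms.

    Extra atoms come first, each as its own 'GLY' protein-like residue is
    not needed here; they are tagged as solvent probes.
    """
    elements = list(extra_elements)
    residue_index = list(range(len(extra_elements)))
    residue_names = ["PRB"] * len(extra_elements)
    groups = []
    for w in range(n_waters):
        base = len(elements)
        elements += ["O", "H", "H"]
        residue_index += [len(residue_names)] * 3
        residue_names.append("HOH")
        groups.append([base, base + 1, base + 2])
    n_res = len(residue_names)
    return Topology(
        elements=np.array(elements, dtype=object),
        residue_index=np.array(residue_index),
        residue_names=residue_names,
        residue_charges=np.zeros(n_res),
        residue_domains=["ion"] * len(extra_elements)
                        + ["solvent"] * n_waters,
        water_groups=np.array(groups, int).reshape(-1, 3),
    )


def water_positions(o, h1, h2):
    return np.vstack([o, h1, h2])


@pytest.fixture
def water_top_factory():
    return make_water_topology
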