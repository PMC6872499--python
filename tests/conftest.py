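import numpy as np
import pytest

from csmorph import GroupConfig, generate_cohort, make_atlas
from csmorph.reconstruction import NeuronRecord, SampleNode


@pytest.fixture(scope="session")
def atlas():
    return make_atlas()


@pytest.fixture(scope="session")
def small_cohort(atlas):
    """10 neurons (6 IT-like, 4 PT-like) with ground truth."""
    groups = [
        GroupConfig(name="IT", n_neurons=6, area="MOs", layer="L2/3",
                    mean_n_ipsi=20.0, p_contra=0.5, mean_n_contra=8.0),
        GroupConfig(name="PT", n_neurons=4, area="MOs", layer="L5",
                    mean_n_ipsi=15.0, sd_xyz=(200.0, 200.0, 200.0), pons_branch=True),
    ]
    return generate_cohort(groups, seed=11, atlas=atlas)


def random_tree(rng: np.random.Generator, n: int = 30) -> NeuronRecord:
    """Random valid forest: soma root, axon/dendrite nodes parented to any earlier node."""
    allen_choices = [672, 985, 549, 0]
    samples = [SampleNode(1, -1, "soma", 767, 4500.0, 1000.0, 3000.0)]
    for i in range(2, n + 2):
        parent = int(rng.integers(1, i))
        cls = "axon" if rng.random() < 0.7 else "dendrite"
        allen = int(rng.choice(allen_choices))
        x, y, z = (float(v) for v in rng.uniform(100, 11000, size=3))
        samples.append(SampleNode(i, parent, cls, allen, x, y, z))
    return NeuronRecord(id_string="RND", doi="", soma=samples[0], samples=samples)


def brute_force_axonal_endpoints(record: NeuronRecord) -> set[int]:
    """O(n^2) scan over all (sample, potential child) pairs."""
    axons = [s for s in record.samples if s.structure_class == "axon"]
    out = set()
    for s in axons:
        if not any(t.parent_id == s.sample_id for t in axons):
            out.add(s.sample_id)
    return out
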