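"""Neuron-type assignment: soma parsing, non-telencephalic fraction, filters."""

import numpy as np
import pytest

from csmorph import (
    ClassifyConfig,
    GroupConfig,
    NeuronType,
    SomaArea,
    SomaLayer,
    classify_neuron,
    generate_cohort,
    make_neuron,
    non_it_axon_fraction,
    run_extract,
    soma_area_layer,
)
from csmorph.atlas import RegionPolicy, ontology_from_records
from csmorph.reconstruction import NeuronRecord, SampleNode
from csmorph.synthetic import CAUDOPUTAMEN, MOS, THALAMUS


def _neuron(samples, nid="T"):
    return NeuronRecord(id_string=nid, doi="", soma=samples[0], samples=samples)


def test_soma_in_secondary_motor_layer5(atlas):
    n = _neuron([SampleNode(1, -1, "soma", 767, 4500, 1000, 3000)])
    assert soma_area_layer(n, atlas.ontology) == (SomaArea.MOS, SomaLayer.L5)


def test_soma_layer_parsed_under_non_motor_ancestor():
    ont = ontology_from_records([
        (997, "root", "", None), (567, "Cerebrum", "", 997),
        (688, "Cerebral cortex", "", 567),
        (400, "Visual area", "", 688),
        (401, "Visual area, layer 2/3", "", 400),
    ])
    n = _neuron([SampleNode(1, -1, "soma", 401, 4500, 1000, 3000)])
    assert soma_area_layer(n, ont) == (SomaArea.OTHER, SomaLayer.L23)


def test_unannotated_soma_warns_not_errors(atlas, caplog):
    n = _neuron([SampleNode(1, -1, "soma", 0, 4500, 1000, 3000)])
    with caplog.at_level("WARNING", logger="csmorph.classify"):
        area, layer = soma_area_layer(n, atlas.ontology)
    assert (area, layer) == (SomaArea.OTHER, SomaLayer.UNKNOWN)
    assert "soma" in caplog.text


def test_layer_6a_not_confused_with_layer_1(atlas):
    n = _neuron([SampleNode(1, -1, "soma", 1021, 4500, 1500, 3000)])  # MOs layer 6a
    assert soma_area_layer(n, atlas.ontology)[1] is SomaLayer.L6A


def test_non_it_fraction_all_telencephalic_is_zero(atlas):
    samples = [SampleNode(1, -1, "soma", 767, 4500, 1000, 3000)]
    samples += [SampleNode(i, i - 1, "axon", CAUDOPUTAMEN, 3000 + i, 3000, 5000) for i in range(2, 12)]
    frac, names = non_it_axon_fraction(_neuron(samples), atlas.policy, atlas.ontology)
    assert frac == 0.0 and names == ()


def test_non_it_fraction_counts_by_construction(atlas):
    """19 telencephalic + 1 thalamic axon sample -> fraction 0.05."""
    samples = [SampleNode(1, -1, "soma", 767, 4500, 1000, 3000)]
    samples += [SampleNode(i, 1, "axon", CAUDOPUTAMEN, 3000, 3000, 5000) for i in range(2, 21)]
    samples.append(SampleNode(21, 1, "axon", THALAMUS, 4500, 4000, 8000))
    frac, names = non_it_axon_fraction(_neuron(samples), atlas.policy, atlas.ontology)
    assert frac == pytest.approx(0.05)
    assert names == ("Thalamus",)


def test_passthrough_and_unannotated_count_only_in_denominator(atlas):
    samples = [
        SampleNode(1, -1, "soma", 767, 4500, 1000, 3000),
        SampleNode(2, 1, "axon", CAUDOPUTAMEN, 3000, 3000, 5000),
        SampleNode(3, 1, "axon", 784, 5500, 4500, 6500),  # corticospinal tract
        SampleNode(4, 1, "axon", 0, 5000, 4500, 6500),    # unannotated
        SampleNode(5, 1, "axon", THALAMUS, 4500, 4000, 8000),
    ]
    frac, _ = non_it_axon_fraction(_neuron(samples), atlas.policy, atlas.ontology)
    assert frac == pytest.approx(1 / 4)


def test_non_it_fraction_requires_axon_samples(atlas):
    with pytest.raises(ValueError, match="no axon"):
        non_it_axon_fraction(_neuron([SampleNode(1, -1, "soma", 767, 1, 1, 1)]),
                             atlas.policy, atlas.ontology)


def test_filter_conjunction_on_constructed_neurons(atlas):
    rng = np.random.default_rng(0)
    pt, _ = make_neuron(GroupConfig(name="g", n_neurons=1, layer="L5", pons_branch=True),
                        atlas, rng)
    assert classify_neuron(pt, atlas.policy, atlas.ontology).neuron_type is NeuronType.PT

    it, _ = make_neuron(GroupConfig(name="g", n_neurons=1, layer="L2/3"), atlas, rng)
    assert classify_neuron(it, atlas.policy, atlas.ontology).neuron_type is NeuronType.IT

    # pons-projecting but non-L5 soma: neither PT nor IT
    odd, _ = make_neuron(GroupConfig(name="g", n_neurons=1, layer="L2/3", pons_branch=True),
                         atlas, rng)
    assert classify_neuron(odd, atlas.policy, atlas.ontology).neuron_type is NeuronType.NOT_CORTICOSTRIATAL

    contam, _ = make_neuron(GroupConfig(name="g", n_neurons=1, layer="L6a", non_it_fraction=0.5),
                            atlas, rng)
    res = classify_neuron(contam, atlas.policy, atlas.ontology)
    assert res.neuron_type is NeuronType.EXCLUDED_NON_IT
    assert res.non_it_fraction > 0.10


def test_threshold_monotonicity(atlas):
    """Raising the exclusion threshold can only move neurons EXCLUDED -> IT."""
    rng = np.random.default_rng(1)
    rec, truth = make_neuron(GroupConfig(name="g", n_neurons=1, non_it_fraction=0.05), atlas, rng)
    f = truth["non_it_fraction"]
    strict = classify_neuron(rec, atlas.policy, atlas.ontology, ClassifyConfig(exclusion_threshold=0.0))
    loose = classify_neuron(rec, atlas.policy, atlas.ontology, ClassifyConfig(exclusion_threshold=f + 0.01))
    assert strict.neuron_type is NeuronType.EXCLUDED_NON_IT
    assert loose.neuron_type is NeuronType.IT


def test_classification_is_sample_order_invariant(atlas):
    rng = np.random.default_rng(2)
    rec, _ = make_neuron(GroupConfig(name="g", n_neurons=1, layer="L5", pons_branch=True,
                                     p_contra=1.0), atlas, rng)
    shuffled = list(rec.samples)
    rng.shuffle(shuffled)
    soma = next(s for s in shuffled if s.structure_class == "soma")
    rec2 = NeuronRecord(id_string=rec.id_string, doi="", soma=soma, samples=shuffled)
    a = classify_neuron(rec, atlas.policy, atlas.ontology)
    b = classify_neuron(rec2, atlas.policy, atlas.ontology)
    assert a == b


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_ground_truth_label_recovery(atlas, seed):
    """Generated cohorts with clean or heavy contamination are labelled perfectly."""
    groups = [
        GroupConfig(name="IT", n_neurons=15, layer="L2/3", p_contra=0.5),
        GroupConfig(name="PT", n_neurons=10, layer="L5", pons_branch=True),
        GroupConfig(name="CT", n_neurons=10, layer="L6a", non_it_fraction=0.5),
    ]
    records, truth = generate_cohort(groups, seed=seed, atlas=atlas)
    table, errors = run_extract(records, policy=atlas.policy, ontology=atlas.ontology)
    assert not errors
    assert list(table["type"]) == list(truth["label"])
    assert list(table["area"]) == list(truth["area"])
    assert list(table["layer"]) == list(truth["layer"])
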