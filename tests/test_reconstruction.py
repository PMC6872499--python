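"""Reading/writing reconstructions and tabular outputs."""

import json
import math

import numpy as np
import pandas as pd
import pytest

from csmorph import (
    GroupConfig,
    make_neuron,
    parse_mouselight_json,
    parse_swc,
    write_metrics_table,
    write_mouselight_json,
    write_swc,
)
from csmorph.reconstruction import (
    METRICS_COLUMNS,
    Manifest,
    NeuronRecord,
    SampleNode,
    SchemaError,
    StructureError,
    read_metrics_table,
    validate_forest,
)


def _minimal_doc(**axon_overrides):
    axon = [
        {"sampleNumber": 2, "parentNumber": 1, "structureIdentifier": 2,
         "allenId": 672, "x": 3000.0, "y": 3000.0, "z": 5000.0},
        {"sampleNumber": 3, "parentNumber": 2, "structureIdentifier": 2,
         "allenId": 672, "x": 3100.0, "y": 3050.0, "z": 5020.0},
    ]
    axon[0].update(axon_overrides)
    return {
        "idString": "AATEST",
        "DOI": "10.0/test",
        "soma": {"sampleNumber": 1, "parentNumber": -1, "allenId": 767,
                 "x": 4500.0, "y": 1000.0, "z": 3000.0},
        "axon": axon,
        "dendrite": [],
    }


def test_minimal_json_soma_plus_axon_chain(tmp_path):
    path = tmp_path / "n.json"
    path.write_text(json.dumps(_minimal_doc()))
    rec = parse_mouselight_json(path)
    assert len(rec.samples) == 3
    assert rec.soma.structure_class == "soma"
    axons = rec.axon_samples()
    assert [s.sample_id for s in axons] == [2, 3]
    assert axons[0].parent_id == rec.soma.sample_id


def test_dangling_parent_is_structure_error(tmp_path):
    path = tmp_path / "n.json"
    path.write_text(json.dumps(_minimal_doc(parentNumber=99)))
    with pytest.raises(StructureError, match="nonexistent parent"):
        parse_mouselight_json(path)


def test_unknown_structure_identifier_rejected(tmp_path):
    path = tmp_path / "n.json"
    path.write_text(json.dumps(_minimal_doc(structureIdentifier=7)))
    with pytest.raises(StructureError, match="structureIdentifier"):
        parse_mouselight_json(path)


def test_missing_field_error_names_the_field(tmp_path):
    doc = _minimal_doc()
    del doc["axon"][0]["allenId"]
    path = tmp_path / "n.json"
    path.write_text(json.dumps(doc))
    with pytest.raises(SchemaError, match="allenId"):
        parse_mouselight_json(path)


def test_cycle_detection():
    s = [
        SampleNode(1, -1, "soma", 767, 0, 0, 0),
        SampleNode(2, 3, "axon", 672, 1, 1, 1),
        SampleNode(3, 2, "axon", 672, 2, 2, 2),
    ]
    with pytest.raises(StructureError, match="cycle"):
        validate_forest(s)


def test_colliding_dendrite_ids_are_remapped(tmp_path):
    doc = _minimal_doc()
    # real exports number dendrites in their own id space starting at 1
    doc["dendrite"] = [
        {"sampleNumber": 2, "parentNumber": -1, "structureIdentifier": 3,
         "allenId": 767, "x": 4510.0, "y": 1010.0, "z": 3010.0},
        {"sampleNumber": 3, "parentNumber": 2, "structureIdentifier": 3,
         "allenId": 767, "x": 4520.0, "y": 1020.0, "z": 3020.0},
    ]
    path = tmp_path / "n.json"
    path.write_text(json.dumps(doc))
    rec = parse_mouselight_json(path)
    assert len(rec.samples) == 5
    assert len({s.sample_id for s in rec.samples}) == 5
    dend = [s for s in rec.samples if s.structure_class == "dendrite"]
    assert dend[1].parent_id == dend[0].sample_id


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_json_round_trip_is_identity(tmp_path, atlas, seed):
    rng = np.random.default_rng(seed)
    group = GroupConfig(name="g", n_neurons=1, p_contra=1.0, pons_branch=True, layer="L5")
    rec, _ = make_neuron(group, atlas, rng, neuron_id=f"SYN{seed}")
    path = write_mouselight_json(rec, tmp_path / "n.json")
    back = parse_mouselight_json(path)
    assert back.id_string == rec.id_string
    # arrays are stored per structure class, so compare order-independently
    key = lambda s: s.sample_id
    assert sorted(back.samples, key=key) == sorted(rec.samples, key=key)


def test_forest_invariant_on_random_synthetic_neurons(atlas):
    rng = np.random.default_rng(42)
    group = GroupConfig(name="g", n_neurons=1, p_contra=0.5, non_it_fraction=0.1)
    for _ in range(100):
        rec, _ = make_neuron(group, atlas, rng)
        validate_forest(rec.samples)  # raises on violation


def test_swc_chain_with_constant_assigner(tmp_path):
    path = tmp_path / "n.swc"
    path.write_text("# hdr\n1 1 0 0 0 1 -1\n2 2 10 0 0 1 1\n3 2 20 0 0 1 2\n")
    rec = parse_swc(path, lambda x, y, z: 672)
    assert len(rec.samples) == 3
    assert {s.allen_id for s in rec.samples} == {672}


def test_swc_bad_type_code_rejected(tmp_path):
    path = tmp_path / "n.swc"
    path.write_text("1 1 0 0 0 1 -1\n2 5 10 0 0 1 1\n")
    with pytest.raises(StructureError, match="type code"):
        parse_swc(path, lambda x, y, z: 0)


def test_swc_malformed_line_reports_line_number(tmp_path):
    path = tmp_path / "n.swc"
    path.write_text("1 1 0 0 0 1 -1\n2 2 10 0\n")
    with pytest.raises(SchemaError, match=":2"):
        parse_swc(path, lambda x, y, z: 0)


def test_cross_format_equivalence_json_vs_swc(tmp_path, atlas):
    """The same neuron via JSON and via SWC + atlas assigner gives identical end-points."""
    from csmorph import extract_endpoint_set

    rng = np.random.default_rng(7)
    group = GroupConfig(name="g", n_neurons=1, p_contra=1.0)
    rec, _ = make_neuron(group, atlas, rng)
    jrec = parse_mouselight_json(write_mouselight_json(rec, tmp_path / "n.json"))
    srec = parse_swc(write_swc(rec, tmp_path / "n.swc"), atlas.assigner(), id_string=rec.id_string)
    es_j = extract_endpoint_set(jrec, atlas.policy)
    es_s = extract_endpoint_set(srec, atlas.policy)
    assert sorted(es_j.ipsi_points) == sorted(es_s.ipsi_points)
    assert sorted(es_j.contra_points) == sorted(es_s.contra_points)


def test_metrics_table_header_only_for_zero_rows(tmp_path):
    path = write_metrics_table([], tmp_path / "m.tsv")
    assert path.read_text().strip() == "\t".join(METRICS_COLUMNS)


def test_metrics_table_round_trip_and_na_encoding(tmp_path):
    rows = [
        {"id": "A", "doi": "", "type": "IT", "area": "MOs", "layer": "L5",
         "n_ipsi": 3, "n_contra": 1, "ln_n_ipsi": math.log(3),
         "sd_x": 10.0, "sd_y": 20.0, "sd_z": 30.0, "sd_dist": 15.0,
         "non_it_fraction": 0.0},
        {"id": "B", "doi": "", "type": "IT", "area": "MOp", "layer": "L1",
         "n_ipsi": 0, "n_contra": 2, "ln_n_ipsi": math.nan,
         "sd_x": math.nan, "sd_y": math.nan, "sd_z": math.nan,
         "sd_dist": math.nan, "non_it_fraction": 0.0},
    ]
    path = write_metrics_table(rows, tmp_path / "m.tsv")
    raw = path.read_text().splitlines()
    assert raw[2].split("\t")[7] == "NA"  # ln_n_ipsi of the zero-ipsi neuron
    back = read_metrics_table(path)
    assert back.loc[0, "sd_x"] == pytest.approx(10.0)
    assert math.isnan(back.loc[1, "ln_n_ipsi"])


def test_manifest_rejects_duplicate_ids():
    with pytest.raises(SchemaError, match="duplicate"):
        Manifest(entries=[("A", "", ""), ("A", "", "")])
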