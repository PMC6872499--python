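"""Neuron-type assignment for corticostriatal neurons.

A neuron with its soma in the cerebral cortex and at least one intra-striatal
axonal end-point is:

* **PT** (pyramidal tract) if its soma is in layer 5 and at least one axon
  sample lies in the pons (descent from the pons root);
* **IT** (intratelencephalic) if no axon sample lies in the pons and the
  fraction of its axon samples in non-telencephalic regions does not exceed
  the exclusion threshold (default 0: any non-telencephalic axon excludes);
* **EXCLUDED_NON_IT** if it would be IT but the non-telencephalic fraction
  exceeds the threshold (corticothalamic and similar extratelencephalic
  cells fall here);
* **NOT_CORTICOSTRIATAL** otherwise (no striatal end-point, soma outside the
  cortex, or a pons-projecting cell whose soma is not in layer 5).

Pass-through structures (tracts, ventricles) and unannotated samples count in
the denominator of the non-telencephalic fraction but never in its numerator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

from .atlas import RegionClass, RegionOntology, RegionPolicy, region_class
from .endpoints import striatal_endpoints
from .reconstruction import NeuronRecord

__all__ = ["NeuronType", "SomaArea", "SomaLayer", "ClassifyConfig",
           "ClassificationResult", "soma_area_layer", "non_it_axon_fraction",
           "classify_neuron"]

logger = logging.getLogger(__name__)


class NeuronType(str, Enum):
    PT = "PT"
    IT = "IT"
    EXCLUDED_NON_IT = "EXCLUDED_NON_IT"
    NOT_CORTICOSTRIATAL = "NOT_CORTICOSTRIATAL"


class SomaArea(str, Enum):
    MOP = "MOp"
    MOS = "MOs"
    OTHER = "other"


class SomaLayer(str, Enum):
    L1 = "L1"
    L23 = "L2/3"
    L5 = "L5"
    L6A = "L6a"
    L6B = "L6b"
    UNKNOWN = "unknown"


#: longest tokens first so "layer 6a" wins over a bare "layer 6" prefix match
DEFAULT_LAYER_TOKENS: tuple[tuple[str, SomaLayer], ...] = (
    ("layer 2/3", SomaLayer.L23),
    ("layer 6a", SomaLayer.L6A),
    ("layer 6b", SomaLayer.L6B),
    ("layer 1", SomaLayer.L1),
    ("layer 5", SomaLayer.L5),
)

DEFAULT_MOTOR_AREAS: Mapping[str, SomaArea] = {
    "Primary motor area": SomaArea.MOP,
    "Secondary motor area": SomaArea.MOS,
}


@dataclass(frozen=True)
class ClassifyConfig:
    exclusion_threshold: float = 0.0
    motor_area_names: Mapping[str, SomaArea] = field(default_factory=lambda: dict(DEFAULT_MOTOR_AREAS))
    layer_tokens: tuple[tuple[str, SomaLayer], ...] = DEFAULT_LAYER_TOKENS


@dataclass(frozen=True)
class ClassificationResult:
    neuron_id: str
    neuron_type: NeuronType
    soma_area: SomaArea
    soma_layer: SomaLayer
    non_it_fraction: float
    non_it_regions: tuple[str, ...] = ()


def soma_area_layer(
    neuron: NeuronRecord,
    ontology: RegionOntology,
    config: ClassifyConfig = ClassifyConfig(),
) -> tuple[SomaArea, SomaLayer]:
    """Resolve cortical area and layer from the soma's annotated structure.

    The area comes from the first self-or-ancestor structure whose name is a
    configured motor-area name; the layer from a "layer ..." token in the
    soma structure's own name. An unannotated soma yields (other, unknown)
    with a logged warning.
    """
    aid = neuron.soma.allen_id
    if aid == 0 or aid not in ontology:
        logger.warning("%s: soma allen id %s not resolvable; area/layer unknown", neuron.id_string, aid)
        return SomaArea.OTHER, SomaLayer.UNKNOWN
    area = SomaArea.OTHER
    for node_id in (aid, *ontology.ancestors(aid)):
        name = ontology.name(node_id)
        if name in config.motor_area_names:
            area = config.motor_area_names[name]
            break
    layer = SomaLayer.UNKNOWN
    soma_name = ontology.name(aid).lower()
    for token, lab in config.layer_tokens:
        if token in soma_name:
            layer = lab
            break
    return area, layer


def non_it_axon_fraction(
    neuron: NeuronRecord, policy: RegionPolicy, ontology: RegionOntology
) -> tuple[float, tuple[str, ...]]:
    """Fraction of axon samples annotated to non-telencephalic structures.

    All axon samples count in the denominator; only samples whose region class
    is non-telencephalic count in the numerator (pass-through and unannotated
    samples never do). Also returns the sorted names of the non-telencephalic
    regions hit.
    """
    axons = neuron.axon_samples()
    if not axons:
        raise ValueError(f"{neuron.id_string}: no axon samples; fraction undefined")
    hits = [s for s in axons if region_class(policy, ontology, s.allen_id) is RegionClass.NON_TELENCEPHALIC]
    names = tuple(sorted({ontology.name(s.allen_id) for s in hits}))
    return len(hits) / len(axons), names


def classify_neuron(
    neuron: NeuronRecord,
    policy: RegionPolicy,
    ontology: RegionOntology,
    config: ClassifyConfig = ClassifyConfig(),
) -> ClassificationResult:
    """Assign PT / IT / EXCLUDED_NON_IT / NOT_CORTICOSTRIATAL to one neuron."""
    area, layer = soma_area_layer(neuron, ontology, config)
    soma_aid = neuron.soma.allen_id
    soma_in_cortex = (
        soma_aid != 0 and soma_aid in ontology
        and ontology.is_descendant(soma_aid, policy.cortex_root_id)
    )
    has_striatal_ep = len(striatal_endpoints(neuron, policy)) >= 1
    axons = neuron.axon_samples()
    has_pons_axon = any(
        region_class(policy, ontology, s.allen_id) is RegionClass.PONS for s in axons
    )
    frac, names = non_it_axon_fraction(neuron, policy, ontology) if axons else (0.0, ())

    if soma_in_cortex and has_striatal_ep and has_pons_axon and layer is SomaLayer.L5:
        ntype = NeuronType.PT
    elif soma_in_cortex and has_striatal_ep and not has_pons_axon:
        ntype = NeuronType.IT if frac <= config.exclusion_threshold else NeuronType.EXCLUDED_NON_IT
    else:
        ntype = NeuronType.NOT_CORTICOSTRIATAL

    return ClassificationResult(
        neuron_id=neuron.id_string,
        neuron_type=ntype,
        soma_area=area,
        soma_layer=layer,
        non_it_fraction=frac,
        non_it_regions=names,
    )
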