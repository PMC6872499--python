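"""Axonal end-point extraction and hemisphere splitting.

An axonal end-point is an axon-class sample that is not the parent of any
other axon-class sample — a leaf of the axonal tree, where leaf status is
judged against axon children only (a sample whose only children are dendritic
still counts as an end-point). Intra-striatal end-points are those whose
allen id lies in the policy's closed striatal set; note a striatal sample
with an axon child outside the striatum is not an end-point.

End-points are split into ipsi- and contra-lateral relative to the soma by
the sign of (x - midline_x): same sign as the soma means ipsilateral.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .atlas import RegionPolicy
from .reconstruction import NeuronRecord, SampleNode

__all__ = ["EndpointSet", "LateralityError", "axonal_endpoints", "striatal_endpoints",
           "split_by_hemisphere", "extract_endpoint_set"]

logger = logging.getLogger(__name__)

Point = tuple[float, float, float]


class LateralityError(ValueError):
    """Soma sits exactly on the midline; laterality is undefined."""


@dataclass
class EndpointSet:
    """Ipsi/contra striatal end-point coordinates for one neuron."""

    neuron_id: str
    soma_side: str  # "left" (x < midline) or "right"
    ipsi_points: list[Point] = field(default_factory=list)
    contra_points: list[Point] = field(default_factory=list)


def axonal_endpoints(neuron: NeuronRecord) -> list[SampleNode]:
    """All axon-class samples that parent no axon-class sample.

    Duplicate coordinates count separately: end-points are samples, not
    unique locations. Output order follows the record's sample order.
    """
    axons = neuron.axon_samples()
    axon_parents = {s.parent_id for s in axons}
    return [s for s in axons if s.sample_id not in axon_parents]


def striatal_endpoints(neuron: NeuronRecord, policy: RegionPolicy) -> list[SampleNode]:
    """Axonal end-points whose allen id is in the closed striatal set."""
    return [s for s in axonal_endpoints(neuron) if s.allen_id in policy.striatal_ids]


def split_by_hemisphere(
    points: Sequence[Point], soma_x: float, midline_x: float
) -> tuple[list[Point], list[Point]]:
    """Partition *points* into (ipsilateral, contralateral) lists.

    A point exactly on the midline is assigned ipsilateral and logged; a soma
    exactly on the midline raises :class:`LateralityError`.
    """
    if soma_x == midline_x:
        raise LateralityError(f"soma x {soma_x} lies exactly on the midline {midline_x}")
    soma_sign = 1.0 if soma_x > midline_x else -1.0
    ipsi: list[Point] = []
    contra: list[Point] = []
    for p in points:
        dx = p[0] - midline_x
        if dx == 0:
            logger.warning("end-point at x=%.6g lies exactly on the midline; assigned ipsilateral", p[0])
            ipsi.append(p)
        elif (1.0 if dx > 0 else -1.0) == soma_sign:
            ipsi.append(p)
        else:
            contra.append(p)
    return ipsi, contra


def extract_endpoint_set(neuron: NeuronRecord, policy: RegionPolicy) -> EndpointSet:
    """Striatal end-points of *neuron*, split by hemisphere against the policy midline."""
    pts = [s.xyz for s in striatal_endpoints(neuron, policy)]
    ipsi, contra = split_by_hemisphere(pts, neuron.soma.x, policy.midline_x)
    side = "right" if neuron.soma.x > policy.midline_x else "left"
    return EndpointSet(neuron_id=neuron.id_string, soma_side=side, ipsi_points=ipsi, contra_points=contra)
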