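"""Allen-style region ontology and the region policy used by the analysis.

The ontology is the Allen structure graph reduced to (id, name, acronym,
parent) records. The policy fixes which structure ids count as striatum
(an explicit, closed id set — not descendant-based), which subtrees count as
pons and telencephalon (descendant-based), which subtrees are treated as
pass-through (fiber tracts, ventricles: neither evidence for nor against an
intratelencephalic projection pattern), and where the medial-lateral midline
sits in CCF micrometres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "RegionNode",
    "RegionOntology",
    "RegionPolicy",
    "RegionClass",
    "OntologyError",
    "LookupError_",
    "load_ontology",
    "ontology_from_records",
    "region_class",
    "DEFAULT_STRIATAL_IDS",
]

# The closed striatal id set: Striatum, Striatum dorsal/ventral region,
# Caudoputamen, Nucleus accumbens, Olfactory tubercle, Fundus of striatum,
# plus the Islands of Calleja and olfactory-tubercle sublayers whose inclusion
# was verified to add no further end-point.
DEFAULT_STRIATAL_IDS = frozenset(
    {477, 485, 493, 672, 56, 754, 998} | {481, 489, 144, 458, 465, 473}
)


class OntologyError(ValueError):
    """Structure-graph file violates the single-rooted-forest contract."""


class LookupError_(KeyError):
    """An allen id is absent from the ontology."""


class RegionClass(str, Enum):
    STRIATAL = "striatal"
    PONS = "pons"
    TELENCEPHALIC = "telencephalic"
    PASSTHROUGH = "passthrough"
    NON_TELENCEPHALIC = "non_telencephalic"
    UNANNOTATED = "unannotated"


@dataclass(frozen=True)
class RegionNode:
    allen_id: int
    name: str
    acronym: str
    parent_id: int | None  # None for the root


class RegionOntology:
    """Validated structure graph with ancestor queries."""

    def __init__(self, nodes: Mapping[int, RegionNode]):
        self.nodes = dict(nodes)
        roots = [n.allen_id for n in self.nodes.values() if n.parent_id is None]
        if len(roots) != 1:
            raise OntologyError(f"ontology must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        for n in self.nodes.values():
            if n.parent_id is not None and n.parent_id not in self.nodes:
                raise OntologyError(f"node {n.allen_id} has dangling parent {n.parent_id}")
        # acyclicity + ancestor cache
        self._ancestors: dict[int, tuple[int, ...]] = {}
        for nid in self.nodes:
            chain: list[int] = []
            cur = self.nodes[nid].parent_id
            while cur is not None:
                if cur in chain or cur == nid:
                    raise OntologyError(f"cycle in parent links at node {nid}")
                chain.append(cur)
                cur = self.nodes[cur].parent_id
            self._ancestors[nid] = tuple(chain)

    def __contains__(self, allen_id: int) -> bool:
        return allen_id in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def name(self, allen_id: int) -> str:
        return self._get(allen_id).name

    def _get(self, allen_id: int) -> RegionNode:
        try:
            return self.nodes[allen_id]
        except KeyError:
            raise LookupError_(f"allen id {allen_id} not in ontology") from None

    def ancestors(self, allen_id: int) -> tuple[int, ...]:
        """Parent chain from immediate parent up to (and including) the root."""
        self._get(allen_id)
        return self._ancestors[allen_id]

    def is_descendant(self, allen_id: int, ancestor: int) -> bool:
        """True iff *ancestor* is on the parent chain of *allen_id*, or equal to it."""
        self._get(ancestor)
        return allen_id == ancestor or ancestor in self.ancestors(allen_id)


def ontology_from_records(records: Iterable[tuple[int, str, str, int | None]]) -> RegionOntology:
    nodes: dict[int, RegionNode] = {}
    for rid, name, acronym, parent in records:
        if rid in nodes:
            raise OntologyError(f"duplicate ontology id {rid}")
        nodes[rid] = RegionNode(int(rid), str(name), str(acronym), None if parent is None else int(parent))
    return RegionOntology(nodes)


def _flatten_allen_graph(node: Mapping, parent: int | None, out: list) -> None:
    out.append((int(node["id"]), node["name"], node.get("acronym", ""), parent))
    for child in node.get("children", []):
        _flatten_allen_graph(child, int(node["id"]), out)


def load_ontology(path: str | Path) -> RegionOntology:
    """Load a structure graph from Allen-style JSON or a flat TSV.

    JSON accepts either the nested Allen structure graph (``msg`` wrapper or a
    root node with ``children``) or a flat list of records with ``id``,
    ``name``, ``acronym`` and ``parent_structure_id``. TSV needs columns
    id, name, acronym, parent_id (empty parent = root).
    """
    path = Path(path)
    records: list[tuple[int, str, str, int | None]] = []
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            doc = json.load(fh)
        if isinstance(doc, Mapping) and "msg" in doc:
            doc = doc["msg"]
        if isinstance(doc, Mapping) and "children" in doc:
            _flatten_allen_graph(doc, None, records)
        else:
            items = doc if isinstance(doc, list) else [doc]
            for it in items:
                if "children" in it:
                    _flatten_allen_graph(it, it.get("parent_structure_id"), records)
                else:
                    parent = it.get("parent_structure_id")
                    records.append(
                        (int(it["id"]), it["name"], it.get("acronym", ""),
                         None if parent in (None, "") else int(parent))
                    )
    else:
        df = pd.read_csv(path, sep="\t", na_values=[""], keep_default_na=False)
        for row in df.itertuples():
            parent = getattr(row, "parent_id")
            parent = None if pd.isna(parent) else int(parent)
            records.append((int(row.id), str(row.name), str(getattr(row, "acronym", "")), parent))
    return ontology_from_records(records)


@dataclass(frozen=True)
class RegionPolicy:
    """Region membership rules for end-point extraction and classification.

    ``striatal_ids`` is an exact id set; pons/telencephalon/pass-through
    membership is by ontology descent from the stated roots. ``midline_x`` is
    the medial-lateral midline in µm (CCF x axis; 5700 by default, with 5500
    an equivalent historical choice for these data).
    """

    striatal_ids: frozenset[int] = DEFAULT_STRIATAL_IDS
    pons_root_id: int = 771
    telencephalon_root_id: int = 567
    cortex_root_id: int = 688
    passthrough_ids: frozenset[int] = frozenset({1009, 73})  # fiber tracts, ventricles
    midline_x: float = 5700.0

    def __post_init__(self) -> None:
        if not self.striatal_ids:
            raise ValueError("striatal_ids must be nonempty")
        if self.midline_x <= 0:
            raise ValueError("midline_x must be positive")
        if self.striatal_ids & self.passthrough_ids:
            raise ValueError("passthrough_ids must be disjoint from striatal_ids")


def region_class(policy: RegionPolicy, ontology: RegionOntology, allen_id: int) -> RegionClass:
    """Classify one allen id into exactly one of six mutually exclusive classes.

    Precedence: striatal (exact set) > pons (descent) > pass-through (member or
    descendant of a pass-through root) > telencephalic (descent) >
    unannotated (id 0) > non-telencephalic (everything else).
    """
    if allen_id < 0:
        raise ValueError(f"allen_id must be non-negative, got {allen_id}")
    if allen_id == 0:
        return RegionClass.UNANNOTATED
    if allen_id not in ontology:
        raise LookupError_(f"allen id {allen_id} not in ontology")
    if allen_id in policy.striatal_ids:
        return RegionClass.STRIATAL
    if policy.pons_root_id in ontology and ontology.is_descendant(allen_id, policy.pons_root_id):
        return RegionClass.PONS
    for pid in policy.passthrough_ids:
        if pid in ontology and ontology.is_descendant(allen_id, pid):
            return RegionClass.PASSTHROUGH
    if policy.telencephalon_root_id in ontology and ontology.is_descendant(
        allen_id, policy.telencephalon_root_id
    ):
        return RegionClass.TELENCEPHALIC
    return RegionClass.NON_TELENCEPHALIC
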