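"""Reading and writing single-neuron reconstructions and tabular outputs.

Two on-disk morphology representations are supported:

* the MouseLight Neuron Browser JSON dialect — a ``soma`` block plus ``axon``
  and ``dendrite`` sample arrays, each sample carrying ``sampleNumber``,
  ``parentNumber``, ``structureIdentifier`` (1 soma, 2 axon, 3 dendrite),
  ``allenId`` and x/y/z coordinates in micrometres (CCF orientation);
* 7-column SWC, with brain-region ids supplied by an external assigner
  (SWC itself carries no atlas annotation).

Both are normalised to :class:`NeuronRecord`: one soma sample plus a merged,
uniquely-numbered sample list whose parent links form a forest.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "SampleNode",
    "NeuronRecord",
    "Manifest",
    "SchemaError",
    "StructureError",
    "parse_mouselight_json",
    "parse_swc",
    "write_mouselight_json",
    "write_swc",
    "write_metrics_table",
    "read_metrics_table",
    "read_manifest",
    "write_manifest",
    "METRICS_COLUMNS",
]

#: fixed column schema for per-neuron result tables
METRICS_COLUMNS = [
    "id", "doi", "type", "area", "layer",
    "n_ipsi", "n_contra", "ln_n_ipsi",
    "sd_x", "sd_y", "sd_z", "sd_dist",
    "non_it_fraction",
]

STRUCTURE_CODES = {1: "soma", 2: "axon", 3: "dendrite"}
STRUCTURE_NAMES = {v: k for k, v in STRUCTURE_CODES.items()}


class SchemaError(ValueError):
    """A required field is missing or has the wrong type."""


class StructureError(ValueError):
    """Sample linkage is inconsistent (cycles, dangling parents, bad codes)."""


@dataclass(frozen=True)
class SampleNode:
    """One reconstruction point with tree linkage and region annotation."""

    sample_id: int
    parent_id: int  # -1 marks a root
    structure_class: str  # "soma" | "axon" | "dendrite"
    allen_id: int  # 0 = unannotated
    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if self.sample_id <= 0:
            raise StructureError(f"sample_id must be positive, got {self.sample_id}")
        if self.structure_class not in STRUCTURE_NAMES:
            raise StructureError(f"unknown structure class {self.structure_class!r}")
        if self.allen_id < 0:
            raise SchemaError(f"allen_id must be non-negative, got {self.allen_id}")
        for axis in ("x", "y", "z"):
            if not math.isfinite(getattr(self, axis)):
                raise SchemaError(f"non-finite {axis} coordinate in sample {self.sample_id}")

    @property
    def xyz(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


@dataclass
class NeuronRecord:
    """A whole reconstructed neuron: soma, sample tree and provenance."""

    id_string: str
    doi: str
    soma: SampleNode
    samples: list[SampleNode]
    source_path: str = ""
    extras: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        validate_forest(self.samples)
        somata = [s for s in self.samples if s.structure_class == "soma"]
        if len(somata) != 1:
            raise StructureError(
                f"{self.id_string or 'neuron'}: expected exactly one soma sample, found {len(somata)}"
            )
        if somata[0] != self.soma:
            raise StructureError(f"{self.id_string}: designated soma is not the soma-class sample")

    def axon_samples(self) -> list[SampleNode]:
        return [s for s in self.samples if s.structure_class == "axon"]


@dataclass
class Manifest:
    """List of (entity id, DOI, expected group label) rows."""

    entries: list[tuple[str, str, str]]

    def __post_init__(self) -> None:
        ids = [e[0] for e in self.entries]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SchemaError(f"duplicate manifest ids: {dupes}")

    def ids(self) -> list[str]:
        return [e[0] for e in self.entries]


def validate_forest(samples: Sequence[SampleNode]) -> None:
    """Check unique ids, resolvable parents and acyclicity of parent links."""
    by_id: dict[int, SampleNode] = {}
    for s in samples:
        if s.sample_id in by_id:
            raise StructureError(f"duplicate sample_id {s.sample_id}")
        by_id[s.sample_id] = s
    for s in samples:
        if s.parent_id != -1 and s.parent_id not in by_id:
            raise StructureError(
                f"sample {s.sample_id} references nonexistent parent {s.parent_id}"
            )
    # walk each parent chain with memoised termination
    ok: set[int] = set()
    for s in samples:
        seen: list[int] = []
        cur = s
        while cur.sample_id not in ok:
            if cur.sample_id in seen:
                raise StructureError(f"cycle in parent links at sample {cur.sample_id}")
            seen.append(cur.sample_id)
            if cur.parent_id == -1:
                break
            cur = by_id[cur.parent_id]
        ok.update(seen)


# ---------------------------------------------------------------------------
# MouseLight JSON dialect
# ---------------------------------------------------------------------------

_SAMPLE_FIELDS = ("sampleNumber", "parentNumber", "structureIdentifier", "allenId", "x", "y", "z")


def _require(mapping: Mapping, key: str, ctx: str):
    if key not in mapping:
        raise SchemaError(f"missing required field {key!r} in {ctx}")
    return mapping[key]


def _decode_sample(raw: Mapping, structure_class: str, ctx: str) -> SampleNode:
    vals = {k: _require(raw, k, ctx) for k in _SAMPLE_FIELDS}
    code = int(vals["structureIdentifier"])
    if code not in STRUCTURE_CODES:
        raise StructureError(f"unknown structureIdentifier {code} in {ctx}")
    # class is taken from the array of origin; per-sample code only validated
    return SampleNode(
        sample_id=int(vals["sampleNumber"]),
        parent_id=int(vals["parentNumber"]),
        structure_class=structure_class,
        allen_id=int(vals["allenId"]),
        x=float(vals["x"]),
        y=float(vals["y"]),
        z=float(vals["z"]),
    )


def parse_mouselight_json(path: str | Path) -> NeuronRecord:
    """Read one neuron from a MouseLight-dialect JSON file.

    The file may hold either a single neuron object or a ``{"neurons": [...]}``
    wrapper (the Neuron Browser export); in the latter case the first neuron is
    taken. Axon and dendrite arrays are merged into one sample list with the
    structure class set by the array of origin. Real exports number axon and
    dendrite samples in separate id spaces; colliding dendrite ids (and their
    parent references) are shifted by a constant offset so that sample ids are
    unique within the record.
    """
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    if isinstance(doc, Mapping) and "neurons" in doc:
        neurons = doc["neurons"]
        if not neurons:
            raise SchemaError(f"empty 'neurons' array in {path}")
        raw = neurons[0]
    elif isinstance(doc, Mapping):
        raw = doc
    else:
        raise SchemaError(f"{path}: top level is not a JSON object")

    ctx = str(path)
    soma_raw = _require(raw, "soma", ctx)
    soma_id = int(soma_raw.get("sampleNumber", 1))
    soma = SampleNode(
        sample_id=soma_id,
        parent_id=int(soma_raw.get("parentNumber", -1)),
        structure_class="soma",
        allen_id=int(_require(soma_raw, "allenId", f"soma of {ctx}")),
        x=float(_require(soma_raw, "x", f"soma of {ctx}")),
        y=float(_require(soma_raw, "y", f"soma of {ctx}")),
        z=float(_require(soma_raw, "z", f"soma of {ctx}")),
    )

    axon = [_decode_sample(s, "axon", f"axon[{i}] of {ctx}") for i, s in enumerate(raw.get("axon", []))]
    dend = [_decode_sample(s, "dendrite", f"dendrite[{i}] of {ctx}") for i, s in enumerate(raw.get("dendrite", []))]

    used = {soma.sample_id} | {s.sample_id for s in axon}
    if used & {s.sample_id for s in dend}:
        offset = max(used)
        remapped = []
        for s in dend:
            parent = s.parent_id if s.parent_id in (-1, soma.sample_id) else s.parent_id + offset
            remapped.append(replace(s, sample_id=s.sample_id + offset, parent_id=parent))
        dend = remapped

    samples = [soma] + axon + dend
    extras = {k: v for k, v in raw.items() if k not in ("soma", "axon", "dendrite", "idString", "DOI")}
    return NeuronRecord(
        id_string=str(raw.get("idString", path.stem)),
        doi=str(raw.get("DOI", "")),
        soma=soma,
        samples=samples,
        source_path=str(path),
        extras=extras,
    )


def write_mouselight_json(record: NeuronRecord, path: str | Path) -> Path:
    """Write a record back to the MouseLight dialect (lossless round trip)."""
    path = Path(path)

    def enc(s: SampleNode) -> dict:
        return {
            "sampleNumber": s.sample_id,
            "parentNumber": s.parent_id,
            "structureIdentifier": STRUCTURE_NAMES[s.structure_class],
            "allenId": s.allen_id,
            "x": s.x, "y": s.y, "z": s.z,
        }

    doc = {
        "neurons": [
            {
                "idString": record.id_string,
                "DOI": record.doi,
                "soma": enc(record.soma),
                "axon": [enc(s) for s in record.samples if s.structure_class == "axon"],
                "dendrite": [enc(s) for s in record.samples if s.structure_class == "dendrite"],
                **dict(record.extras),
            }
        ]
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return path


# ---------------------------------------------------------------------------
# SWC
# ---------------------------------------------------------------------------

def parse_swc(
    path: str | Path,
    region_assigner: Callable[[float, float, float], int],
    id_string: str | None = None,
) -> NeuronRecord:
    """Read a 7-column SWC file, annotating regions with *region_assigner*.

    SWC type codes outside {1, 2, 3} (soma/axon/dendrite) are rejected: the
    downstream analysis has no meaning for other neurite classes.
    """
    path = Path(path)
    samples: list[SampleNode] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SchemaError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
            try:
                sid, code = int(parts[0]), int(parts[1])
                x, y, z = float(parts[2]), float(parts[3]), float(parts[4])
                parent = int(parts[6])
            except ValueError as exc:
                raise SchemaError(f"{path}:{lineno}: {exc}") from exc
            if code not in STRUCTURE_CODES:
                raise StructureError(f"{path}:{lineno}: SWC type code {code} outside soma/axon/dendrite")
            try:
                allen = int(region_assigner(x, y, z))
            except Exception as exc:
                raise SchemaError(f"{path}:{lineno}: region annotation failed: {exc}") from exc
            samples.append(SampleNode(sid, parent, STRUCTURE_CODES[code], allen, x, y, z))
    somata = [s for s in samples if s.structure_class == "soma"]
    if len(somata) != 1:
        raise StructureError(f"{path}: expected exactly one soma sample, found {len(somata)}")
    return NeuronRecord(
        id_string=id_string or path.stem,
        doi="",
        soma=somata[0],
        samples=samples,
        source_path=str(path),
    )


def write_swc(record: NeuronRecord, path: str | Path, radius: float = 1.0) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for s in record.samples:
            fh.write(
                f"{s.sample_id} {STRUCTURE_NAMES[s.structure_class]} "
                f"{s.x:.6g} {s.y:.6g} {s.z:.6g} {radius:.6g} {s.parent_id}\n"
            )
    return path


# ---------------------------------------------------------------------------
# Tabular outputs
# ---------------------------------------------------------------------------

def write_metrics_table(rows: Iterable[Mapping[str, object]] | pd.DataFrame, path: str | Path) -> Path:
    """Write per-neuron result rows as TSV, encoding missing values as ``NA``."""
    path = Path(path)
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows), columns=METRICS_COLUMNS)
    missing = [c for c in METRICS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"metrics rows missing columns {missing}")
    df = df[METRICS_COLUMNS]
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
    return path


def read_metrics_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)


def read_manifest(path: str | Path) -> Manifest:
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[], keep_default_na=False)
    for col in ("id", "doi", "group"):
        if col not in df.columns:
            raise SchemaError(f"manifest {path} missing column {col!r}")
    return Manifest(entries=[(r.id, r.doi, r.group) for r in df.itertuples()])


def write_manifest(manifest: Manifest, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(manifest.entries, columns=["id", "doi", "group"]).to_csv(path, sep="\t", index=False)
    return path
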