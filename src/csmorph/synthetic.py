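"""Synthetic reconstruction generator with known ground truth.

Emulates the statistical structure the analysis assumes so every stage is
testable without downloads: rooted sample trees with soma/axon/dendrite
classes, region-annotated samples from a toy box atlas that mirrors the CCF
layout (left/right symmetric about the x = 5700 µm midline), roughly
monotonically decreasing end-point count distributions (zero-truncated
geometric with separate zero inflation), per-axis Gaussian end-point spread
rejection-resampled into the striatum box, bilateral vs ipsilateral-only
targeting, optional pons branches (pyramidal-tract-like neurons) and optional
thalamic contamination (extratelencephalic axon samples).

The toy atlas reuses real Allen structure ids (caudoputamen 672, pons 771,
cerebrum 567, ...) so the default :class:`~csmorph.atlas.RegionPolicy`
applies unchanged. Axis-aligned boxes stand in for region volumes; the
geometry is schematic, not anatomical.

Default cohort parameters mirror the study conditions observed in the real
database: about 10% of intratelencephalic (IT) neurons lack ipsilateral
end-points, about 74% target the contralateral striatum, ipsilateral counts
have mean ~30 (IT) vs ~20 (PT), and IT clouds are wider (400/300/300 µm per
axis) than PT clouds (200 µm isotropic).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .atlas import RegionOntology, RegionPolicy, ontology_from_records
from .reconstruction import (
    Manifest,
    NeuronRecord,
    SampleNode,
    write_manifest,
    write_mouselight_json,
    write_swc,
)

__all__ = ["Box", "SyntheticAtlas", "GroupConfig", "GenerationError",
           "make_atlas", "make_neuron", "generate_cohort", "make_cohort",
           "default_study_groups", "MIRROR_X", "TRUTH_COLUMNS"]

MIRROR_X = 11400.0  # full medial-lateral extent; mirror plane at 5700

TRUTH_COLUMNS = ["id", "group", "label", "area", "layer", "soma_side",
                 "n_ipsi", "n_contra", "gen_sd_x", "gen_sd_y", "gen_sd_z",
                 "non_it_fraction"]


class GenerationError(RuntimeError):
    """Placement could not be satisfied within the resampling budget."""


@dataclass(frozen=True)
class Box:
    """Axis-aligned µm range; inclusive bounds."""

    xlo: float
    xhi: float
    ylo: float
    yhi: float
    zlo: float
    zhi: float

    def contains(self, x: float, y: float, z: float) -> bool:
        return (self.xlo <= x <= self.xhi and self.ylo <= y <= self.yhi
                and self.zlo <= z <= self.zhi)

    def mirrored(self) -> "Box":
        return Box(MIRROR_X - self.xhi, MIRROR_X - self.xlo,
                   self.ylo, self.yhi, self.zlo, self.zhi)

    def center(self) -> tuple[float, float, float]:
        return ((self.xlo + self.xhi) / 2, (self.ylo + self.yhi) / 2,
                (self.zlo + self.zhi) / 2)

    def sample_uniform(self, rng: np.random.Generator, margin: float = 0.0) -> tuple[float, float, float]:
        return (
            float(rng.uniform(self.xlo + margin, self.xhi - margin)),
            float(rng.uniform(self.ylo + margin, self.yhi - margin)),
            float(rng.uniform(self.zlo + margin, self.zhi - margin)),
        )


# ontology ids reused from the Allen structure graph
ROOT, CEREBRUM, CORTEX, STRIATUM, CAUDOPUTAMEN = 997, 567, 688, 477, 672
THALAMUS, PONS, PONS_SENSORY = 549, 771, 1132
FIBER_TRACTS, CST, VENTRICLES = 1009, 784, 73
MOP, MOS = 985, 993

_LAYER_IDS = {
    ("MOp", "L1"): 320, ("MOp", "L2/3"): 943, ("MOp", "L5"): 648,
    ("MOp", "L6a"): 844, ("MOp", "L6b"): 882,
    ("MOs", "L1"): 656, ("MOs", "L2/3"): 962, ("MOs", "L5"): 767,
    ("MOs", "L6a"): 1021, ("MOs", "L6b"): 1085,
}

_LAYER_NAMES = {"L1": "layer 1", "L2/3": "layer 2/3", "L5": "layer 5",
                "L6a": "layer 6a", "L6b": "layer 6b"}

# left-hemisphere boxes; right side is the mirror image about x = 5700.
# All left boxes stop at x <= 5690 and in fact at x <= 5300 for the regions
# that carry somata or end-points, so nothing falls between midline choices
# 5500 and 5700.
_LAYER_Y = {"L1": (100, 300), "L2/3": (300, 800), "L5": (800, 1400),
            "L6a": (1400, 1800), "L6b": (1800, 2000)}
_AREA_XZ = {"MOp": (3200, 4200, 3600, 4600), "MOs": (4300, 5300, 2600, 3600)}


def _layer_boxes() -> dict[int, Box]:
    out = {}
    for (area, layer), rid in _LAYER_IDS.items():
        x0, x1, z0, z1 = _AREA_XZ[area]
        y0, y1 = _LAYER_Y[layer]
        out[rid] = Box(x0, x1, y0, y1, z0, z1)
    return out


_BASE_BOXES: dict[int, Box] = {
    **_layer_boxes(),
    CAUDOPUTAMEN: Box(2600, 5300, 2600, 5400, 3800, 7200),
    THALAMUS: Box(3900, 5600, 3200, 5200, 7600, 9400),
    PONS_SENSORY: Box(4600, 5690, 5600, 7200, 9600, 10800),
    CST: Box(5350, 5690, 4000, 5000, 6000, 7000),
    VENTRICLES: Box(5400, 5690, 1000, 2000, 4000, 5000),
}


def _ontology() -> RegionOntology:
    rec = [
        (ROOT, "root", "root", None),
        (CEREBRUM, "Cerebrum", "CH", ROOT),
        (CORTEX, "Cerebral cortex", "CTX", CEREBRUM),
        (STRIATUM, "Striatum", "STR", CEREBRUM),
        (CAUDOPUTAMEN, "Caudoputamen", "CP", STRIATUM),
        (THALAMUS, "Thalamus", "TH", ROOT),
        (PONS, "Pons", "P", ROOT),
        (PONS_SENSORY, "Pons, sensory related", "P-sen", PONS),
        (FIBER_TRACTS, "fiber tracts", "fiber tracts", ROOT),
        (CST, "corticospinal tract", "cst", FIBER_TRACTS),
        (VENTRICLES, "ventricular systems", "VS", ROOT),
        (MOP, "Primary motor area", "MOp", CORTEX),
        (MOS, "Secondary motor area", "MOs", CORTEX),
    ]
    for (area, layer), rid in _LAYER_IDS.items():
        parent = MOP if area == "MOp" else MOS
        area_name = "Primary motor area" if area == "MOp" else "Secondary motor area"
        rec.append((rid, f"{area_name}, {_LAYER_NAMES[layer]}",
                    f"{area}{layer.replace('L', '').replace('/', '')}", parent))
    return ontology_from_records(rec)


@dataclass(frozen=True)
class SyntheticAtlas:
    """Toy ontology plus mirror-symmetric region boxes and a matching policy."""

    ontology: RegionOntology
    boxes: dict[int, tuple[Box, Box]]  # (left, right) per region
    policy: RegionPolicy

    def region_at(self, x: float, y: float, z: float) -> int:
        """Allen id of the box containing the point; 0 when unannotated."""
        for rid, (left, right) in self.boxes.items():
            if left.contains(x, y, z) or right.contains(x, y, z):
                return rid
        return 0

    def assigner(self) -> Callable[[float, float, float], int]:
        return self.region_at

    def striatum_box(self, side: str) -> Box:
        left, right = self.boxes[CAUDOPUTAMEN]
        return left if side == "left" else right

    def layer_box(self, area: str, layer: str, side: str) -> Box:
        left, right = self.boxes[_LAYER_IDS[(area, layer)]]
        return left if side == "left" else right


def make_atlas() -> SyntheticAtlas:
    """Deterministic fixed toy atlas; identical on every call."""
    boxes = {rid: (box, box.mirrored()) for rid, box in _BASE_BOXES.items()}
    return SyntheticAtlas(ontology=_ontology(), boxes=boxes, policy=RegionPolicy())


@dataclass(frozen=True)
class GroupConfig:
    """Generation law for one cohort group.

    ``mean_n_ipsi``/``mean_n_contra`` parameterise zero-truncated geometric
    count laws on {1, 2, ...}; ``p_no_ipsi`` is a separate zero-inflation
    probability; ``sd_xyz`` are the generating per-axis Gaussian spreads in
    µm around a per-neuron center drawn inside the striatum box.
    """

    name: str
    n_neurons: int
    area: str = "MOs"
    layer: str = "L2/3"
    mean_n_ipsi: float = 30.0
    p_no_ipsi: float = 0.0
    sd_xyz: tuple[float, float, float] = (400.0, 300.0, 300.0)
    p_contra: float = 0.0
    mean_n_contra: float = 10.0
    pons_branch: bool = False
    non_it_fraction: float = 0.0
    soma_side: str = "left"

    def __post_init__(self) -> None:
        if not (0 <= self.p_no_ipsi <= 1 and 0 <= self.p_contra <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.mean_n_ipsi < 1 or self.mean_n_contra < 1:
            raise ValueError("count-law means must be >= 1")
        if any(s < 0 for s in self.sd_xyz):
            raise ValueError("spread SDs must be >= 0")
        if not 0 <= self.non_it_fraction < 1:
            raise ValueError("non_it_fraction must lie in [0, 1)")
        if (self.area, self.layer) not in _LAYER_IDS:
            raise ValueError(f"unknown soma location {(self.area, self.layer)}")


def default_study_groups(n_it: int = 161, n_pt: int = 33) -> list[GroupConfig]:
    """Cohort defaults mirroring the study conditions (see module docstring)."""
    return [
        GroupConfig(name="IT", n_neurons=n_it, area="MOs", layer="L2/3",
                    mean_n_ipsi=30.0, p_no_ipsi=0.10,
                    sd_xyz=(400.0, 300.0, 300.0),
                    p_contra=0.74, mean_n_contra=15.0),
        GroupConfig(name="PT", n_neurons=n_pt, area="MOs", layer="L5",
                    mean_n_ipsi=20.0, p_no_ipsi=0.0,
                    sd_xyz=(200.0, 200.0, 200.0),
                    pons_branch=True),
    ]


def _truncated_geometric(rng: np.random.Generator, mean: float) -> int:
    # geometric on {1, 2, ...} with mean m  <=>  success prob 1/m
    return int(rng.geometric(1.0 / mean))


def _gaussian_in_box(
    rng: np.random.Generator,
    center: Sequence[float],
    sd: Sequence[float],
    box: Box,
    max_tries: int = 1000,
) -> tuple[float, float, float]:
    for _ in range(max_tries):
        p = rng.normal(center, sd)
        if box.contains(*p):
            return (round(float(p[0]), 2), round(float(p[1]), 2), round(float(p[2]), 2))
    raise GenerationError(f"could not place a point in {box} around {center} after {max_tries} draws")


def make_neuron(
    group: GroupConfig,
    atlas: SyntheticAtlas,
    rng: np.random.Generator,
    neuron_id: str = "SYN0001",
) -> tuple[NeuronRecord, dict]:
    """Build one neuron and its ground truth.

    Tree layout: soma -> cortical axon trunk -> striatal hub whose axon-class
    children are exactly the drawn ipsilateral end-points (the hub itself is
    never a leaf when end-points exist); an analogous mirrored hub for
    contralateral end-points; optionally a two-sample pons branch and a chain
    of thalamic samples sized to hit the requested non-telencephalic axon
    fraction. Every sample's allen id is assigned from the containing atlas
    box, exactly as the database annotates reconstructions.
    """
    side = group.soma_side
    soma_box = atlas.layer_box(group.area, group.layer, side)
    sx, sy, sz = (round(v, 2) for v in soma_box.sample_uniform(rng, margin=20.0))

    samples: list[SampleNode] = []
    next_id = 1

    def add(parent: int, cls: str, x: float, y: float, z: float) -> int:
        nonlocal next_id
        sid = next_id
        next_id += 1
        samples.append(SampleNode(sid, parent, cls, atlas.region_at(x, y, z), x, y, z))
        return sid

    soma_id = add(-1, "soma", sx, sy, sz)
    # short dendrite so dendrite-array handling is exercised
    add(soma_id, "dendrite", *(round(v, 2) for v in soma_box.sample_uniform(rng, margin=20.0)))
    trunk_id = add(soma_id, "axon", *(round(v, 2) for v in soma_box.sample_uniform(rng, margin=20.0)))

    k_ipsi = 0 if rng.random() < group.p_no_ipsi else _truncated_geometric(rng, group.mean_n_ipsi)
    str_box = atlas.striatum_box(side)
    if k_ipsi > 0:
        center = str_box.sample_uniform(rng, margin=400.0)
        hub = add(trunk_id, "axon", *(round(v, 2) for v in center))
        for _ in range(k_ipsi):
            add(hub, "axon", *_gaussian_in_box(rng, center, group.sd_xyz, str_box))

    targeting = rng.random() < group.p_contra
    k_contra = _truncated_geometric(rng, group.mean_n_contra) if targeting else 0
    if k_contra > 0:
        cbox = atlas.striatum_box("right" if side == "left" else "left")
        ccenter = cbox.sample_uniform(rng, margin=400.0)
        chub = add(trunk_id, "axon", *(round(v, 2) for v in ccenter))
        for _ in range(k_contra):
            add(chub, "axon", *_gaussian_in_box(rng, ccenter, group.sd_xyz, cbox))

    if group.pons_branch:
        pbox = atlas.boxes[PONS_SENSORY][0 if side == "left" else 1]
        pid = add(trunk_id, "axon", *(round(v, 2) for v in pbox.sample_uniform(rng, margin=50.0)))
        add(pid, "axon", *(round(v, 2) for v in pbox.sample_uniform(rng, margin=50.0)))

    n_thal = 0
    if group.non_it_fraction > 0:
        n_axon = sum(1 for s in samples if s.structure_class == "axon")
        f = group.non_it_fraction
        n_thal = max(1, round(f * n_axon / (1.0 - f)))
        tbox = atlas.boxes[THALAMUS][0 if side == "left" else 1]
        parent = trunk_id
        for _ in range(n_thal):
            parent = add(parent, "axon", *(round(v, 2) for v in tbox.sample_uniform(rng, margin=50.0)))

    n_axon_total = sum(1 for s in samples if s.structure_class == "axon")
    realized_f = n_thal / n_axon_total if n_axon_total else 0.0

    if k_ipsi + k_contra == 0:
        label = "NOT_CORTICOSTRIATAL"
    elif group.pons_branch:
        label = "PT" if group.layer == "L5" else "NOT_CORTICOSTRIATAL"
    elif n_thal > 0:
        label = "EXCLUDED_NON_IT"
    else:
        label = "IT"

    record = NeuronRecord(
        id_string=neuron_id, doi="", soma=samples[0], samples=samples,
        source_path="synthetic",
    )
    truth = {
        "id": neuron_id, "group": group.name, "label": label,
        "area": group.area, "layer": group.layer, "soma_side": side,
        "n_ipsi": k_ipsi, "n_contra": k_contra,
        "gen_sd_x": group.sd_xyz[0], "gen_sd_y": group.sd_xyz[1],
        "gen_sd_z": group.sd_xyz[2],
        "non_it_fraction": realized_f,
    }
    return record, truth


def generate_cohort(
    groups: Iterable[GroupConfig],
    seed: int,
    atlas: SyntheticAtlas | None = None,
) -> tuple[list[NeuronRecord], pd.DataFrame]:
    """In-memory cohort: one record per neuron plus a ground-truth table."""
    atlas = atlas or make_atlas()
    rng = np.random.default_rng(seed)
    records: list[NeuronRecord] = []
    truths: list[dict] = []
    i = 1
    for group in groups:
        for _ in range(group.n_neurons):
            rec, truth = make_neuron(group, atlas, rng, neuron_id=f"SYN{i:04d}")
            records.append(rec)
            truths.append(truth)
            i += 1
    return records, pd.DataFrame(truths, columns=TRUTH_COLUMNS)


def make_cohort(
    groups: Iterable[GroupConfig],
    out_dir: str | Path,
    seed: int,
    atlas: SyntheticAtlas | None = None,
    swc: bool = False,
) -> tuple[list[Path], pd.DataFrame]:
    """Write a cohort to disk: one JSON per neuron, manifest and truth TSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records, truth = generate_cohort(groups, seed, atlas)
    paths = []
    for rec in records:
        paths.append(write_mouselight_json(rec, out_dir / f"{rec.id_string}.json"))
        if swc:
            write_swc(rec, out_dir / f"{rec.id_string}.swc")
    manifest = Manifest(entries=[(t["id"], "", t["group"]) for t in truth.to_dict("records")])
    write_manifest(manifest, out_dir / "manifest.tsv")
    truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return paths, truth
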