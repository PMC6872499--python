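"""End-to-end orchestration: extraction table and the comparison suite.

``run_extract`` turns reconstructions (in-memory records, or a manifest plus
a directory of JSON files) into one row per neuron: classification, soma
area/layer, end-point counts and dispersion metrics. ``run_compare`` runs the
full comparison suite on such a table: Welch tests with Cohen's d on log
ipsilateral counts and on the dispersion metrics for every group pair of
interest, uncorrected chi-square with phi on the "more than 50 ipsilateral
end-points" dichotomy, and Pearson/OLS relations between dispersion and log
count per group — each comparison recording its exact inclusion rule and
group sizes. Neurons classified EXCLUDED_NON_IT or NOT_CORTICOSTRIATAL stay
in the table but never enter comparisons.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas import RegionOntology, RegionPolicy
from .classify import ClassifyConfig, classify_neuron
from .endpoints import extract_endpoint_set
from .metrics import compute_metrics
from .reconstruction import (
    METRICS_COLUMNS,
    Manifest,
    NeuronRecord,
    parse_mouselight_json,
    read_manifest,
    write_metrics_table,
)
from . import stats as _stats

__all__ = ["Comparison", "ComparisonReport", "run_extract", "run_compare",
           "report_to_text", "report_to_frame", "reproduce_published_counts",
           "DEFAULT_ENDPOINT_THRESHOLD"]

logger = logging.getLogger(__name__)

DEFAULT_ENDPOINT_THRESHOLD = 50


@dataclass
class Comparison:
    """One named comparison with its inclusion rule and group sizes."""

    kind: str  # "welch" | "chi2" | "corr"
    name: str
    inclusion: str
    n1: int
    n2: int
    result: object | None  # WelchResult | Chi2Result | CorrRegResult | None
    note: str = ""

    @property
    def computable(self) -> bool:
        return self.result is not None


@dataclass
class ComparisonReport:
    per_neuron_table: pd.DataFrame
    comparisons: list[Comparison]
    counts: dict[str, int]
    endpoint_threshold: int

    def get(self, kind: str, name: str) -> Comparison:
        for c in self.comparisons:
            if c.kind == kind and c.name == name:
                return c
        raise KeyError(f"no {kind} comparison named {name!r}")


def run_extract(
    records: Iterable[NeuronRecord] | None = None,
    manifest: Manifest | str | Path | None = None,
    data_dir: str | Path | None = None,
    *,
    policy: RegionPolicy,
    ontology: RegionOntology,
    config: ClassifyConfig = ClassifyConfig(),
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Per-neuron table from records or from a manifest + data directory.

    A neuron that fails to parse is recorded in the returned error list and
    the run continues. Returns ``(table, errors)``.
    """
    errors: list[tuple[str, str]] = []
    if records is None:
        if manifest is None or data_dir is None:
            raise ValueError("provide either records, or a manifest and data_dir")
        if not isinstance(manifest, Manifest):
            manifest = read_manifest(manifest)
        if not manifest.entries:
            raise ValueError("empty manifest")
        data_dir = Path(data_dir)

        def _iter():
            for nid, _doi, _group in manifest.entries:
                path = data_dir / f"{nid}.json"
                try:
                    yield parse_mouselight_json(path)
                except Exception as exc:  # parse failures recorded, run continues
                    errors.append((nid, str(exc)))
                    logger.warning("skipping %s: %s", nid, exc)

        records = _iter()

    rows = []
    for rec in records:
        cls = classify_neuron(rec, policy, ontology, config)
        es = extract_endpoint_set(rec, policy)
        m = compute_metrics(es)
        rows.append({
            "id": rec.id_string, "doi": rec.doi,
            "type": cls.neuron_type.value,
            "area": cls.soma_area.value, "layer": cls.soma_layer.value,
            "n_ipsi": m.n_ipsi, "n_contra": m.n_contra, "ln_n_ipsi": m.ln_n_ipsi,
            "sd_x": m.sd_x, "sd_y": m.sd_y, "sd_z": m.sd_z, "sd_dist": m.sd_dist,
            "non_it_fraction": cls.non_it_fraction,
        })
    return pd.DataFrame(rows, columns=METRICS_COLUMNS), errors


def _analysis_groups(df: pd.DataFrame) -> dict[str, pd.DataFrame]:
    it = df[df["type"] == "IT"]
    pt = df[df["type"] == "PT"]
    mos_l23 = it[(it["area"] == "MOs") & (it["layer"] == "L2/3")]
    return {
        "IT": it,
        "PT": pt,
        "MOp IT": it[it["area"] == "MOp"],
        "MOp PT": pt[pt["area"] == "MOp"],
        "MOs IT": it[it["area"] == "MOs"],
        "MOs PT": pt[pt["area"] == "MOs"],
        "MOs L5 IT": it[(it["area"] == "MOs") & (it["layer"] == "L5")],
        "MOs L2/3 IT": mos_l23,
        # bilateral: targets both sides; contra-non-targeting: no contra point
        "MOs L2/3 IT bilateral": mos_l23[(mos_l23["n_ipsi"] >= 1) & (mos_l23["n_contra"] >= 1)],
        "MOs L2/3 IT contra-non": mos_l23[mos_l23["n_contra"] == 0],
    }


_WELCH_PAIRS = [
    ("IT", "PT"),
    ("MOp IT", "MOp PT"),
    ("MOs IT", "MOs PT"),
    ("MOs L5 IT", "MOs L2/3 IT"),
    ("MOs L5 IT", "MOs PT"),
    ("MOs L2/3 IT", "MOs PT"),
    ("MOs L2/3 IT bilateral", "MOs L2/3 IT contra-non"),
    ("MOs L2/3 IT bilateral", "MOs L5 IT"),
    ("MOs L2/3 IT bilateral", "MOs PT"),
    ("MOs L2/3 IT contra-non", "MOs L5 IT"),
    ("MOs L2/3 IT contra-non", "MOs PT"),
]

_CHI2_PAIRS = [("IT", "PT"), ("MOs L5 IT", "MOs L2/3 IT")]

_CORR_GROUPS = ["PT", "IT", "MOp PT", "MOp IT", "MOs PT", "MOs IT"]


def _welch_comparison(name: str, var: str, g1: pd.DataFrame, g2: pd.DataFrame) -> Comparison:
    # log-count and dispersion analyses exclude neurons with no ipsi point
    x = g1.loc[g1["n_ipsi"] >= 1, var].to_numpy(dtype=float)
    y = g2.loc[g2["n_ipsi"] >= 1, var].to_numpy(dtype=float)
    inclusion = "n_ipsi >= 1"
    if len(x) < 2 or len(y) < 2:
        return Comparison("welch", name, inclusion, len(x), len(y), None,
                          note="not computable: a group has < 2 eligible neurons")
    try:
        res = _stats.welch_t_d(x, y)
    except _stats.DegenerateInputError as exc:
        return Comparison("welch", name, inclusion, len(x), len(y), None, note=str(exc))
    return Comparison("welch", name, inclusion, len(x), len(y), res)


def _chi2_comparison(name: str, g1: pd.DataFrame, g2: pd.DataFrame, threshold: int) -> Comparison:
    inclusion = f"n_ipsi >= 1; dichotomy at > {threshold}"
    e1 = g1[g1["n_ipsi"] >= 1]
    e2 = g2[g2["n_ipsi"] >= 1]
    a = int((e1["n_ipsi"] > threshold).sum())
    c = int((e2["n_ipsi"] > threshold).sum())
    if len(e1) == 0 or len(e2) == 0:
        return Comparison("chi2", name, inclusion, len(e1), len(e2), None,
                          note="not computable: empty group")
    res = _stats.chi2_phi(a, len(e1) - a, c, len(e2) - c)
    return Comparison("chi2", name, inclusion, len(e1), len(e2), res)


def _corr_comparison(name: str, var: str, g: pd.DataFrame, drop_singletons: bool) -> Comparison:
    sel = g["n_ipsi"] > 1 if drop_singletons else g["n_ipsi"] >= 1
    inclusion = "n_ipsi > 1" if drop_singletons else "n_ipsi >= 1"
    sub = g[sel]
    x = sub["ln_n_ipsi"].to_numpy(dtype=float)
    y = sub[var].to_numpy(dtype=float)
    if len(x) < 3:
        return Comparison("corr", name, inclusion, len(x), len(x), None,
                          note="not computable: fewer than 3 eligible neurons")
    try:
        res = _stats.ols_fit(x, y)
    except _stats.DegenerateInputError as exc:
        return Comparison("corr", name, inclusion, len(x), len(x), None, note=str(exc))
    return Comparison("corr", name, inclusion, len(x), len(x), res)


def _counts_summary(df: pd.DataFrame, threshold: int) -> dict[str, int]:
    g = _analysis_groups(df)
    it, pt = g["IT"], g["PT"]
    it_e = it[it["n_ipsi"] >= 1]
    pt_e = pt[pt["n_ipsi"] >= 1]
    l5 = g["MOs L5 IT"]
    l23 = g["MOs L2/3 IT"]
    excluded = df[df["type"] == "EXCLUDED_NON_IT"]
    return {
        "it_total": len(it),
        "pt_total": len(pt),
        "it_no_ipsi": int((it["n_ipsi"] == 0).sum()),
        "it_no_contra": int((it["n_contra"] == 0).sum()),
        "it_ipsi_gt_contra": int((it["n_ipsi"] > it["n_contra"]).sum()),
        "it_contra_gt_ipsi": int((it["n_contra"] > it["n_ipsi"]).sum()),
        "it_ipsi_eq_contra": int((it["n_ipsi"] == it["n_contra"]).sum()),
        "pt_with_contra": int((pt["n_contra"] >= 1).sum()),
        "it_with_ipsi": len(it_e),
        "pt_with_ipsi": len(pt_e),
        "it_gt_threshold": int((it_e["n_ipsi"] > threshold).sum()),
        "pt_gt_threshold": int((pt_e["n_ipsi"] > threshold).sum()),
        "mos_l5_it_total": len(l5),
        "mos_l5_it_with_contra": int((l5["n_contra"] >= 1).sum()),
        "mos_l5_it_bilateral": int(((l5["n_contra"] >= 1) & (l5["n_ipsi"] >= 1)).sum()),
        "mos_l23_it_total": len(l23),
        "mos_l23_it_contra_targeting": int((l23["n_contra"] >= 1).sum()),
        "mos_l23_it_contra_non_targeting": int((l23["n_contra"] == 0).sum()),
        "flagged_non_it": len(excluded),
        "flagged_non_it_above_10pct": int((excluded["non_it_fraction"] > 0.10).sum()),
        "not_corticostriatal": int((df["type"] == "NOT_CORTICOSTRIATAL").sum()),
    }


def run_compare(
    table: pd.DataFrame,
    endpoint_threshold: int = DEFAULT_ENDPOINT_THRESHOLD,
) -> ComparisonReport:
    """Full comparison suite on a per-neuron table (see module docstring)."""
    groups = _analysis_groups(table)
    comps: list[Comparison] = []
    for a, b in _WELCH_PAIRS:
        for var, tag in (("ln_n_ipsi", "ln n_ipsi"), ("sd_x", "sd_x"),
                         ("sd_y", "sd_y"), ("sd_z", "sd_z"), ("sd_dist", "sd_dist")):
            comps.append(_welch_comparison(f"{tag}: {a} vs {b}", var, groups[a], groups[b]))
    for a, b in _CHI2_PAIRS:
        comps.append(_chi2_comparison(f"> {endpoint_threshold} ipsi: {a} vs {b}",
                                      groups[a], groups[b], endpoint_threshold))
    for gname in _CORR_GROUPS:
        for var in ("sd_x", "sd_dist"):
            for drop in (False, True):
                suffix = " (excl. single-end-point)" if drop else ""
                comps.append(_corr_comparison(f"{var} ~ ln n_ipsi: {gname}{suffix}",
                                              var, groups[gname], drop))
    # excluded + included must add up per group; log the accounting
    for name in ("IT", "PT"):
        g = groups[name]
        n_excl = int((g["n_ipsi"] == 0).sum())
        logger.info("%s: %d neurons, %d excluded from log/dispersion analyses (no ipsi point)",
                    name, len(g), n_excl)
    return ComparisonReport(
        per_neuron_table=table,
        comparisons=comps,
        counts=_counts_summary(table, endpoint_threshold),
        endpoint_threshold=endpoint_threshold,
    )


def report_to_frame(report: ComparisonReport) -> pd.DataFrame:
    """Flatten the comparison suite to one row per comparison."""
    rows = []
    for c in report.comparisons:
        row: dict[str, object] = {
            "kind": c.kind, "name": c.name, "inclusion": c.inclusion,
            "n1": c.n1, "n2": c.n2, "note": c.note,
        }
        r = c.result
        if r is None:
            pass
        elif c.kind == "welch":
            row.update(t=r.t, df=r.df, p=r.p, d=r.d, mean1=r.mean1, mean2=r.mean2)
        elif c.kind == "chi2":
            row.update(chi2=r.chi2, p=r.p, phi=r.phi)
        else:
            row.update(r=r.r, p=r.p_r, intercept=r.intercept, slope=r.slope,
                       p_intercept=r.p_intercept, p_slope=r.p_slope)
        rows.append(row)
    return pd.DataFrame(rows)


def report_to_text(report: ComparisonReport) -> str:
    lines = [f"Comparison report (end-point dichotomy threshold: {report.endpoint_threshold})", ""]
    lines.append("Counts:")
    for k, v in report.counts.items():
        lines.append(f"  {k}: {v}")
    lines.append("")
    for c in report.comparisons:
        r = c.result
        if r is None:
            lines.append(f"[{c.kind}] {c.name} (n={c.n1}/{c.n2}; {c.inclusion}): {c.note}")
        elif c.kind == "welch":
            lines.append(f"[welch] {c.name} (n={c.n1}/{c.n2}; {c.inclusion}): "
                         f"t={r.t:.4g} df={r.df:.3g} p={r.p:.3g} d={r.d:.3g}")
        elif c.kind == "chi2":
            lines.append(f"[chi2] {c.name} (n={c.n1}/{c.n2}; {c.inclusion}): "
                         f"chi2={r.chi2:.4g} p={r.p:.3g} phi={r.phi:.3g}")
        else:
            lines.append(f"[corr] {c.name} (n={c.n1}; {c.inclusion}): "
                         f"r={r.r:.3g} p={r.p_r:.3g} intercept={r.intercept:.4g} "
                         f"(p={r.p_intercept:.3g}) slope={r.slope:.4g} (p={r.p_slope:.3g})")
    return "\n".join(lines) + "\n"


def reproduce_published_counts(
    data_dir: str | Path,
    manifest: Manifest | str | Path,
    *,
    policy: RegionPolicy,
    ontology: RegionOntology,
    config: ClassifyConfig = ClassifyConfig(),
    endpoint_threshold: int = DEFAULT_ENDPOINT_THRESHOLD,
) -> dict[str, float]:
    """Re-derive the headline cohort counts from a directory of entity files.

    Needs the DOI-versioned reconstruction JSONs (one ``<ID>.json`` per
    manifest entry; see the ``fetch`` CLI subcommand) and a full Allen
    structure-graph ontology. Returns the counts summary plus the maximum
    non-telencephalic axon fraction observed among flagged neurons.
    """
    table, errors = run_extract(manifest=manifest, data_dir=data_dir,
                                policy=policy, ontology=ontology, config=config)
    if errors:
        raise RuntimeError(f"{len(errors)} entities failed to parse; first: {errors[0]}")
    report = run_compare(table, endpoint_threshold)
    out: dict[str, float] = dict(report.counts)
    flagged = table[table["type"] == "EXCLUDED_NON_IT"]
    if len(flagged):
        out["max_flagged_non_it_fraction"] = float(flagged["non_it_fraction"].max())
    return out


def fetch_entities(
    manifest: Manifest | str | Path,
    data_dir: str | Path,
    base_url: str = "https://ml-neuronbrowser.janelia.org/json",
    timeout: float = 60.0,
) -> list[str]:
    """Download entity JSONs by id into *data_dir* (network required; cached).

    Returns the ids actually fetched; entities already on disk are kept.
    """
    import urllib.request

    if not isinstance(manifest, Manifest):
        manifest = read_manifest(manifest)
    data_dir = Path(data_dir)
    data_dir.mkdir(parents=True, exist_ok=True)
    fetched = []
    for nid, _doi, _group in manifest.entries:
        target = data_dir / f"{nid}.json"
        if target.exists():
            continue
        req = urllib.request.Request(
            base_url,
            data=__import__("json").dumps({"ids": [nid]}).encode(),
            headers={"Content-Type": "application/json"},
        )
        with urllib.request.urlopen(req, timeout=timeout) as resp:
            target.write_bytes(resp.read())
        fetched.append(nid)
        logger.info("fetched %s", nid)
    return fetched
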