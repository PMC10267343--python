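"""End-to-end pipeline: observations -> threshold networks -> report bundle.

``run_pipeline`` executes the full analysis — aggregate the qualifying
approaches, build the three threshold networks, compute cohesion metrics
and presence-adjusted degrees per network, run E-I assortment tests
(parity, breeding group, coreness), the k-core decomposition, brokerage
typologies, and subgroup degree comparisons — and writes a machine-readable
report bundle (JSON + CSVs + graph exports) under ``out_dir``. Assortment,
brokerage and subgroup comparisons run on the mean (threshold 2) network by
default, the standard choice for filtered preferential-association
analysis; this is overridable via ``analysis_threshold``.

The run is deterministic: all stage seeds derive from one master seed and
re-running with identical inputs and configuration produces a byte-identical
``report.json``. A provenance block records input hashes, seeds, package
version and the documented modelling substitutions.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .assortment import ei_permutation_test
from .brokerage import brokerage_profiles, census
from .build import adjusted_degrees, aggregate, apply_threshold
from .data import (
    AnimalRegistry,
    ObservationRecord,
    read_observations,
    read_registry,
    write_network,
    write_observations,
    write_registry,
)
from .inference import INFERENCE_NOTE, compare_subgroups
from .metrics import kcore_assign, summarize
from .synthetic import SyntheticHerdConfig, generate_dataset

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message carries the stage name and cause."""


@dataclass
class PipelineConfig:
    out_dir: str | Path
    seed: int = 1
    observations: str | Path | None = None
    registry: str | Path | None = None
    simulate: SyntheticHerdConfig | None = None
    thresholds: Sequence[int] = (1, 2, 3)
    analysis_threshold: int = 2
    attributes: Sequence[str] = ("parity", "breeding_group", "kcore")
    n_perm_ei: int = 10_000
    n_perm_brokerage: int = 1000
    n_perm_groups: int = 5000
    min_toleration_s: float = 60.0
    drop_isolates: bool = False


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _jsonify(obj):
    """Make a report JSON-safe: numpy scalars -> python, NaN/inf -> None."""
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if not math.isfinite(f) else f
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns the report dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance: dict = {
        "package": "sownet",
        "version": __version__,
        "seed": config.seed,
        "notes": [INFERENCE_NOTE],
        "inputs": {},
    }

    # --- load or simulate -------------------------------------------------
    if config.simulate is not None:
        herd, records = _stage("simulate")(generate_dataset)(config.simulate)
        registry = herd.registry
        obs_path, reg_path = out / "observations.csv", out / "registry.csv"
        write_observations(records, obs_path)
        write_registry(registry, reg_path)
        provenance["inputs"]["simulated"] = config.simulate.to_dict()
    else:
        if config.observations is None or config.registry is None:
            raise PipelineError("stage 'load' failed: need observations+registry paths or a simulate config")
        obs_path, reg_path = Path(config.observations), Path(config.registry)
        records = _stage("load")(read_observations)(obs_path)
        registry = _stage("load")(read_registry)(reg_path)
    provenance["inputs"]["observations_sha256"] = _sha256(obs_path)
    provenance["inputs"]["registry_sha256"] = _sha256(reg_path)

    report: dict = {"provenance": provenance, "networks": {}, "n_records": len(records)}

    # --- networks, metrics, degrees ---------------------------------------
    original = _stage("aggregate")(aggregate)(records, registry, config.min_toleration_s)
    H_total = registry.total_hours
    nets = {}
    for level in config.thresholds:
        net = _stage("threshold")(apply_threshold)(original, level, config.drop_isolates)
        nets[level] = net
        summary = _stage("metrics")(summarize)(net)
        degrees = _stage("degrees")(adjusted_degrees)(net, registry, H_total)
        deg_path = out / f"degrees_{net.threshold_label}.csv"
        degrees.to_csv(deg_path)
        for fmt, ext in (("edgelist_csv", "csv"), ("graphml", "graphml"), ("ucinet_dl", "dl")):
            write_network(net, out / f"network_{net.threshold_label}.{ext}", fmt)
        report["networks"][net.threshold_label] = {
            "summary": summary.to_dict(),
            "degrees_csv": deg_path.name,
        }

    summary_table = pd.DataFrame(
        {lbl: blk["summary"] for lbl, blk in report["networks"].items()}
    )
    summary_table.to_csv(out / "summary.csv")

    # --- analysis network: k-cores, E-I, brokerage, comparisons -----------
    analysis_net = nets[config.analysis_threshold]
    coreness = _stage("kcore")(kcore_assign)(analysis_net)
    pd.Series(coreness, name="coreness").rename_axis("animal_id").to_csv(out / "coreness.csv")
    report["analysis_network"] = analysis_net.threshold_label
    report["kcore"] = {
        "shell_sizes": {
            int(k): int(sum(1 for v in coreness.values() if v == k))
            for k in sorted(set(coreness.values()))
        }
    }

    attribute_labels = {}
    for attr in config.attributes:
        if attr == "kcore":
            attribute_labels[attr] = {a: int(k) for a, k in coreness.items()}
        else:
            attribute_labels[attr] = registry.attribute(attr)

    report["ei"] = {}
    for i, attr in enumerate(config.attributes):
        try:
            res = ei_permutation_test(
                analysis_net,
                attribute_labels[attr],
                n_perm=config.n_perm_ei,
                seed=config.seed + 100 + i,
                attribute=attr,
            )
            report["ei"][attr] = res.to_dict()
        except ValueError as exc:
            report["ei"][attr] = {"attribute": attr, "undefined": str(exc)}

    profiles = _stage("brokerage")(brokerage_profiles)(
        analysis_net, attribute_labels["kcore"] if "kcore" in attribute_labels else coreness,
        n_perm=config.n_perm_brokerage, seed=config.seed + 200,
    )
    profiles.to_csv(out / "brokerage_profiles.csv")
    cens = _stage("brokerage")(census)(analysis_net, {a: int(k) for a, k in coreness.items()})
    cens.to_csv(out / "brokerage_census.csv")
    report["brokerage"] = {
        "typology_counts": profiles["typology"].value_counts().sort_index().to_dict(),
        "n_excluded": int(profiles["excluded"].sum()),
        "census": cens.reset_index().to_dict(orient="records"),
        "profiles_csv": "brokerage_profiles.csv",
    }

    degrees_analysis = adjusted_degrees(analysis_net, registry, H_total)
    report["subgroup_comparison"] = {}
    for j, measure in enumerate(("in", "out")):
        try:
            comp = compare_subgroups(
                degrees_analysis,
                coreness,
                measure=measure,
                n_perm=config.n_perm_groups,
                seed=config.seed + 300 + j,
            )
            report["subgroup_comparison"][measure] = comp.to_dict()
        except ValueError as exc:
            report["subgroup_comparison"][measure] = {"undefined": str(exc)}

    report = _jsonify(report)
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return report
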