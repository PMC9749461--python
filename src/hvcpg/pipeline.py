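"""End-to-end pipeline orchestration with a reproducible run manifest.

Stages run in the fixed order filter -> adjust -> outlier-remove ->
variance -> detect -> reliability-filter -> controls -> clusters
(-> enrichment when feature inputs are supplied).  Inputs are never
mutated; every artefact lands in the run directory and is recorded in
``manifest.json`` with its SHA-256 hash, the stage parameters and seeds,
so an identical configuration reproduces identical output hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import pandas as pd

from . import io as hio
from .clusters import build_clusters, decluster
from .controls import ks_match_controls
from .core import ConfigurationError
from .detect import (apply_reliability_filter, dataset_variances, hvcpg_ids,
                     identify_hvcpgs, array_background_ids, top_variance_flags)
from .enrichment import set_overlap_report
from .preprocess import AdjustmentSpec, FilterRules, preprocess_dataset
from .synthetic import SimulationConfig, simulate_study

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative configuration for :func:`run_pipeline`.

    Either ``simulate`` (a :class:`SimulationConfig`) or ``datasets`` (a
    manifest of per-dataset file paths: ``beta``, optional ``covariates``,
    ``detection_p``, ``dataset_id``, ``tissue``, ``ethnicity``) must be
    given.  Stage parameters default to the pipeline's standard values
    (top 5% variance, 65% of covered datasets, >= 15 datasets, 4 kb
    cluster gap, KS p > 0.1, 10 PCs, Tukey k = 3).
    """

    outdir: str = "hvcpg_run"
    simulate: Optional[SimulationConfig] = None
    datasets: List[dict] = field(default_factory=list)
    annotation: Optional[str] = None
    unreliable_list: Optional[str] = None
    published_sets: dict = field(default_factory=dict)
    top_pct: float = 5.0
    dataset_fraction_pct: float = 65.0
    min_datasets: int = 15
    cluster_gap_bp: int = 4000
    ks_min_p: float = 0.1
    n_pcs: int = 10
    tukey_k: float = 3.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulate = SimulationConfig(**sim)
        return cfg

    def validate(self) -> None:
        if self.simulate is None and not self.datasets:
            raise ConfigurationError("config needs either 'simulate' or 'datasets'")
        for entry in self.datasets:
            for key in ("beta",):
                if key not in entry:
                    raise ConfigurationError(f"dataset manifest entry missing {key!r}")
                if not Path(entry[key]).exists():
                    raise ConfigurationError(f"missing input file: {entry[key]}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full discovery pipeline; returns the run directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "params": {
        k: v for k, v in dataclasses.asdict(config).items() if k not in ("datasets", "simulate")
    }}
    if config.simulate is not None:
        manifest["params"]["simulate"] = dataclasses.asdict(config.simulate)
    events: List[dict] = []

    def stage(name: str, **info):
        events.append({"stage": name, **info})
        logger.info("stage %s: %s", name, info)

    # --- inputs -----------------------------------------------------------
    annotation = None
    truth = None
    if config.simulate is not None:
        datasets, annotation, truth = simulate_study(config.simulate)
        stage("simulate", n_datasets=len(datasets), n_cpgs=config.simulate.n_cpgs,
              seed=config.simulate.seed)
    else:
        datasets = [
            hio.read_dataset(
                e["beta"], e.get("covariates"), e.get("detection_p"),
                e.get("dataset_id"), e.get("tissue", ""), e.get("ethnicity", ""),
            )
            for e in config.datasets
        ]
        stage("load", n_datasets=len(datasets))
    if config.annotation:
        annotation = hio.read_annotation(config.annotation)

    # --- preprocess: filter -> adjust -> outlier removal ------------------
    rules = FilterRules()
    spec = AdjustmentSpec(n_pcs=min(config.n_pcs, min(d.n_samples for d in datasets) - 1))
    processed = []
    for ds in datasets:
        out = preprocess_dataset(ds, rules, spec, tukey_k=config.tukey_k)
        processed.append(out)
        stage("preprocess", dataset=ds.dataset_id, n_cpgs_in=ds.n_cpgs, n_cpgs_out=out.n_cpgs)

    # --- variance + detection --------------------------------------------
    variances = {d.dataset_id: dataset_variances(d) for d in processed}
    flags = {k: top_variance_flags(v, config.top_pct) for k, v in variances.items()}
    result = identify_hvcpgs(flags, config.top_pct, config.dataset_fraction_pct, config.min_datasets)
    stage("detect", n_hvcpgs=int(result["is_hvcpg"].sum()),
          n_background=int(result["in_background"].sum()))

    unreliable = set()
    if config.unreliable_list:
        unreliable = hio.read_id_list(config.unreliable_list)
    elif annotation is not None:
        unreliable = annotation.unreliable_ids()
    if unreliable:
        result = apply_reliability_filter(result, unreliable)
        stage("reliability_filter", n_removed=result.attrs.get("n_unreliable_removed", 0))

    hv = hvcpg_ids(result)
    background = array_background_ids(result).difference(hv).difference(unreliable)
    result_tsv = outdir / "hvcpg_result.tsv"
    hio.write_hvcpg_result(result, annotation, result_tsv,
                           outdir / "hvcpgs.bed" if annotation is not None else None)
    hio.write_id_list(hv, outdir / "hvcpgs.txt")

    # --- distribution-matched controls ------------------------------------
    match = None
    if len(hv) and len(background):
        reference = max(processed, key=lambda d: d.n_samples)
        match = ks_match_controls(hv, background, reference, min_p=config.ks_min_p)
        match.pairs.to_csv(outdir / "distribution_matched_controls.tsv", sep="\t", index=False)
        stage("controls", reference=reference.dataset_id, n_matched=len(match.pairs),
              n_unmatched=len(match.unmatched))

    # --- clusters ----------------------------------------------------------
    declustered = []
    if annotation is not None and len(hv):
        cs = build_clusters(hv, annotation, gap=config.cluster_gap_bp)
        declustered = decluster(cs, seed=config.seed)
        hio.write_cluster_set(cs, annotation, outdir / "hvcpg_clusters.bed",
                              outdir / "hvcpg_cluster_membership.tsv")
        hio.write_id_list(declustered, outdir / "hvcpgs_declustered.txt")
        stage("clusters", n_clusters=cs.n_clusters, n_singletons=cs.n_singletons,
              n_declustered=len(declustered))

    # --- optional set enrichment ------------------------------------------
    if config.published_sets and match is not None and len(match.pairs):
        sets = {name: hio.read_id_list(p) for name, p in config.published_sets.items()}
        report = set_overlap_report(hv, sets, match.pairs["control"],
                                    background=array_background_ids(result))
        report.to_csv(outdir / "set_enrichment.tsv", sep="\t")
        stage("enrichment", n_sets_tested=len(report))

    # --- manifest ----------------------------------------------------------
    if truth is not None:
        truth.labels.to_csv(outdir / "ground_truth.tsv", sep="\t")
    manifest["stages"] = events
    manifest["outputs"] = {
        p.name: _sha256(p) for p in sorted(outdir.iterdir()) if p.is_file() and p.name != "manifest.json"
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return outdir
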