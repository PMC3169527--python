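"""End-to-end orchestration: simulate (or load) -> normalize -> fit ->
respond -> couple -> cluster, with a manifest recording provenance.

The configuration is a plain YAML mapping.  Either a ``simulate`` block
(genome size, class counts, seeds, model constants) or an ``inputs`` block
(paths to existing TSV matrices) must be present; thresholds default to the
study's values (responsiveness fold change 1.75, fit R^2 0.9, stability
ratio 1.5, k = 3 clusters).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as cluster_mod
from . import coupling as coupling_mod
from . import response as response_mod
from .containers import ExpressionMatrix, StudyBundle
from .halflife import ExponentialDecayModel, stability_change
from .imprinting import ImprintingModelParams
from .normalize import ReferenceDecayProfile, reference_scale, zero_transform
from .simulate import GenomeDesign, MutantDesign, ObservationParams, generate_study

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Thresholds, seeds, and either simulation parameters or input paths."""

    outdir: str = "pipeline_out"
    seed: int = 0
    fc_threshold: float = 1.75
    rsq_threshold: float = 0.9
    hl_threshold: float = 1.5
    k_clusters: int = 3
    reference_halflife: float = 20.0  # min; genome-mean reference decay profile
    simulate: dict | None = None
    inputs: dict | None = None

    def __post_init__(self) -> None:
        for name in ("fc_threshold", "rsq_threshold", "hl_threshold", "k_clusters"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.simulate is None and self.inputs is None:
            raise ValueError("config needs either a 'simulate' or an 'inputs' block")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "outdir": self.outdir, "seed": self.seed,
            "fc_threshold": self.fc_threshold, "rsq_threshold": self.rsq_threshold,
            "hl_threshold": self.hl_threshold, "k_clusters": self.k_clusters,
            "reference_halflife": self.reference_halflife,
            "simulate": self.simulate, "inputs": self.inputs,
        }

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _bundle_from_config(config: PipelineConfig) -> StudyBundle:
    if config.simulate is not None:
        sim = dict(config.simulate)
        design = GenomeDesign(**sim.get("genome", {}))
        model_params = ImprintingModelParams(**sim.get("model", {}))
        obs = ObservationParams(**sim.get("observation", {}))
        mutant = MutantDesign(**sim.get("mutant", {}))
        return generate_study(design, model_params, obs, mutant, seed=config.seed)
    bundle = StudyBundle()
    inputs = config.inputs or {}
    for key in ("wild_type", "mutant"):
        strain_in = inputs.get(key)
        if strain_in is None:
            raise FileNotFoundError(f"inputs block missing strain {key!r}")
        for condition in ("reference", "oxidative"):
            path = strain_in.get(f"{condition}_decay")
            if path is None or not Path(path).exists():
                raise FileNotFoundError(
                    f"missing decay input for {key}/{condition}: {path}"
                )
            bundle.decay[(key, condition)] = ExpressionMatrix.from_tsv(
                path, strain=key, condition=condition, experiment="decay"
            )
        path = strain_in.get("abundance")
        if path is None or not Path(path).exists():
            raise FileNotFoundError(f"missing abundance input for {key}: {path}")
        bundle.abundance[key] = ExpressionMatrix.from_tsv(
            path, strain=key, condition="oxidative", experiment="abundance"
        )
    return bundle


@dataclass
class PipelineResult:
    """Everything run_all computes, plus the output manifest."""

    bundle: StudyBundle
    decay_fits: dict
    stability: dict
    responses: dict
    coupling: dict
    enrichment: dict
    clusters: cluster_mod.ClusterResult | None
    cluster_slopes: list
    basal: coupling_mod.BasalComparison | None
    manifest: dict = field(default_factory=dict)


def run_all(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write all tables under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = _bundle_from_config(config)
    files: list[str] = []

    # --- normalize + fit half-lives per strain/condition -----------------
    decay_fits: dict = {}
    for (strain, condition), mat in sorted(bundle.decay.items()):
        ref = ReferenceDecayProfile.exponential(mat.times, config.reference_halflife)
        scaled = reference_scale(mat, ref)
        log2 = zero_transform(scaled)
        fit = ExponentialDecayModel(log2).fit(rsq_threshold=config.rsq_threshold)
        decay_fits[(strain, condition)] = fit
        name = f"halflives_{strain}_{condition}.tsv"
        fit.to_tsv(outdir / name)
        files.append(name)

    # --- stability changes ----------------------------------------------
    stability: dict = {}
    for strain in ("wild_type", "mutant"):
        key_ref, key_str = (strain, "reference"), (strain, "oxidative")
        if key_ref in decay_fits and key_str in decay_fits:
            table = stability_change(decay_fits[key_ref].records,
                                     decay_fits[key_str].records)
            stability[strain] = table
            name = f"stability_change_{strain}.tsv"
            table.to_csv(outdir / name, sep="\t", index=False)
            files.append(name)

    # --- abundance responses ---------------------------------------------
    responses: dict = {}
    for strain, mat in sorted(bundle.abundance.items()):
        log2 = zero_transform(mat)
        table = response_mod.profile_responses(log2, config.fc_threshold)
        responses[strain] = table
        name = f"responses_{strain}.tsv"
        table.to_csv(outdir / name, sep="\t", index=False)
        files.append(name)

    # --- coupling + enrichment -------------------------------------------
    coupling_res: dict = {}
    enrichment: dict = {}
    for strain in stability:
        if strain not in responses:
            continue
        stab, resp = stability[strain], responses[strain]
        common = stab.index.intersection(resp.index)
        model = coupling_mod.CouplingModel(resp.loc[common, "max_fc"],
                                           stab.loc[common, "delta"])
        coupling_res[strain] = {
            "all": model.fit(),
            "responsive": coupling_mod.CouplingModel.from_tables(
                stab, resp, responsive_only=True
            ).fit(),
        }
        labels = coupling_mod.classify_changes(
            resp.loc[common, "max_fc"], stab.loc[common, "delta"],
            config.fc_threshold, config.hl_threshold,
        )
        enrichment[strain] = coupling_mod.fold_enrichment(
            labels, {"fc": config.fc_threshold, "hl": config.hl_threshold}
        )

    # --- clustering -------------------------------------------------------
    clusters = None
    cluster_slopes: list = []
    if "wild_type" in responses and "mutant" in bundle.abundance:
        wt_log2 = zero_transform(bundle.abundance["wild_type"])
        mut_log2 = zero_transform(bundle.abundance["mutant"])
        shared = [g for g in wt_log2.gene_ids if g in set(mut_log2.gene_ids)]
        wt_log2, mut_log2 = wt_log2.select_genes(shared), mut_log2.select_genes(shared)
        mask = responses["wild_type"]["responsive"]
        if int(mask.reindex(shared).fillna(False).sum()) >= config.k_clusters:
            clusters = cluster_mod.cluster_profiles(
                wt_log2, mut_log2, mask, k=config.k_clusters
            )
            name = "clusters.tsv"
            clusters.assignments.to_csv(outdir / name, sep="\t")
            (outdir / "dendrogram.nwk").write_text(clusters.to_newick())
            files += [name, "dendrogram.nwk"]
            if "wild_type" in stability and "mutant" in stability:
                cluster_slopes = cluster_mod.cluster_stability_slopes(
                    clusters, stability["wild_type"], stability["mutant"]
                )

    # --- basal comparison (simulated bundles carry spike-ins) -------------
    basal = None
    wt_key, mut_key = ("wild_type", "reference"), ("mutant", "reference")
    if (wt_key in bundle.decay and mut_key in bundle.decay
            and ("wild_type", "reference", "decay") in bundle.spike_ins):
        wt_mat, mut_mat = bundle.decay[wt_key], bundle.decay[mut_key]
        wt_rec = decay_fits[wt_key].passed
        mut_rec = decay_fits[mut_key].passed
        basal = coupling_mod.basal_comparison(
            wt_mat.values[:, 0], mut_mat.values[:, 0],
            bundle.spike_ins[("wild_type", "reference", "decay")][0],
            bundle.spike_ins[("mutant", "reference", "decay")][0],
            wt_rec["halflife"], mut_rec["halflife"],
            gene_ids=wt_mat.gene_ids,
        )
        name = "basal_comparison.tsv"
        basal.table.to_csv(outdir / name, sep="\t")
        files.append(name)

    # --- summaries + manifest ---------------------------------------------
    summary = {
        "coupling": {
            s: {k: v.to_dict() for k, v in d.items()} for s, d in coupling_res.items()
        },
        "enrichment": {
            s: t.cells.to_dict(orient="records") for s, t in enrichment.items()
        },
        "cluster_slopes": [f.to_dict() for f in cluster_slopes],
        "basal_median_abundance_shift":
            None if basal is None else basal.median_abundance_shift,
        "pass_fractions": {
            f"{s}_{c}": decay_fits[(s, c)].pass_fraction for (s, c) in decay_fits
        },
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    files.append("summary.json")

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.digest(),
        "seed": config.seed,
        "files": sorted(files),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return PipelineResult(
        bundle=bundle, decay_fits=decay_fits, stability=stability,
        responses=responses, coupling=coupling_res, enrichment=enrichment,
        clusters=clusters, cluster_slopes=cluster_slopes, basal=basal,
        manifest=manifest,
    )
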