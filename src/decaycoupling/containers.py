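"""Tabular containers shared across the pipeline.

The central object is :class:`ExpressionMatrix`, a genes x time-points
matrix tagged with the metadata the analysis needs to route it correctly:
which strain it came from, which condition (unstressed reference vs. a
stress), which experiment type (decay course after transcription arrest
vs. conventional abundance course), and on which scale the values live
(linear hybridization intensities vs. log2 ratios to the first time point).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

STRAINS = ("wild_type", "mutant")
CONDITIONS = ("reference", "oxidative", "mms_like")
EXPERIMENTS = ("decay", "abundance")
SCALES = ("linear_intensity", "log2_to_t0")


@dataclass
class ExpressionMatrix:
    """Genes x time-points expression values plus experiment metadata.

    Parameters
    ----------
    gene_ids : sequence of str
        Row labels.
    times : array-like of float
        Sampling times in minutes, strictly increasing.
    values : ndarray, shape (n_genes, n_times)
        Expression values on the scale given by ``scale``.
    strain, condition, experiment, scale : str
        Metadata tags; see module constants for the allowed vocabulary.
    """

    gene_ids: list[str]
    times: np.ndarray
    values: np.ndarray
    strain: str = "wild_type"
    condition: str = "reference"
    experiment: str = "decay"
    scale: str = "linear_intensity"

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (genes x times)")
        if self.values.shape != (len(self.gene_ids), self.times.size):
            raise ValueError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.gene_ids)} genes x {self.times.size} times"
            )
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        for name, value, allowed in (
            ("strain", self.strain, STRAINS),
            ("condition", self.condition, CONDITIONS),
            ("experiment", self.experiment, EXPERIMENTS),
            ("scale", self.scale, SCALES),
        ):
            if value not in allowed:
                raise ValueError(f"unknown {name} {value!r}; expected one of {allowed}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def copy_with(self, **changes) -> "ExpressionMatrix":
        """Return a copy with ``values`` (and/or metadata) replaced."""
        out = replace(self, **changes)
        if "values" not in changes:
            out.values = self.values.copy()
        return out

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{t:g}" for t in self.times]
        return pd.DataFrame(self.values, index=pd.Index(self.gene_ids, name="gene_id"), columns=cols)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, **meta) -> "ExpressionMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        times = np.array([float(c) for c in frame.columns])
        return cls(list(frame.index.astype(str)), times, frame.to_numpy(dtype=float), **meta)

    def select_genes(self, gene_ids) -> "ExpressionMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in gene_ids]
        return self.copy_with(gene_ids=list(gene_ids), values=self.values[rows])


@dataclass
class StudyBundle:
    """The full two-strain, three-experiment design in one object.

    ``decay[(strain, condition)]`` and ``abundance[strain]`` hold observed
    (or noiseless) matrices; ``truth`` carries the generator's ground-truth
    table when the bundle was simulated.
    """

    decay: dict = field(default_factory=dict)
    abundance: dict = field(default_factory=dict)
    spike_ins: dict = field(default_factory=dict)
    truth: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> dict:
        """Write every matrix as TSV plus a JSON manifest; returns the manifest."""
        import json

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest: dict = {"files": [], "meta": _jsonable(self.meta)}
        for (strain, condition), mat in sorted(self.decay.items()):
            name = f"decay_{strain}_{condition}.tsv"
            mat.to_tsv(outdir / name)
            manifest["files"].append(
                {"path": name, "strain": strain, "condition": condition,
                 "experiment": "decay", "scale": mat.scale}
            )
        for strain, mat in sorted(self.abundance.items()):
            name = f"abundance_{strain}.tsv"
            mat.to_tsv(outdir / name)
            manifest["files"].append(
                {"path": name, "strain": strain, "condition": mat.condition,
                 "experiment": "abundance", "scale": mat.scale}
            )
        for key, vec in sorted(self.spike_ins.items()):
            name = "spikein_" + "_".join(key) + ".tsv"
            pd.Series(vec).to_csv(outdir / name, sep="\t", header=False)
            manifest["files"].append({"path": name, "kind": "spike_in", "key": list(key)})
        if self.truth is not None:
            self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
            manifest["files"].append({"path": "truth.tsv", "kind": "truth"})
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        def _key(k):
            if isinstance(k, tuple):
                return "_".join(map(str, k))
            return k if isinstance(k, str) else str(k)
        return {_key(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
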