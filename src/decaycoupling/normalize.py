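"""Bespoke normalizations for transcription-arrest decay courses.

Two procedures live here.

``reference_scale``
    Decay courses measured after a global transcription arrest cannot be
    normalized against spike-in controls, because the arrest drug
    (1,10-phenanthroline) inhibits all RNA polymerases including the one
    transcribing the control.  Instead each array (time point) is rescaled so
    that the genome-mean intensity follows a prescribed reference decay
    profile.  The scaling is per-column and monotone, so within-array gene
    rankings are untouched; absolute decay rates are pinned to the reference,
    which centers between-condition global differences on zero.

``spike_in_normalize``
    For basal (t=0, pre-arrest) abundance comparisons between strains,
    arrays are scaled to a constant internal-standard intensity.  Unlike
    rank/quantile normalization this preserves true global differences in
    mean mRNA level between samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass
class ReferenceDecayProfile:
    """Expected genome-mean intensity at each decay time point.

    Only the shape matters: the profile is rescaled to the data's own t=0
    genome mean before use.  Values must be positive and non-increasing.
    """

    times: np.ndarray
    mean_intensity: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.mean_intensity = np.asarray(self.mean_intensity, dtype=float)
        if self.times.shape != self.mean_intensity.shape:
            raise ValueError("times and mean_intensity must have equal length")
        if np.any(self.mean_intensity <= 0):
            raise ValueError("reference profile must be strictly positive")
        if np.any(np.diff(self.mean_intensity) > 0):
            raise ValueError("reference profile must be non-increasing")

    @classmethod
    def exponential(cls, times, halflife: float = 20.0, scale: float = 1.0
                    ) -> "ReferenceDecayProfile":
        """Genome-mean decay as a single exponential with the given half-life (min)."""
        times = np.asarray(times, dtype=float)
        return cls(times, scale * 0.5 ** (times / halflife))

    @classmethod
    def from_matrix(cls, matrix: ExpressionMatrix) -> "ReferenceDecayProfile":
        """Take the genome-mean profile of a (noiseless) matrix as reference."""
        mean = matrix.values.mean(axis=0)
        return cls(matrix.times, np.minimum.accumulate(mean))

    def at(self, times) -> np.ndarray:
        """Reference values at ``times``, log-linearly interpolated if needed."""
        times = np.asarray(times, dtype=float)
        if times.shape == self.times.shape and np.allclose(times, self.times):
            return self.mean_intensity.copy()
        if times.min() < self.times.min() or times.max() > self.times.max():
            raise ValueError("requested times outside the reference profile range")
        return np.exp(np.interp(times, self.times, np.log(self.mean_intensity)))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"time_min": self.times, "mean_intensity": self.mean_intensity}).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReferenceDecayProfile":
        frame = pd.read_csv(path, sep="\t")
        return cls(frame.iloc[:, 0].to_numpy(), frame.iloc[:, 1].to_numpy())


def reference_scale(matrix: ExpressionMatrix, ref: ReferenceDecayProfile
                    ) -> ExpressionMatrix:
    """Rescale each array so the genome mean follows the reference profile.

    Column ``t`` is multiplied by
    ``c_t = ref(t) * (mean_0 / ref(0)) / mean_t`` where ``mean_t`` is the
    genome-mean intensity of column ``t``; afterwards the genome mean decays
    exactly along the (t0-rescaled) reference.  ``c_0`` is 1 by construction
    and the operation is idempotent.
    """
    if matrix.scale != "linear_intensity":
        raise ValueError("reference_scale expects linear intensities")
    col_means = matrix.values.mean(axis=0)
    if np.any(col_means <= 0):
        raise ValueError("zero or negative column mean; cannot reference-scale")
    expected = ref.at(matrix.times)
    c = expected * (col_means[0] / expected[0]) / col_means
    return matrix.copy_with(values=matrix.values * c[None, :])


def zero_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log2-transform each profile relative to its first time point.

    Genes with any non-positive intensity cannot be log-transformed; they are
    dropped with a logged count (the estimation stage never imputes).
    """
    if matrix.scale != "linear_intensity":
        raise ValueError("zero_transform expects linear intensities")
    ok = np.all(matrix.values > 0, axis=1)
    if not np.all(ok):
        log.warning("zero_transform: dropping %d gene(s) with non-positive values",
                    int((~ok).sum()))
    values = matrix.values[ok]
    log2 = np.log2(values / values[:, [0]])
    gene_ids = [g for g, keep in zip(matrix.gene_ids, ok) if keep]
    return matrix.copy_with(gene_ids=gene_ids, values=log2, scale="log2_to_t0")


def spike_in_normalize(columns: np.ndarray, spike_in: np.ndarray,
                       reference_level: float | None = None) -> np.ndarray:
    """Scale array columns to a constant internal-standard intensity.

    Parameters
    ----------
    columns : ndarray, shape (n_genes, n_arrays) or (n_genes,)
    spike_in : one observed spike-in intensity per array
    reference_level : target spike level; defaults to the first array's.

    Each column ``j`` is multiplied by ``reference_level / spike_in[j]``,
    which undoes global array scale distortions while preserving true
    between-sample differences in mean mRNA level.
    """
    columns = np.asarray(columns, dtype=float)
    one_d = columns.ndim == 1
    cols = columns[:, None] if one_d else columns
    spike = np.atleast_1d(np.asarray(spike_in, dtype=float))
    if spike.size != cols.shape[1]:
        raise ValueError("need one spike-in value per column")
    if np.any(spike <= 0):
        raise ValueError("spike-in intensities must be > 0")
    if reference_level is None:
        reference_level = spike[0]
    out = cols * (reference_level / spike)[None, :]
    return out[:, 0] if one_d else out
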