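"""Synthetic microarray-like observations and the one-call study generator.

The observation layer converts true copy numbers into intensity measurements
with the distortions a real array series carries: multiplicative log-normal
measurement noise per value and a global multiplicative scale distortion per
array (time point).  A constant-abundance spike-in control is observed
through the same distortions, so spike-in normalization can undo them.

``generate_study`` reproduces the full experimental design: for each of two
strains (wild type and a reduced-recruitment mutant) it simulates a reference
decay course, a stress decay course and a stress abundance course, observes
each, and returns the bundle together with the ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, StudyBundle
from .imprinting import (
    ABUNDANCE_SAMPLE_TIMES,
    DECAY_SAMPLE_TIMES,
    DEFAULT_ARREST_DELAY,
    ConstantProfile,
    GeneKineticParams,
    ImprintingModel,
    ImprintingModelParams,
    PulseProfile,
    StepProfile,
)

log = logging.getLogger(__name__)


@dataclass
class ObservationParams:
    """Distortions applied between true copy numbers and measured intensities.

    noise_sd is the standard deviation (log2 units) of multiplicative
    log-normal measurement noise; array_scale_factors are per-time-point
    global multiplicative distortions (drawn log-normally with
    ``scale_sd`` log2 units when not given explicitly).  The spike-in
    intensity reported per array is the mean over ``spike_n_probes``
    independent control probes (a single summary value, but with the
    correspondingly reduced measurement noise).
    """

    noise_sd: float = 0.15
    array_scale_factors: np.ndarray | None = None
    scale_sd: float = 0.2
    spike_in_level: float = 100.0
    spike_n_probes: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.array_scale_factors is not None:
            self.array_scale_factors = np.asarray(self.array_scale_factors, dtype=float)
            if np.any(self.array_scale_factors <= 0):
                raise ValueError("array scale factors must be > 0")


def observe(truth: ExpressionMatrix, params: ObservationParams):
    """Observe a truth matrix through the array distortion model.

    Returns
    -------
    observed : ExpressionMatrix (linear_intensity)
    spike_in : ndarray, one observed spike-in intensity per time point
    """
    if np.any(truth.values < 0):
        raise ValueError("truth values must be >= 0")
    rng = np.random.default_rng(params.seed)
    n_times = truth.times.size
    scales = params.array_scale_factors
    if scales is None:
        scales = 2.0 ** rng.normal(0.0, params.scale_sd, size=n_times)
    elif scales.size != n_times:
        raise ValueError(
            f"{scales.size} scale factors for {n_times} time points"
        )
    eps = rng.normal(0.0, params.noise_sd, size=truth.values.shape)
    observed = truth.values * scales[None, :] * 2.0 ** eps
    spike_eps = rng.normal(0.0, params.noise_sd,
                           size=(max(params.spike_n_probes, 1), n_times))
    spike = (params.spike_in_level * scales * 2.0 ** spike_eps).mean(axis=0)
    return truth.copy_with(values=observed), spike


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

@dataclass
class GenomeDesign:
    """Composition and kinetic distributions of a simulated genome.

    Class counts default to 300 induced / 400 neutral / 300 repressed.
    Basal transcription rates are log-normal; induced genes start from a
    lower basal rate (stress genes tend to be lowly expressed before
    induction).  The per-gene imprinting affinity is uniform on
    ``affinity_range``.  Response magnitudes are heterogeneous: each
    responsive gene's multiplier is drawn log-normally around the class
    default (``multiplier_log2_sd`` log2 units), matching the wide range of
    induction/repression depths a real stress transcriptome shows.
    """

    n_induced: int = 300
    n_neutral: int = 400
    n_repressed: int = 300
    beta_log2_mean: float = 1.0
    beta_log2_sd: float = 0.8
    induced_beta_factor: float = 0.25
    affinity_range: tuple[float, float] = (0.35, 1.0)
    induced_multiplier: float = 8.0
    repressed_multiplier: float = 0.125
    multiplier_log2_sd: float = 0.8
    pulse_tau_on: float = 2.0
    pulse_tau_off: float = 15.0
    repressed_tau_off: float = 25.0
    sustained: bool = False  # True -> step profiles (MMS-like) instead of pulses

    @property
    def n_genes(self) -> int:
        return self.n_induced + self.n_neutral + self.n_repressed


def make_genome(design: GenomeDesign | None = None, *, seed: int = 0,
                strain_recruitment: float = 1.0,
                beta_multipliers: np.ndarray | None = None) -> list[GeneKineticParams]:
    """Draw a genome of :class:`GeneKineticParams` from a design.

    The same ``seed`` yields the same gene parameters, so a wild-type and a
    mutant genome differing only in ``strain_recruitment`` (and optionally
    per-gene ``beta_multipliers``) can be built for the same genes.
    """
    design = design or GenomeDesign()
    rng = np.random.default_rng(seed)
    n = design.n_genes
    beta = 2.0 ** rng.normal(design.beta_log2_mean, design.beta_log2_sd, size=n)
    affinity = rng.uniform(*design.affinity_range, size=n)
    classes = (
        ["induced"] * design.n_induced
        + ["neutral"] * design.n_neutral
        + ["repressed"] * design.n_repressed
    )
    # per-gene response magnitudes, log-normal around the class default
    up_mult = design.induced_multiplier * 2.0 ** rng.normal(
        0.0, design.multiplier_log2_sd, size=design.n_induced
    )
    down_mult = design.repressed_multiplier * 2.0 ** rng.normal(
        0.0, design.multiplier_log2_sd, size=design.n_repressed
    )
    if design.sustained:
        up: object = StepProfile(up_mult)
        down: object = StepProfile(down_mult)
    else:
        up = PulseProfile(up_mult, design.pulse_tau_on, design.pulse_tau_off)
        down = PulseProfile(down_mult, design.pulse_tau_on, design.repressed_tau_off)
    flat = ConstantProfile()
    profiles = {"induced": up, "neutral": flat, "repressed": down}
    if beta_multipliers is None:
        beta_multipliers = np.ones(n)
    genes = []
    for i, cls in enumerate(classes):
        b = beta[i] * beta_multipliers[i]
        if cls == "induced":
            b *= design.induced_beta_factor
        genes.append(
            GeneKineticParams(
                gene_id=f"g{i:04d}",
                beta_basal=b,
                stress_class=cls,
                phi=profiles[cls],
                affinity=affinity[i],
                strain_recruitment=strain_recruitment,
            )
        )
    return genes


# ---------------------------------------------------------------------------
# full-study generator
# ---------------------------------------------------------------------------

@dataclass
class MutantDesign:
    """How the mutant strain differs from wild type.

    ``recruitment`` (rho) scales the effective imprinting probability.
    ``attenuation`` is the target median basal mRNA abundance of the mutant
    relative to wild type; the generator calibrates per-gene transcription
    rates so the realized steady-state median matches it.
    ``attenuation_affinity_coupling`` (gamma) spreads the production defect
    across genes in proportion to imprinting affinity — genes that rely most
    on Rpb4/7 recruitment lose the most production — with zero keeping the
    defect uniform.
    """

    recruitment: float = 0.4
    attenuation: float = 0.7
    attenuation_affinity_coupling: float = 0.6


def generate_study(
    design: GenomeDesign | None = None,
    model_params: ImprintingModelParams | None = None,
    obs_params: ObservationParams | None = None,
    mutant: MutantDesign | None = None,
    *,
    seed: int = 0,
    arrest_delay: float = DEFAULT_ARREST_DELAY,
    outdir=None,
) -> StudyBundle:
    """Simulate and observe the full two-strain, three-experiment study.

    Returns a :class:`StudyBundle` holding six decay matrices (two strains x
    {reference, oxidative, mms_like} conditions), two stress abundance
    matrices, spike-in vectors for every array series, and a truth table with
    per-gene class, kinetic parameters, and ground-truth half-lives per
    strain and condition.  If ``outdir`` is given everything is also written
    there as TSV plus a JSON manifest.
    """
    design = design or GenomeDesign()
    model_params = model_params or ImprintingModelParams()
    obs_params = obs_params or ObservationParams()
    mutant = mutant or MutantDesign()

    wt_genes = make_genome(design, seed=seed, strain_recruitment=1.0)
    affinity = np.array([g.affinity for g in wt_genes])

    # per-gene production defect, affinity-coupled and median-calibrated so
    # the realized basal abundance ratio (production x stability effects)
    # matches the requested attenuation
    gamma = mutant.attenuation_affinity_coupling
    rel = 2.0 ** (-gamma * (affinity - np.median(affinity)))
    wt_model = ImprintingModel(wt_genes, model_params)
    wt_ss = wt_model.steady_state().total
    # fixed-point calibration: the steady state responds slightly
    # nonlinearly to a global beta rescaling (machinery redistribution), so
    # iterate the global factor until the realized median basal abundance
    # ratio matches the requested attenuation
    correction = 1.0
    for _ in range(3):
        mut_genes = make_genome(
            design, seed=seed, strain_recruitment=mutant.recruitment,
            beta_multipliers=rel * correction,
        )
        mut_model = ImprintingModel(mut_genes, model_params)
        mut_ss = mut_model.steady_state().total
        realized = np.median(mut_ss / wt_ss)
        if abs(np.log2(realized / mutant.attenuation)) < 1e-4:
            break
        correction *= mutant.attenuation / realized

    # MMS-like variants: identical kinetic draws but sustained (step) stress
    # transcription profiles
    mms_design = replace(design, sustained=True)
    wt_mms = ImprintingModel(make_genome(mms_design, seed=seed), model_params)
    mut_mms = ImprintingModel(
        make_genome(mms_design, seed=seed, strain_recruitment=mutant.recruitment,
                    beta_multipliers=rel * correction),
        model_params,
    )

    rng = np.random.default_rng(seed)
    bundle = StudyBundle()
    truth_cols: dict[str, np.ndarray] = {
        "gene_id": np.array([g.gene_id for g in wt_genes]),
        "stress_class": np.array([g.stress_class for g in wt_genes]),
        "affinity": affinity,
        "beta_wt": np.array([g.beta_basal for g in wt_genes]),
        "beta_mut": np.array([g.beta_basal for g in mut_genes]),
        "basal_abundance_wt": wt_ss,
    }

    mms_models = {"wild_type": wt_mms, "mutant": mut_mms}
    mean_profiles: dict = {}
    for strain, model in (("wild_type", wt_model), ("mutant", mut_model)):
        runs = (
            ("reference", model, "reference_decay"),
            ("oxidative", model, "stress_decay"),
            ("mms_like", mms_models[strain], "stress_decay"),
        )
        for condition, run_model, scenario in runs:
            res = run_model.run_scenario(scenario, DECAY_SAMPLE_TIMES, arrest_delay=arrest_delay)
            mat = res.matrix.copy_with(strain=strain, condition=condition)
            sub_seed = int(rng.integers(2**31 - 1))
            observed, spike = observe(mat, replace(obs_params, seed=sub_seed))
            bundle.decay[(strain, condition)] = observed
            bundle.spike_ins[(strain, condition, "decay")] = spike
            mean_profiles[(strain, condition)] = res.counts.mean(axis=0)
            key = {"reference": "ref", "oxidative": "stress", "mms_like": "mms"}[condition]
            truth_cols[f"true_halflife_{key}_{strain}"] = res.true_halflife.to_numpy()
            truth_cols[f"truth_t0_{key}_{strain}"] = res.counts[:, 0]
        res = model.run_scenario("stress_abundance", ABUNDANCE_SAMPLE_TIMES)
        mat = res.matrix.copy_with(strain=strain)
        sub_seed = int(rng.integers(2**31 - 1))
        observed, spike = observe(mat, replace(obs_params, seed=sub_seed))
        bundle.abundance[strain] = observed
        bundle.spike_ins[(strain, "oxidative", "abundance")] = spike
        # noiseless abundance trajectory for truth-level checks
        truth_cols[f"abundance_truth_{strain}"] = list(res.counts)

    truth = pd.DataFrame({k: v for k, v in truth_cols.items() if not k.startswith("abundance_truth")})
    bundle.truth = truth
    bundle.meta = {
        "seed": seed,
        "arrest_delay": arrest_delay,
        "n_genes": design.n_genes,
        "class_counts": {
            "induced": design.n_induced,
            "neutral": design.n_neutral,
            "repressed": design.n_repressed,
        },
        "model_params": vars(model_params).copy(),
        "obs_params": {
            "noise_sd": obs_params.noise_sd,
            "scale_sd": obs_params.scale_sd,
            "spike_in_level": obs_params.spike_in_level,
        },
        "mutant": vars(mutant).copy(),
        "abundance_truth": {
            s: np.asarray(truth_cols[f"abundance_truth_{s}"]) for s in ("wild_type", "mutant")
        },
        "abundance_times": np.asarray(ABUNDANCE_SAMPLE_TIMES),
        # noiseless genome-mean decay profiles, the analogue of the study's
        # externally measured reference decay profile
        "mean_decay_profiles": mean_profiles,
        "decay_times": np.asarray(DECAY_SAMPLE_TIMES),
    }
    if outdir is not None:
        bundle.write(outdir)
    return bundle
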