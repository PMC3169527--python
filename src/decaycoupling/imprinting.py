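"""Forward simulator of co-transcriptional mRNA imprinting kinetics.

The model: during transcription each new mRNA molecule is exported to the
cytoplasm either *imprinted* (associated with the Pol II subunits Rpb4/7)
with probability ``q_i = p(t) * affinity_i * rho_i`` or non-imprinted with
probability ``1 - q_i``.  Imprinted molecules recruit the general cytoplasmic
decay machinery; that machinery exists in a limited total amount ``D`` and is
distributed across genes in proportion to each gene's imprinted-copy
fraction ``f_i = I_i / (I_i + U_i)``.  Stress raises the genome-wide
imprinting probability from ``p_basal`` to ``p_stress``, which redistributes
the limited machinery toward genes whose mRNA pool turns over fastest —
induced genes — destabilizing them while repressed genes, starved of new
imprinted molecules, are stabilized.

Per gene ``i`` the deterministic copy-number dynamics are

    dI_i/dt = q_i(t) beta_i(t) - k_U I_i - min(D s_i, lambda_max I_i)
    dU_i/dt = (1 - q_i(t)) beta_i(t) - k_U U_i

with machinery shares ``s_i = f_i / sum_j f_j`` (0 when every pool is
empty), a basal first-order decay ``k_U`` acting on all molecules, and a
per-molecule cap ``lambda_max`` on machinery-mediated decay.  Integration is
explicit Euler; the model argues at the level of mean copy numbers, so a
deterministic scheme keeps the tests exact.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

LN2 = math.log(2.0)

#: Transcription-arrest decay courses are sampled at these minutes after the
#: arrest drug is added.
DECAY_SAMPLE_TIMES = (0.0, 5.0, 10.0, 20.0, 30.0, 40.0, 50.0)
#: Conventional abundance courses are sampled at these minutes after stress.
ABUNDANCE_SAMPLE_TIMES = (0.0, 5.0, 10.0, 15.0, 25.0, 35.0, 45.0)
#: Minutes between stress onset and transcription arrest in a stress-decay run.
DEFAULT_ARREST_DELAY = 7.0

STRESS_CLASSES = ("induced", "neutral", "repressed")


# ---------------------------------------------------------------------------
# stress transcription profiles
# ---------------------------------------------------------------------------

class StressProfile:
    """Dimensionless multiplier on the basal transcription rate.

    ``__call__(t)`` takes time since stress onset (min) and may be scalar or
    vector; before stress onset the multiplier is 1 by construction of the
    simulator.
    """

    def __call__(self, t):  # pragma: no cover - interface
        raise NotImplementedError


@dataclass(frozen=True)
class ConstantProfile(StressProfile):
    """No transcriptional response (neutral genes)."""

    def __call__(self, t):
        return np.ones_like(np.asarray(t, dtype=float))


class StepProfile(StressProfile):
    """Sustained response: multiplier jumps to ``multiplier`` and stays (MMS-like).

    ``multiplier`` may be a scalar or a vector (one value per gene sharing
    this profile object).
    """

    def __init__(self, multiplier=8.0):
        self.multiplier = np.asarray(multiplier, dtype=float)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return np.where(t >= 0.0, self.multiplier, 1.0)


class PulseProfile(StressProfile):
    """Transient drive: exponential onset then relaxation back to baseline.

    ``phi(t) = 1 + (multiplier - 1) * (1 - exp(-t/tau_on)) * exp(-t/tau_off)``
    so the drive rises with time constant ``tau_on``, peaks a few minutes in,
    and decays with ``tau_off`` (oxidative-stress-like kinetics).
    ``multiplier`` may be a scalar or a per-gene vector.
    """

    def __init__(self, multiplier=8.0, tau_on: float = 2.0, tau_off: float = 15.0):
        self.multiplier = np.asarray(multiplier, dtype=float)
        self.tau_on = tau_on
        self.tau_off = tau_off

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        shape = (1.0 - np.exp(-np.maximum(t, 0.0) / self.tau_on)) * np.exp(
            -np.maximum(t, 0.0) / self.tau_off
        )
        return np.where(t >= 0.0, 1.0 + (self.multiplier - 1.0) * shape, 1.0)


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class ImprintingModelParams:
    """Global constants of the imprinting model.

    Parameters
    ----------
    p_basal, p_stress : float
        Genome-wide imprinting probability before / after stress onset.
        For stress scenarios ``p_basal <= p_stress`` is required.
    D : float
        Total machinery-mediated degradation capacity (molecules/min)
        distributed across genes by imprinted-copy fraction.
    k_U : float
        Basal first-order decay rate (1/min) acting on every molecule.
    lambda_max : float
        Per-molecule cap (1/min) on machinery-mediated decay of imprinted
        molecules; the realized flux to gene i is ``min(D s_i, lambda_max I_i)``.
    stress_onset : float
        Time (min) at which p switches from p_basal to p_stress.
    dt : float
        Euler step (min).
    t_end : float
        Integration horizon (min).
    """

    p_basal: float = 0.3
    p_stress: float = 0.8
    D: float = 120.0
    k_U: float = 0.02
    lambda_max: float = 0.35
    stress_onset: float = 0.0
    dt: float = 0.05
    t_end: float = 120.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_basal <= 1.0 and 0.0 <= self.p_stress <= 1.0):
            raise ValueError("imprinting probabilities must lie in [0, 1]")
        if self.D < 0:
            raise ValueError("machinery pool D must be >= 0")
        if self.k_U <= 0:
            raise ValueError("basal decay rate k_U must be > 0")
        if self.dt <= 0:
            raise ValueError("integration step dt must be > 0")


@dataclass
class GeneKineticParams:
    """Per-gene ground-truth kinetic parameters.

    ``affinity`` scales the gene's effective imprinting probability;
    ``strain_recruitment`` (rho) is 1 for wild type and < 1 for a mutant with
    reduced ability to recruit Rpb4/7 onto transcripts.
    """

    gene_id: str
    beta_basal: float
    stress_class: str = "neutral"
    phi: StressProfile = field(default_factory=ConstantProfile)
    affinity: float = 0.7
    strain_recruitment: float = 1.0

    def __post_init__(self) -> None:
        if self.beta_basal < 0:
            raise ValueError("beta_basal must be >= 0")
        if self.stress_class not in STRESS_CLASSES:
            raise ValueError(f"unknown stress_class {self.stress_class!r}")
        if not 0.0 <= self.affinity * self.strain_recruitment <= 1.0:
            raise ValueError("affinity * strain_recruitment must lie in [0, 1]")


@dataclass
class ModelState:
    """Per-gene imprinted (I) and non-imprinted (U) copy counts at time t."""

    t: float
    I: np.ndarray
    U: np.ndarray

    def __post_init__(self) -> None:
        self.I = np.asarray(self.I, dtype=float)
        self.U = np.asarray(self.U, dtype=float)
        if self.I.shape != self.U.shape:
            raise ValueError("I and U must have the same shape")
        if np.any(self.I < 0) or np.any(self.U < 0):
            raise ValueError("copy counts must be non-negative")

    @property
    def total(self) -> np.ndarray:
        return self.I + self.U

    @property
    def imprinted_fraction(self) -> np.ndarray:
        """f_i = I_i/(I_i+U_i), defined as 0 for an empty pool."""
        tot = self.total
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(tot > 0, self.I / np.where(tot > 0, tot, 1.0), 0.0)
        return f


@dataclass
class ScenarioResult:
    """Output of :meth:`ImprintingModel.run_scenario`."""

    scenario: str
    sample_times: np.ndarray
    counts: np.ndarray  # genes x sample times, total copies I+U
    gene_ids: list[str]
    true_halflife: pd.Series | None = None  # decay scenarios only

    @property
    def matrix(self):
        from .containers import ExpressionMatrix

        condition = "reference" if self.scenario == "reference_decay" else "oxidative"
        experiment = "decay" if self.scenario.endswith("decay") else "abundance"
        return ExpressionMatrix(
            self.gene_ids, self.sample_times, self.counts,
            condition=condition, experiment=experiment, scale="linear_intensity",
        )


# ---------------------------------------------------------------------------
# machinery allocation
# ---------------------------------------------------------------------------

def machinery_shares(state: ModelState) -> np.ndarray:
    """Share of the decay-machinery pool allocated to each gene.

    Shares are proportional to each gene's imprinted-copy fraction,
    normalized over the genome; if every pool is empty all shares are 0.
    """
    f = state.imprinted_fraction
    total = f.sum()
    if total <= 0.0:
        return np.zeros_like(f)
    return f / total


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class ImprintingModel:
    """Deterministic forward model for a genome of genes.

    Parameters
    ----------
    genes : sequence of GeneKineticParams
    params : ImprintingModelParams

    Examples
    --------
    >>> genes = [GeneKineticParams("g1", beta_basal=1.0)]
    >>> model = ImprintingModel(genes, ImprintingModelParams(D=0.0))
    >>> res = model.run_scenario("reference_decay", sample_times=[0, 10, 20])
    >>> res.counts.shape
    (1, 3)
    """

    def __init__(self, genes, params: ImprintingModelParams):
        self.genes = list(genes)
        self.params = params
        self.gene_ids = [g.gene_id for g in self.genes]
        self._beta = np.array([g.beta_basal for g in self.genes], dtype=float)
        self._affinity = np.array([g.affinity for g in self.genes], dtype=float)
        self._rho = np.array([g.strain_recruitment for g in self.genes], dtype=float)
        self.stress_class = np.array([g.stress_class for g in self.genes])
        # group genes by identical profile object so phi is evaluated once
        # per distinct profile per step
        self._phi_groups: list[tuple[StressProfile, np.ndarray]] = []
        seen: dict[int, list[int]] = {}
        order: dict[int, StressProfile] = {}
        for idx, g in enumerate(self.genes):
            seen.setdefault(id(g.phi), []).append(idx)
            order[id(g.phi)] = g.phi
        for key, idxs in seen.items():
            self._phi_groups.append((order[key], np.array(idxs)))

    # -- time-dependent coefficients ------------------------------------

    def imprinting_probability(self, t: float) -> np.ndarray:
        """Effective per-gene imprinting probability q_i(t), clipped to [0, 1]."""
        p = self.params.p_basal if t < self.params.stress_onset else self.params.p_stress
        return np.clip(p * self._affinity * self._rho, 0.0, 1.0)

    def transcription_rate(self, t: float) -> np.ndarray:
        """beta_i(t) = beta_basal * phi_i(t - stress_onset)."""
        beta = self._beta.copy()
        tau = t - self.params.stress_onset
        if tau >= 0.0:
            mult = np.ones_like(beta)
            for phi, idxs in self._phi_groups:
                # a profile may be scalar- or vector-valued (one entry per
                # gene sharing the profile object, in gene order)
                mult[idxs] = np.asarray(phi(tau), dtype=float)
            beta *= mult
        return beta

    # -- integration -----------------------------------------------------

    def step(self, state: ModelState, *, transcription_on: bool = True) -> ModelState:
        """Advance the state by one Euler step of size ``params.dt``.

        Pools that would go negative are clipped to zero with a logged
        warning (the default dt is far below the stability limit for the
        default rates).
        """
        p = self.params
        q = self.imprinting_probability(state.t)
        beta = self.transcription_rate(state.t) if transcription_on else 0.0
        s = machinery_shares(state)
        machinery_flux = np.minimum(p.D * s, p.lambda_max * state.I)
        dI = q * beta - p.k_U * state.I - machinery_flux
        dU = (1.0 - q) * beta - p.k_U * state.U
        I_new = state.I + p.dt * dI
        U_new = state.U + p.dt * dU
        if np.any(I_new < 0) or np.any(U_new < 0):
            log.warning(
                "pool went negative at t=%.2f (dt too large?); clipping to 0", state.t
            )
            I_new = np.maximum(I_new, 0.0)
            U_new = np.maximum(U_new, 0.0)
        return ModelState(t=state.t + p.dt, I=I_new, U=U_new)

    def steady_state(self, *, tol: float = 1e-10, max_minutes: float = 4000.0) -> ModelState:
        """Relax the basal (pre-stress) system to its steady state.

        Integrates with stress and arrest switched off until the largest
        relative change per minute drops below ``tol``.  The result is
        cached; a fresh copy is returned on each call.
        """
        cached = getattr(self, "_steady_cache", None)
        if cached is not None:
            return ModelState(t=0.0, I=cached.I.copy(), U=cached.U.copy())
        q = np.clip(self.params.p_basal * self._affinity * self._rho, 0.0, 1.0)
        # machinery-free steady state as the starting guess
        I = q * self._beta / (self.params.k_U + self.params.lambda_max)
        U = (1.0 - q) * self._beta / self.params.k_U
        state = ModelState(t=-max_minutes, I=I, U=U)
        basal = replace(self.params, stress_onset=np.inf)
        frozen = ImprintingModel.__new__(ImprintingModel)
        frozen.__dict__ = {**self.__dict__, "params": basal}
        steps_per_check = max(1, int(round(5.0 / basal.dt)))
        for _ in range(int(max_minutes / (steps_per_check * basal.dt))):
            prev = state
            for _ in range(steps_per_check):
                state = frozen.step(state)
            scale = np.maximum(state.total, 1e-12)
            drift = np.max(np.abs(state.total - prev.total) / scale) / (
                steps_per_check * basal.dt
            )
            if drift < tol:
                break
        state.t = 0.0
        self._steady_cache = ModelState(t=0.0, I=state.I.copy(), U=state.U.copy())
        return state

    def _integrate(self, state: ModelState, t_stop: float, record_times,
                   *, arrest_time: float | None = None):
        """Euler-integrate to ``t_stop`` recording totals at ``record_times``."""
        record_times = np.asarray(record_times, dtype=float)
        recorded = np.empty((len(self.genes), record_times.size))
        next_rec = 0
        dt = self.params.dt
        n_steps = int(round(t_stop / dt))
        for istep in range(n_steps + 1):
            t = istep * dt
            state.t = t
            while next_rec < record_times.size and t >= record_times[next_rec] - dt / 2:
                recorded[:, next_rec] = state.total
                next_rec += 1
            if istep == n_steps:
                break
            on = arrest_time is None or t < arrest_time - dt / 2
            state = self.step(state, transcription_on=on)
        return state, recorded

    # -- scenarios --------------------------------------------------------

    def run_scenario(self, scenario: str, sample_times=None,
                     arrest_delay: float = DEFAULT_ARREST_DELAY) -> ScenarioResult:
        """Simulate one of the three experiment types.

        ``reference_decay``
            no stress; transcription arrested at t=0; sampled on the arrest
            clock (default 0,5,10,20,30,40,50 min).
        ``stress_decay``
            stress at t=0; transcription arrested ``arrest_delay`` minutes
            later; the sampling clock restarts at the arrest.
        ``stress_abundance``
            stress at t=0, no arrest; sampled at 0,5,10,15,25,35,45 min.

        Decay scenarios also return the ground-truth effective half-life:
        ln 2 over the least-squares slope of ln(copies) against time on the
        noiseless sampled trajectory.
        """
        if scenario not in ("reference_decay", "stress_decay", "stress_abundance"):
            raise ValueError(f"unknown scenario {scenario!r}")
        if sample_times is None:
            sample_times = (
                ABUNDANCE_SAMPLE_TIMES if scenario == "stress_abundance" else DECAY_SAMPLE_TIMES
            )
        sample_times = np.asarray(sample_times, dtype=float)

        offset = arrest_delay if scenario == "stress_decay" else 0.0
        horizon = offset + sample_times.max()
        if horizon > self.params.t_end:
            raise ValueError(
                f"sample time {sample_times.max():g} (+{offset:g} min arrest delay) "
                f"exceeds t_end={self.params.t_end:g}"
            )

        state = self.steady_state()
        if scenario == "reference_decay":
            run = self._without_stress()
            _, counts = run._integrate(state, horizon, sample_times, arrest_time=0.0)
        elif scenario == "stress_decay":
            _, counts = self._integrate(
                state, horizon, sample_times + offset, arrest_time=arrest_delay
            )
        else:
            _, counts = self._integrate(state, horizon, sample_times, arrest_time=None)

        truth = None
        if scenario.endswith("decay"):
            truth = pd.Series(
                true_halflife(counts, sample_times), index=self.gene_ids, name="true_halflife"
            )
        return ScenarioResult(scenario, sample_times, counts, list(self.gene_ids), truth)

    def _without_stress(self) -> "ImprintingModel":
        clone = ImprintingModel.__new__(ImprintingModel)
        clone.__dict__ = {**self.__dict__, "params": replace(self.params, stress_onset=np.inf)}
        return clone


def true_halflife(counts: np.ndarray, times: np.ndarray) -> np.ndarray:
    """ln2 / (least-squares slope of ln counts vs time), per gene.

    The simulated trajectories are not exactly single-exponential (the
    machinery term redistributes over time), so the effective half-life is
    defined as what a log-linear fit over the sampled window reports —
    the same functional the estimation pipeline targets.
    """
    from ._ols import loglinear_rates

    k, _ = loglinear_rates(np.log(np.maximum(counts, 1e-300)), np.asarray(times, float))
    k = -k
    with np.errstate(divide="ignore"):
        return np.where(k > 0, LN2 / np.where(k > 0, k, 1.0), np.inf)
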