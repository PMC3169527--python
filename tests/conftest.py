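"""Shared fixtures: simulated study bundles and derived analysis products.

The heavy fixtures are session-scoped; everything is generated
programmatically with fixed seeds, nothing is read from disk.
"""

from __future__ import annotations

import numpy as np
import pytest

from decaycoupling.halflife import ExponentialDecayModel, stability_change
from decaycoupling.imprinting import ImprintingModelParams
from decaycoupling.normalize import ReferenceDecayProfile, reference_scale, zero_transform
from decaycoupling.response import profile_responses
from decaycoupling.simulate import (
    GenomeDesign,
    MutantDesign,
    ObservationParams,
    generate_study,
)

#: canonical fixture seed, fixed a priori for the whole suite
SEED = 1


def small_design(n: int = 100) -> GenomeDesign:
    frac = n // 10
    return GenomeDesign(n_induced=3 * frac, n_neutral=n - 6 * frac, n_repressed=3 * frac)


def scaled_params(n: int, **overrides) -> ImprintingModelParams:
    """Model constants with the machinery pool scaled to genome size."""
    defaults = ImprintingModelParams()
    D = overrides.pop("D", defaults.D * n / 1000.0)
    return ImprintingModelParams(D=D, **overrides)


@pytest.fixture(scope="session")
def default_bundle():
    """The full-size (1000 genes) noisy two-strain study at the fixed seed."""
    return generate_study(
        GenomeDesign(), ImprintingModelParams(), ObservationParams(), MutantDesign(),
        seed=SEED,
    )


@pytest.fixture(scope="session")
def zero_noise_bundle():
    """Noise- and distortion-free variant of the default study."""
    return generate_study(
        GenomeDesign(), ImprintingModelParams(),
        ObservationParams(noise_sd=0.0, scale_sd=0.0), MutantDesign(),
        seed=SEED,
    )


@pytest.fixture(scope="session")
def null_bundle():
    """Same design but the imprinting probability does not change on stress."""
    return generate_study(
        GenomeDesign(), ImprintingModelParams(p_stress=0.3), ObservationParams(),
        MutantDesign(), seed=SEED,
    )


def analyse_decay(bundle, strain, reference_halflife=20.0):
    """reference-scale -> zero-transform -> fit, for both decay conditions."""
    fits = {}
    for cond in ("reference", "oxidative"):
        mat = bundle.decay[(strain, cond)]
        ref = ReferenceDecayProfile.exponential(mat.times, reference_halflife)
        fits[cond] = ExponentialDecayModel(
            zero_transform(reference_scale(mat, ref))
        ).fit()
    stab = stability_change(fits["reference"].records, fits["oxidative"].records)
    return fits, stab


@pytest.fixture(scope="session")
def default_analysis(default_bundle):
    """Half-life fits, stability changes and responses for both strains."""
    out = {}
    for strain in ("wild_type", "mutant"):
        fits, stab = analyse_decay(default_bundle, strain)
        out[strain] = {
            "fits": fits,
            "stability": stab,
            "responses": profile_responses(
                zero_transform(default_bundle.abundance[strain])
            ),
        }
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
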