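"""Seeded synthetic titration datasets with the study's replicate structure.

The generator is the generative twin of the fitted models: it draws
signals from the same dose-response curves and the same
absolute+relative Gaussian error model that the likelihood assumes, with
the replicate hierarchy of the experiments it emulates -- MST series of
3 biological x 5 technical replicates at a fixed 10 nM labelled-partner
concentration over a 16-point 2-fold dilution from 500 nM titrant, and
plate-based Ca2+ titrations spanning 0.34 uM to 8.0 mM with 3 biological
x 3-4 technical replicates.

Shared (biological) parameters are identical across biological
replicates; amplitudes are jittered +/-10% between replicates,
deterministically from the seed, mimicking preparation-to-preparation
variability. A spec plus its seed fully determines the dataset.

Presets carry the study conditions: dissociation constants of 3.1, 5.6,
14.6 and 28.2 nM for the four MST conditions (Ca2+/Mg2+ with and
without myristoylation) and Ca2+ EC50 values of 161.1 and 152.6 uM for
the hydrophobicity-probe (FPH) assay.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .likelihood import ErrorModelParams, GlobalParameterVector, TitrationDataset
from .models import (
    HillReplicateParams,
    MstReplicateParams,
    SharedBindingParams,
    hill_response,
    mst_response,
)

__all__ = ["SyntheticSpec", "generate", "true_parameters", "preset", "PRESETS"]

# MST defaults: 16-capillary 2-fold serial dilution from 500 nM brackets
# every preset KD with both asymptotes resolved.
MST_TOP = 500e-9
MST_DILUTION = 2.0
MST_N_DOSES = 16
# FPH dose list spans the stated titration range endpoints.
FPH_DOSE_RANGE = (0.34e-6, 8.0e-3)
FPH_N_DOSES = 12


def _mst_doses() -> tuple:
    return tuple(MST_TOP / MST_DILUTION**i for i in range(MST_N_DOSES))


def _fph_doses() -> tuple:
    return tuple(np.geomspace(*FPH_DOSE_RANGE, FPH_N_DOSES))


@dataclass(frozen=True)
class SyntheticSpec:
    """Fully-specified recipe for one synthetic dataset.

    ``n_tech`` may be a single count or one count per biological
    replicate. ``amp_jitter`` is the relative half-width of the uniform
    amplitude perturbation across biological replicates. Noise scales
    follow the error model of the likelihood (sigma_abs in signal units,
    sigma_rel dimensionless).
    """

    model_kind: str
    shared: SharedBindingParams
    doses: tuple
    n_bio: int = 3
    n_tech: tuple | int = 5
    Btot: float = 10e-9  # MST labelled-partner concentration (mol/L)
    # base amplitudes; per-replicate values are jittered around these
    Fn_B: float = 1.0
    Fn_AB: float = 0.5
    F0: float = 0.2
    Fmax: float = 1.0
    sigma_abs: float = 0.01
    sigma_rel: float = 0.0
    amp_jitter: float = 0.10
    seed: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        if self.model_kind not in ("mst", "hill"):
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        if self.n_bio < 1:
            raise ValueError("n_bio must be >= 1")
        if min(self.tech_counts()) < 1:
            raise ValueError("n_tech must be >= 1")
        if any(d <= 0 for d in self.doses):
            raise ValueError("doses must be positive")

    def tech_counts(self) -> tuple:
        if isinstance(self.n_tech, int):
            return (self.n_tech,) * self.n_bio
        if len(self.n_tech) != self.n_bio:
            raise ValueError("n_tech tuple must have one entry per biological replicate")
        return tuple(self.n_tech)


def _jitter_rng(spec: SyntheticSpec) -> np.random.Generator:
    return np.random.default_rng([spec.seed, 101])


def _noise_rng(spec: SyntheticSpec) -> np.random.Generator:
    return np.random.default_rng([spec.seed, 202])


def true_parameters(spec: SyntheticSpec) -> GlobalParameterVector:
    """The exact generating parameters, including the jittered amplitudes.

    Reproducible from the spec alone (the jitter stream is independent of
    the noise stream), so simulation studies can compare estimates
    against the truth that actually generated each replicate.
    """
    rng = _jitter_rng(spec)
    per = {}
    err = ErrorModelParams(spec.sigma_abs, spec.sigma_rel)
    for i in range(spec.n_bio):
        label = f"bio{i + 1}"
        if spec.model_kind == "mst":
            f_b = spec.Fn_B * (1.0 + spec.amp_jitter * rng.uniform(-1, 1))
            f_ab = spec.Fn_AB * (1.0 + spec.amp_jitter * rng.uniform(-1, 1))
            per[label] = (MstReplicateParams(spec.Btot, f_b, f_ab), err)
        else:
            f0 = spec.F0 * (1.0 + spec.amp_jitter * rng.uniform(-1, 1))
            fmax = spec.Fmax * (1.0 + spec.amp_jitter * rng.uniform(-1, 1))
            per[label] = HillReplicateParams(f0, fmax)
    hill_noise = err if spec.model_kind == "hill" else None
    return GlobalParameterVector(spec.model_kind, spec.shared, per, hill_noise=hill_noise)


def generate(spec: SyntheticSpec) -> TitrationDataset:
    """Draw one dataset: model curve plus seeded Gaussian noise.

    One row per (biological replicate x technical replicate x dose);
    noise standard deviation is sqrt(sigma_abs^2 + (sigma_rel*f)^2) at
    the curve value f. With both noise scales zero every signal lies
    exactly on the generating curve. Identical spec+seed gives an
    identical dataset.
    """
    truth = true_parameters(spec)
    rng = _noise_rng(spec)
    doses = np.asarray(spec.doses, dtype=float)
    rows = []
    for i in range(spec.n_bio):
        label = f"bio{i + 1}"
        if spec.model_kind == "mst":
            rep, err = truth.per_replicate[label]
            curve = np.asarray(mst_response(truth.shared, rep, doses))
        else:
            rep = truth.per_replicate[label]
            err = truth.hill_noise
            curve = np.asarray(hill_response(truth.shared, rep, doses))
        sigma = np.sqrt(err.sigma_abs**2 + (err.sigma_rel * curve) ** 2)
        for t in range(spec.tech_counts()[i]):
            noise = rng.standard_normal(len(doses)) * sigma
            for d, s in zip(doses, curve + noise):
                rows.append((d, s, label, f"tech{t + 1}"))
    frame = pd.DataFrame(rows, columns=["dose", "signal", "bio_rep", "tech_rep"])
    meta = {"model_kind": spec.model_kind, "seed": spec.seed}
    if spec.name:
        meta["preset"] = spec.name
    return TitrationDataset(frame, metadata=meta)


def _mst_spec(kd: float, name: str) -> SyntheticSpec:
    return SyntheticSpec(
        model_kind="mst",
        shared=SharedBindingParams(KD=kd),
        doses=_mst_doses(),
        n_bio=3,
        n_tech=5,
        sigma_abs=0.02 * abs(1.0 - 0.5),  # 2% of the amplitude span
        sigma_rel=0.0,
        name=name,
    )


def _fph_spec(ec50: float, name: str) -> SyntheticSpec:
    return SyntheticSpec(
        model_kind="hill",
        shared=SharedBindingParams(EC50=ec50, n=1.5),
        doses=_fph_doses(),
        n_bio=3,
        n_tech=(4, 3, 3),
        sigma_abs=0.03 * 1.0,  # 3% of the base Fmax
        sigma_rel=0.0,
        name=name,
    )


PRESETS = {
    "mst_ca": lambda: _mst_spec(3.1e-9, "mst_ca"),
    "mst_mg": lambda: _mst_spec(14.6e-9, "mst_mg"),
    "mst_myr_ca": lambda: _mst_spec(5.6e-9, "mst_myr_ca"),
    "mst_myr_mg": lambda: _mst_spec(28.2e-9, "mst_myr_mg"),
    "fph": lambda: _fph_spec(161.1e-6, "fph"),
    "fph_myr": lambda: _fph_spec(152.6e-6, "fph_myr"),
}


def preset(name: str, seed: int = 0) -> SyntheticSpec:
    """Named study condition: MST Ca2+/Mg2+ (+/- myristoylation) or FPH."""
    try:
        spec = PRESETS[name]()
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None
    return replace(spec, seed=seed)
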