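"""Closed-form binding-curve models.

Two dose-response families are implemented:

* the exact one-site binding isotherm under ligand depletion, where the
  labelled partner concentration is comparable to the dissociation
  constant ``KD`` so the free-ligand approximation fails and the complex
  concentration must be obtained from the quadratic mass-action solution;
* the Hill equation for cooperative dose-response curves (used here for
  Ca2+ titrations read out by an environment-sensitive dye).

All concentrations are carried in mol/L throughout the package; signals
are in arbitrary fluorescence units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SharedBindingParams",
    "MstReplicateParams",
    "HillReplicateParams",
    "complex_concentration",
    "mst_response",
    "hill_response",
]


@dataclass(frozen=True)
class SharedBindingParams:
    """Globally shared (biological) parameters.

    For the depletion isotherm only ``KD`` is used; for the Hill model
    ``EC50`` and the Hill coefficient ``n``. Unused entries may be None.
    """

    KD: float | None = None
    EC50: float | None = None
    n: float | None = None

    def __post_init__(self) -> None:
        if self.KD is not None and not self.KD > 0:
            raise ValueError(f"KD must be > 0, got {self.KD}")
        if self.EC50 is not None and not self.EC50 > 0:
            raise ValueError(f"EC50 must be > 0, got {self.EC50}")
        if self.n is not None and not self.n > 0:
            raise ValueError(f"Hill coefficient n must be > 0, got {self.n}")


@dataclass(frozen=True)
class MstReplicateParams:
    """Per-biological-replicate parameters of the MST dose-response.

    Btot is the total labelled-partner concentration (mol/L, nominally
    10 nM); Fn_B and Fn_AB are the normalized thermophoresis signals of
    the free labelled partner and of the complex.
    """

    Btot: float
    Fn_B: float
    Fn_AB: float

    def __post_init__(self) -> None:
        if not self.Btot > 0:
            raise ValueError(f"Btot must be > 0, got {self.Btot}")
        if not (np.isfinite(self.Fn_B) and np.isfinite(self.Fn_AB)):
            raise ValueError("Fn_B and Fn_AB must be finite")
        if self.Fn_B == self.Fn_AB:
            warnings.warn(
                "Fn_B == Fn_AB: the dose-response is flat and KD is not "
                "identifiable from this replicate",
                stacklevel=2,
            )


@dataclass(frozen=True)
class HillReplicateParams:
    """Per-replicate amplitudes of the Hill curve.

    F0 is the signal without ligand; Fmax the maximal signal change
    (either sign: the direction of the change is data-determined).
    """

    F0: float
    Fmax: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.F0) and np.isfinite(self.Fmax)):
            raise ValueError("F0 and Fmax must be finite")


def _check_nonneg(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0) or np.any(~np.isfinite(arr)):
        raise ValueError(f"{name} must be non-negative and finite, got {value}")
    return arr


def complex_concentration(KD, Atot, Btot):
    """Equilibrium complex concentration AB of a 1:1 binding reaction.

    Solves the mass-action quadratic (Atot - AB)(Btot - AB) = KD * AB
    exactly, i.e. without the free-ligand approximation, so it remains
    correct in the ligand-depletion regime Btot ~ KD.

    The root is evaluated as ``2*Atot*Btot / (S + sqrt(S^2 - 4*Atot*Btot))``
    with ``S = KD + Atot + Btot``.  This is algebraically identical to the
    textbook form ``(S - sqrt(S^2 - 4*Atot*Btot)) / 2`` but avoids the
    catastrophic cancellation that destroys all precision of the textbook
    form when ``Atot*Btot << S^2`` (e.g. Atot << KD).

    Parameters are in mol/L; scalars or broadcastable arrays. Returns the
    complex concentration in mol/L, satisfying 0 <= AB <= min(Atot, Btot).
    """
    KD = _check_nonneg("KD", KD)
    Atot = _check_nonneg("Atot", Atot)
    Btot = _check_nonneg("Btot", Btot)
    s = KD + Atot + Btot
    prod = Atot * Btot
    disc = np.maximum(s * s - 4.0 * prod, 0.0)
    denom = s + np.sqrt(disc)
    with np.errstate(invalid="ignore"):
        ab = np.where(denom > 0.0, 2.0 * prod / np.where(denom > 0, denom, 1.0), 0.0)
    if ab.ndim == 0:
        return float(ab)
    return ab


def mst_response(shared: SharedBindingParams, rep: MstReplicateParams, Atot):
    """Normalized MST signal at total titrant concentration Atot.

    The observed thermophoresis is the bound-fraction-weighted mixture of
    the free-partner and complex signals:

        Fn = (B/Btot) * Fn_B + (AB/Btot) * Fn_AB,   B = Btot - AB.

    At Atot = 0 this returns exactly Fn_B; at saturation it approaches
    Fn_AB.
    """
    ab = complex_concentration(shared.KD, Atot, rep.Btot)
    frac = np.asarray(ab, dtype=float) / rep.Btot
    out = rep.Fn_B + frac * (rep.Fn_AB - rep.Fn_B)
    if np.ndim(Atot) == 0:
        return float(out)
    return out


def hill_response(shared: SharedBindingParams, rep: HillReplicateParams, c):
    """Hill dose-response F(c) = F0 + Fmax / (1 + (EC50/c)^n).

    At c = 0 the power (EC50/c)^n diverges; the response is defined by its
    limit F0 so the curve is continuous at zero dose.
    """
    c_arr = _check_nonneg("c", c)
    ec50, n = shared.EC50, shared.n
    if ec50 is None or n is None:
        raise ValueError("Hill model requires EC50 and n in SharedBindingParams")
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(c_arr > 0, ec50 / np.where(c_arr > 0, c_arr, 1.0), np.inf)
        out = rep.F0 + rep.Fmax / (1.0 + ratio**n)
    out = np.where(c_arr > 0, out, rep.F0)
    if np.ndim(c) == 0:
        return float(out)
    return out
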