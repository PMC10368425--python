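"""Replicate-hierarchical global model: parameter vector, error model, likelihood.

Biological quantities (KD, or EC50 and the Hill coefficient) are shared
across biological replicates; experimental amplitudes and, for MST, the
noise scales are individual per biological replicate. Technical
replicates are treated as independent observations under their
biological replicate's parameter set.

The observation model is Gaussian with a signal-dependent standard
deviation sigma(f) = sqrt(sigma_abs^2 + (sigma_rel*f)^2) evaluated at the
model prediction f (not the observation), combining an absolute and a
relative noise scale. The Hill model uses a single dose-independent
sigma_abs shared by all replicates of a condition (sigma_rel fixed at 0),
so that for three biological replicates the MST model has 1 + 5*3 = 16
free parameters and the Hill model 2 + 2*3 + 1 = 9.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import (
    HillReplicateParams,
    MstReplicateParams,
    SharedBindingParams,
    complex_concentration,
)

__all__ = [
    "ErrorModelParams",
    "TitrationDataset",
    "GlobalParameterVector",
    "ParameterLayout",
    "count_parameters",
    "error_sigma",
    "negative_log_likelihood",
    "build_layout",
    "make_objective",
]

LOG_2PI = math.log(2.0 * math.pi)

DATASET_COLUMNS = ("dose", "signal", "bio_rep", "tech_rep")


@dataclass(frozen=True)
class ErrorModelParams:
    """Two-parameter noise model: absolute plus relative Gaussian scales."""

    sigma_abs: float
    sigma_rel: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_abs < 0 or self.sigma_rel < 0:
            raise ValueError("noise scales must be >= 0")


def error_sigma(f, err: ErrorModelParams):
    """Standard deviation at model prediction f.

    sigma(f) = sqrt(sigma_abs^2 + (sigma_rel * f)^2); raises if both
    scales are zero (degenerate likelihood).
    """
    if err.sigma_abs == 0.0 and err.sigma_rel == 0.0:
        raise ValueError("degenerate error model: sigma_abs and sigma_rel both zero")
    out = np.sqrt(err.sigma_abs**2 + (err.sigma_rel * np.asarray(f, dtype=float)) ** 2)
    if np.ndim(f) == 0:
        return float(out)
    return out


class TitrationDataset:
    """Dose-response observations annotated by biological/technical replicate.

    Thin validated wrapper around a pandas DataFrame with columns
    ``dose`` (mol/L), ``signal`` (a.u.), ``bio_rep`` and ``tech_rep``
    (labels). Row order is preserved.
    """

    def __init__(self, frame: pd.DataFrame, metadata: dict | None = None):
        missing = [c for c in DATASET_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"dataset missing required column(s): {', '.join(missing)}")
        frame = frame.reset_index(drop=True)
        dose = pd.to_numeric(frame["dose"], errors="coerce")
        signal = pd.to_numeric(frame["signal"], errors="coerce")
        for name, col in (("dose", dose), ("signal", signal)):
            bad = col.index[col.isna()]
            if len(bad):
                raise ValueError(f"non-numeric {name} at row {bad[0]}")
        if (dose < 0).any():
            row = int(dose.index[dose < 0][0])
            raise ValueError(f"negative dose at row {row}")
        self.frame = pd.DataFrame(
            {
                "dose": dose.astype(float),
                "signal": signal.astype(float),
                "bio_rep": frame["bio_rep"].astype(str),
                "tech_rep": frame["tech_rep"].astype(str),
            }
        )
        self.metadata = dict(metadata or {})

    def check_identifiable(self) -> None:
        """Require >= 2 distinct doses per biological replicate.

        A single-dose series cannot constrain a dose-response curve;
        called by the fitting routine before optimization starts.
        """
        for label, grp in self.frame.groupby("bio_rep"):
            if grp["dose"].nunique() < 2:
                raise ValueError(
                    f"biological replicate {label!r} has fewer than 2 distinct "
                    "doses; the dose-response is not identifiable"
                )

    @property
    def dose(self) -> np.ndarray:
        return self.frame["dose"].to_numpy()

    @property
    def signal(self) -> np.ndarray:
        return self.frame["signal"].to_numpy()

    @property
    def bio_labels(self) -> list[str]:
        # first-appearance order, stable across runs
        return list(dict.fromkeys(self.frame["bio_rep"]))

    def __len__(self) -> int:
        return len(self.frame)

    def subset(self, bio_rep: str) -> pd.DataFrame:
        return self.frame[self.frame["bio_rep"] == bio_rep]


@dataclass
class GlobalParameterVector:
    """Structured view of the full hierarchical parameter set.

    ``per_replicate`` maps biological-replicate label to its parameter
    tuple: ``(MstReplicateParams, ErrorModelParams)`` for the MST model,
    ``HillReplicateParams`` for the Hill model (whose single shared noise
    lives in ``hill_noise``).
    """

    model_kind: str
    shared: SharedBindingParams
    per_replicate: dict = field(default_factory=dict)
    hill_noise: ErrorModelParams | None = None

    def __post_init__(self) -> None:
        if self.model_kind not in ("mst", "hill"):
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        if self.model_kind == "hill" and self.hill_noise is None:
            raise ValueError("hill model requires hill_noise")


def count_parameters(model_kind: str, n_bio: int) -> int:
    """Number of simultaneously fitted free parameters.

    MST: one global KD plus (Btot, Fn_B, Fn_AB, sigma_abs, sigma_rel) per
    biological replicate -> 1 + 5*n_bio (16 for three replicates).
    Hill: global EC50 and n, (F0, Fmax) per replicate, one shared noise
    scale -> 2 + 2*n_bio + 1 (9 for three replicates).
    """
    if n_bio < 1:
        raise ValueError("n_bio must be >= 1")
    if model_kind == "mst":
        return 1 + 5 * n_bio
    if model_kind == "hill":
        return 2 + 2 * n_bio + 1
    raise ValueError(f"unknown model_kind {model_kind!r}")


# --- flat transformed parameter vector ---------------------------------------

_LOG10 = "log10"
_LINEAR = "linear"


@dataclass(frozen=True)
class ParameterLayout:
    """Mapping between a GlobalParameterVector and a flat transformed vector.

    Concentrations and noise scales are carried as log10 values in the
    flat vector because they span decades; amplitudes and the Hill
    coefficient are linear. ``flatten`` and ``unflatten`` are exact
    inverses of each other.
    """

    model_kind: str
    bio_labels: tuple
    names: tuple
    transforms: tuple

    @property
    def n_params(self) -> int:
        return len(self.names)

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(
                f"unknown parameter {name!r}; available: {', '.join(self.names)}"
            ) from None

    def flatten(self, params: GlobalParameterVector) -> np.ndarray:
        vals = []
        if self.model_kind == "mst":
            vals.append(params.shared.KD)
            for label in self.bio_labels:
                rep, err = params.per_replicate[label]
                vals += [rep.Btot, rep.Fn_B, rep.Fn_AB, err.sigma_abs, err.sigma_rel]
        else:
            vals += [params.shared.EC50, params.shared.n]
            for label in self.bio_labels:
                rep = params.per_replicate[label]
                vals += [rep.F0, rep.Fmax]
            vals.append(params.hill_noise.sigma_abs)
        x = np.asarray(vals, dtype=float)
        logmask = np.asarray([t == _LOG10 for t in self.transforms])
        x[logmask] = np.log10(x[logmask])
        return x

    def unflatten(self, x: np.ndarray) -> GlobalParameterVector:
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n_params,):
            raise ValueError(f"expected vector of length {self.n_params}, got {x.shape}")
        v = x.copy()
        logmask = np.asarray([t == _LOG10 for t in self.transforms])
        v[logmask] = 10.0 ** v[logmask]
        if self.model_kind == "mst":
            shared = SharedBindingParams(KD=v[0])
            per = {}
            for i, label in enumerate(self.bio_labels):
                b = v[1 + 5 * i : 1 + 5 * (i + 1)]
                per[label] = (
                    MstReplicateParams(Btot=b[0], Fn_B=b[1], Fn_AB=b[2]),
                    ErrorModelParams(sigma_abs=b[3], sigma_rel=b[4]),
                )
            return GlobalParameterVector("mst", shared, per)
        shared = SharedBindingParams(EC50=v[0], n=v[1])
        per = {}
        for i, label in enumerate(self.bio_labels):
            b = v[2 + 2 * i : 2 + 2 * (i + 1)]
            per[label] = HillReplicateParams(F0=b[0], Fmax=b[1])
        noise = ErrorModelParams(sigma_abs=v[-1], sigma_rel=0.0)
        return GlobalParameterVector("hill", shared, per, hill_noise=noise)


def build_layout(model_kind: str, bio_labels) -> ParameterLayout:
    bio_labels = tuple(str(b) for b in bio_labels)
    names: list[str] = []
    transforms: list[str] = []
    if model_kind == "mst":
        names.append("KD")
        transforms.append(_LOG10)
        for label in bio_labels:
            names += [f"Btot[{label}]", f"Fn_B[{label}]", f"Fn_AB[{label}]",
                      f"sigma_abs[{label}]", f"sigma_rel[{label}]"]
            transforms += [_LOG10, _LINEAR, _LINEAR, _LOG10, _LOG10]
    elif model_kind == "hill":
        names += ["EC50", "n"]
        transforms += [_LOG10, _LINEAR]
        for label in bio_labels:
            names += [f"F0[{label}]", f"Fmax[{label}]"]
            transforms += [_LINEAR, _LINEAR]
        names.append("sigma_abs")
        transforms.append(_LOG10)
    else:
        raise ValueError(f"unknown model_kind {model_kind!r}")
    layout = ParameterLayout(model_kind, bio_labels, tuple(names), tuple(transforms))
    assert layout.n_params == count_parameters(model_kind, len(bio_labels))
    return layout


def make_objective(data: TitrationDataset, layout: ParameterLayout):
    """Compile the NLL and its gradient for the flat transformed vector.

    Rows are grouped by biological replicate once; evaluation is then a
    handful of vectorized numpy operations with an analytic gradient
    (chain rule through the quadratic isotherm or the Hill curve and the
    log10 transforms), which keeps the multistart optimizer and the
    profile scans cheap. Returns ``fun(x) -> (nll, grad)``.
    """
    labels = layout.bio_labels
    missing = [b for b in data.bio_labels if b not in labels]
    if missing:
        raise ValueError(
            f"dataset contains biological replicate(s) without parameters: "
            f"{', '.join(missing)}"
        )
    bio_index = np.asarray(
        [labels.index(b) for b in data.frame["bio_rep"]], dtype=np.intp
    )
    dose = data.dose
    y = data.signal
    n_obs = len(y)
    n_bio = len(labels)
    const = 0.5 * n_obs * LOG_2PI
    ln10 = math.log(10.0)

    def _persum(w):
        return np.bincount(bio_index, weights=w, minlength=n_bio)

    if layout.model_kind == "mst":

        def objective(x: np.ndarray):
            kd = 10.0 ** x[0]
            blk = x[1:].reshape(n_bio, 5)
            btot_r = 10.0 ** blk[:, 0]
            btot = btot_r[bio_index]
            fnb = blk[:, 1][bio_index]
            fnab = blk[:, 2][bio_index]
            s_abs = (10.0 ** blk[:, 3])[bio_index]
            s_rel = (10.0 ** blk[:, 4])[bio_index]

            s = kd + dose + btot
            prod = dose * btot
            root = np.sqrt(np.maximum(s * s - 4.0 * prod, 1e-300))
            denom = s + root
            ab = 2.0 * prod / denom
            amp = fnab - fnb
            phi = ab / btot
            f = fnb + phi * amp
            var = s_abs * s_abs + (s_rel * f) ** 2
            r = y - f
            nll = float(np.sum(r * r / (2.0 * var)) + 0.5 * np.sum(np.log(var)) + const)

            # dL/df and dL/dvar
            dl_dvar = -r * r / (2.0 * var * var) + 0.5 / var
            dl_df = -r / var + dl_dvar * 2.0 * s_rel * s_rel * f
            # isotherm derivatives: ab = 2P/(S+R), R = sqrt(S^2-4P)
            dd_ds = 1.0 + s / root  # d(denom)/dS
            dab_ds = -ab / denom * dd_ds
            dab_dp = (2.0 + 2.0 * ab / root) / denom
            dab_dkd = dab_ds
            dab_dbtot = dab_ds + dose * dab_dp
            df_dkd = amp / btot * dab_dkd
            dphi_dbtot = (dab_dbtot * btot - ab) / (btot * btot)
            df_dbtot = amp * dphi_dbtot

            grad = np.empty_like(x)
            grad[0] = float(np.sum(dl_df * df_dkd)) * kd * ln10
            g_btot = _persum(dl_df * df_dbtot) * btot_r * ln10
            g_fnb = _persum(dl_df * (1.0 - phi))
            g_fnab = _persum(dl_df * phi)
            g_sa = _persum(dl_dvar * 2.0 * s_abs) * (10.0 ** blk[:, 3]) * ln10
            g_sr = _persum(dl_dvar * 2.0 * s_rel * f * f) * (10.0 ** blk[:, 4]) * ln10
            grad[1:] = np.stack([g_btot, g_fnb, g_fnab, g_sa, g_sr], axis=1).ravel()
            return nll, grad

    else:

        def objective(x: np.ndarray):
            ec50 = 10.0 ** x[0]
            n_hill = x[1]
            blk = x[2:-1].reshape(n_bio, 2)
            f0 = blk[:, 0][bio_index]
            fmax = blk[:, 1][bio_index]
            sigma = 10.0 ** x[-1]
            pos = dose > 0
            safe = np.where(pos, dose, 1.0)
            with np.errstate(divide="ignore", over="ignore"):
                g = np.where(pos, 1.0 / (1.0 + (ec50 / safe) ** n_hill), 0.0)
            f = f0 + fmax * g
            r = y - f
            inv_var = 1.0 / (sigma * sigma)
            nll = float(
                np.sum(r * r) * 0.5 * inv_var + n_obs * math.log(sigma) + const
            )

            dl_df = -r * inv_var
            gg = g * (1.0 - g)  # = u/(1+u)^2, overflow-safe
            log_ratio = np.where(pos, np.log(ec50 / safe), 0.0)
            grad = np.empty_like(x)
            # d f/d log10 ec50 = -fmax * n * g(1-g) * ln10
            grad[0] = float(np.sum(dl_df * (-fmax) * n_hill * gg)) * ln10
            grad[1] = float(np.sum(dl_df * (-fmax) * gg * log_ratio))
            g_f0 = _persum(dl_df)
            g_fmax = _persum(dl_df * g)
            grad[2:-1] = np.stack([g_f0, g_fmax], axis=1).ravel()
            grad[-1] = (-np.sum(r * r) * inv_var + n_obs) * ln10
            return nll, grad

    return objective


def negative_log_likelihood(params: GlobalParameterVector, data: TitrationDataset) -> float:
    """Gaussian negative log-likelihood of the dataset under the global model.

    Sum over observations of (y - f)^2 / (2 sigma^2) + log sigma plus the
    (N/2) log 2*pi constant, with f the model curve of the observation's
    biological replicate and sigma = error_sigma(f). Additive over
    disjoint datasets; an empty dataset scores 0.
    """
    if len(data) == 0:
        return 0.0
    total = 0.5 * len(data) * LOG_2PI
    for label, grp in data.frame.groupby("bio_rep", sort=False):
        if label not in params.per_replicate:
            raise ValueError(f"no parameters for biological replicate {label!r}")
        dose = grp["dose"].to_numpy()
        y = grp["signal"].to_numpy()
        if params.model_kind == "mst":
            rep, err = params.per_replicate[label]
            ab = complex_concentration(params.shared.KD, dose, rep.Btot)
            f = rep.Fn_B + (np.asarray(ab) / rep.Btot) * (rep.Fn_AB - rep.Fn_B)
        else:
            rep = params.per_replicate[label]
            err = params.hill_noise
            from .models import hill_response

            f = hill_response(params.shared, rep, dose)
        sigma = error_sigma(f, err)
        sigma = np.broadcast_to(np.asarray(sigma, dtype=float), f.shape)
        total += float(np.sum((y - f) ** 2 / (2.0 * sigma**2) + np.log(sigma)))
    return total
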