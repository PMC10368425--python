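"""CSV/JSON readers and writers, run configuration, and the pipeline driver.

Data files carry concentrations strictly in mol/L (reports print nM/uM
for readability but the readers never accept them); CSVs are RFC-4180
with a required header. Floats are written with Python's shortest
round-tripping repr so that write(read(f)) is byte-identical for
canonically formatted files and identical runs produce identical
reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import FitConfig, FitResult, multistart_fit
from .likelihood import DATASET_COLUMNS, TitrationDataset, build_layout
from .profile import ProfileResult, profile

__all__ = [
    "read_titration_csv",
    "write_titration_csv",
    "fit_result_to_dict",
    "fit_result_from_dict",
    "write_json",
    "format_concentration",
    "RunConfig",
    "run_pipeline",
]

logger = logging.getLogger("bindprof")


def read_titration_csv(path) -> TitrationDataset:
    """Read a titration CSV with columns dose, signal, bio_rep, tech_rep.

    Doses are mol/L with dot decimals; row order is preserved. Missing
    columns, negative doses and non-numeric signals raise with the
    offending column or row named.
    """
    frame = pd.read_csv(
        path, dtype={"bio_rep": str, "tech_rep": str}, float_precision="round_trip"
    )
    missing = [c for c in DATASET_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    return TitrationDataset(frame)


def write_titration_csv(data: TitrationDataset, path) -> None:
    """Write a dataset in canonical formatting (header, repr floats)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(",".join(DATASET_COLUMNS) + "\n")
        for row in data.frame.itertuples(index=False):
            fh.write(f"{row.dose!r},{row.signal!r},{row.bio_rep},{row.tech_rep}\n")


def write_json(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def fit_result_to_dict(fit: FitResult) -> dict:
    """JSON-ready fit report; contains enough state to resume profiling."""
    d = fit.to_dict()
    d["bio_labels"] = list(fit.layout.bio_labels)
    d["best_x"] = [float(v) for v in fit.best_x]
    d["bounds"] = [[float(lo), float(hi)] for lo, hi in fit.bounds]
    return d


def fit_result_from_dict(d: dict) -> FitResult:
    layout = build_layout(d["model_kind"], d["bio_labels"])
    best_x = np.asarray(d["best_x"], dtype=float)
    return FitResult(
        best=layout.unflatten(best_x),
        best_x=best_x,
        nll_min=float(d["nll_min"]),
        starts=d["starts"],
        layout=layout,
        bounds=np.asarray(d["bounds"], dtype=float),
        config=FitConfig.from_dict(d["config"]),
    )


def format_concentration(value: float) -> str:
    """Human-readable concentration: pick nM, uM or mM by magnitude."""
    if value < 1e-6:
        return f"{value * 1e9:.3g} nM"
    if value < 1e-3:
        return f"{value * 1e6:.3g} uM"
    return f"{value * 1e3:.3g} mM"


def _conc_number(value: float, unit: str) -> str:
    scale = {"nM": 1e9, "uM": 1e6, "mM": 1e3}[unit]
    return f"{value * scale:.3g}"


def summary_line(param: str, prof: ProfileResult) -> str:
    """One-line estimate with CI, e.g. ``KD = 3.1 [2.8; 3.4] nM``."""
    if param.split("[")[0] in ("KD", "EC50", "Btot"):
        unit = "nM" if prof.estimate < 1e-6 else ("uM" if prof.estimate < 1e-3 else "mM")
        est, lo, hi = (_conc_number(v, unit) for v in (prof.estimate, prof.lower, prof.upper))
        return f"{param} = {est} [{lo}; {hi}] {unit}"
    return f"{param} = {prof.estimate:.4g} [{prof.lower:.4g}; {prof.upper:.4g}]"


@dataclass
class RunConfig:
    """End-to-end pipeline settings: data in, fit + profile reports out."""

    model_kind: str
    data_path: str
    out_dir: str
    fit: FitConfig = field(default_factory=FitConfig)
    profile_params: tuple = ()
    level: float = 0.95
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0.0 < self.level < 1.0:
            raise ValueError("confidence level must be in (0, 1)")
        if not self.profile_params:
            self.profile_params = ("KD",) if self.model_kind == "mst" else ("EC50",)

    def to_dict(self) -> dict:
        return {
            "model_kind": self.model_kind,
            "data_path": self.data_path,
            "out_dir": self.out_dir,
            "fit": self.fit.to_dict(),
            "profile_params": list(self.profile_params),
            "level": self.level,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "fit" in d:
            d["fit"] = FitConfig.from_dict(d["fit"])
        if "profile_params" in d:
            d["profile_params"] = tuple(d["profile_params"])
        return cls(**d)


def run_pipeline(config: RunConfig) -> dict:
    """Read data, fit, profile the requested parameters, write reports.

    Emits ``fit.json``, one ``profile_<param>.json`` per requested
    parameter, and ``summary.txt`` with estimate-and-CI lines. Returns a
    mapping of report names to paths.
    """
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data = read_titration_csv(config.data_path)
    logger.info("read %d observations from %s", len(data), config.data_path)

    fit = multistart_fit(data, config.model_kind, config.fit)
    logger.info("best NLL %.6f", fit.nll_min)
    outputs = {}
    fit_path = out_dir / "fit.json"
    write_json(fit_result_to_dict(fit), fit_path)
    outputs["fit"] = str(fit_path)

    lines = []
    for param in config.profile_params:
        prof = profile(fit, data, param, level=config.level)
        safe = param.replace("[", "_").replace("]", "")
        p_path = out_dir / f"profile_{safe}.json"
        write_json(prof.to_dict(), p_path)
        outputs[f"profile_{param}"] = str(p_path)
        lines.append(summary_line(param, prof))

    summary_path = out_dir / "summary.txt"
    summary_path.write_text("\n".join(lines) + "\n")
    outputs["summary"] = str(summary_path)
    logger.info("%s", "; ".join(lines))
    return outputs
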