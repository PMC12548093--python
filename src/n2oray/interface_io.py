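"""CSV/JSON input-output, run configuration, and the end-to-end pipeline.

The input CSV has one row per sampling event with columns ``replicate_id``,
``time_min``, one N2O column (``n2o_nmol_in_bottle`` plus optional
``n2o_nmol_removed``, or ``n2o_nmol_cumulative``), ``d15N_bulk``,
``d15N_alpha``, optional ``d15N_beta``, and ``d18O``. The report mirrors the
standard per-measurement table: enrichment factor and KIE with standard
errors, R^2, linear and nonlinear RMSE, and p-values for the slope and for
rho and tau against 0.5, plus a bootstrap section and the exclusion log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .expanded_rayleigh import estimate_rho_tau, position_specific
from .isotope_core import DeltaSet, IsotopeStandard, AIR_N2, VSMOW
from .qc_stats import apply_outlier_policy, bootstrap_models
from .rayleigh_bulk import bulk_kie, fit_rayleigh_linear, sp_trend
from .reaction_accounting import (
    Dataset,
    Observation,
    cumulative_n2o,
    filter_observations,
)

logger = logging.getLogger("n2oray")

__all__ = ["RunConfig", "read_observations", "run_full_analysis",
           "write_report", "read_report", "dataset_to_frame",
           "write_observations"]

REQUIRED_COLUMNS = ("replicate_id", "time_min", "d15N_bulk", "d15N_alpha", "d18O")


@dataclass
class RunConfig:
    """Validated knobs of one analysis run, echoed into every report."""

    input_paths: list[str] = field(default_factory=list)
    no_initial_nmol: float = 10300.0
    r_standard_15n: float = AIR_N2.r_standard
    r_standard_18o: float = VSMOW.r_standard
    min_conversion: float = 0.1
    plateau_fraction: float = 0.01
    grubbs_alpha: float = 0.05
    outlier_policy: str = "remove"  # or "keep"
    n_boot: int = 1000
    seed: int = 0
    output_dir: str = "results"
    cumulative_column: bool = False  # n2o column is already cumulative

    def __post_init__(self) -> None:
        for name in ("no_initial_nmol", "r_standard_15n", "r_standard_18o",
                     "min_conversion", "plateau_fraction", "grubbs_alpha"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"config field {name} must be positive, got {v!r}")
        if not 0 < self.min_conversion < 1:
            raise ValueError("min_conversion must lie in (0, 1)")
        if not 0 < self.grubbs_alpha < 1:
            raise ValueError("grubbs_alpha must lie in (0, 1)")
        if self.outlier_policy not in ("remove", "keep"):
            raise ValueError("outlier_policy must be 'remove' or 'keep'")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            data = yaml.safe_load(text)
        elif path.suffix == ".json":
            data = json.loads(text)
        elif path.suffix == ".toml":
            import tomllib
            data = tomllib.loads(text)
        else:
            raise ValueError(f"unrecognized config format: {path.suffix}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    @property
    def n_standard(self) -> IsotopeStandard:
        return IsotopeStandard("air-N2", self.r_standard_15n)

    @property
    def o_standard(self) -> IsotopeStandard:
        return IsotopeStandard("VSMOW", self.r_standard_18o)


def read_observations(path: str | Path, config: RunConfig) -> Dataset:
    """Parse an input CSV into a typed Dataset with f and abscissa filled."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if config.cumulative_column or "n2o_nmol_cumulative" in df.columns:
        if "n2o_nmol_cumulative" not in df.columns:
            raise ValueError(f"{path}: missing column n2o_nmol_cumulative")
        df = df.assign(_n2o_cum=df["n2o_nmol_cumulative"])
    else:
        if "n2o_nmol_in_bottle" not in df.columns:
            raise ValueError(
                f"{path}: need n2o_nmol_in_bottle or n2o_nmol_cumulative"
            )
        removed = df.get("n2o_nmol_removed")
        cums = []
        for _, group in df.groupby("replicate_id", sort=False):
            g = group.sort_values("time_min")
            rem = (removed.loc[g.index].tolist()[:-1]
                   if removed is not None else [])
            cums.append(pd.Series(
                cumulative_n2o(g["n2o_nmol_in_bottle"].tolist(), rem),
                index=g.index,
            ))
        df = df.assign(_n2o_cum=pd.concat(cums))

    numeric_cols = ["time_min", "_n2o_cum", "d15N_bulk", "d15N_alpha", "d18O"]
    for col in numeric_cols:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            lines = [int(i) + 2 for i in df.index[bad]]  # +2: header + 0-base
            raise ValueError(f"{path}: non-numeric value in {col!r}, line(s) {lines}")
        if df[col].isna().any():
            lines = [int(i) + 2 for i in df.index[df[col].isna()]]
            raise ValueError(f"{path}: missing value in {col!r}, line(s) {lines}")

    dup = df.duplicated(subset=["replicate_id", "time_min"])
    if dup.any():
        raise ValueError(
            f"{path}: duplicated (replicate_id, time_min) rows at "
            f"line(s) {[int(i) + 2 for i in df.index[dup]]}"
        )

    observations = []
    for _, row in df.iterrows():
        kwargs = dict(
            d15n_bulk=float(row["d15N_bulk"]),
            d15n_alpha=float(row["d15N_alpha"]),
            d18o=float(row["d18O"]),
        )
        if "d15N_beta" in df.columns and not pd.isna(row["d15N_beta"]):
            beta = float(row["d15N_beta"])
            implied = (kwargs["d15n_alpha"] + beta) / 2.0
            if abs(kwargs["d15n_bulk"] - implied) > 0.05:
                logger.warning(
                    "replicate %s t=%s: |bulk - (alpha+beta)/2| = %.3f ‰",
                    row["replicate_id"], row["time_min"],
                    abs(kwargs["d15n_bulk"] - implied),
                )
            kwargs["d15n_beta"] = beta
        observations.append(Observation(
            replicate_id=str(row["replicate_id"]),
            time=float(row["time_min"]),
            n2o_cum=float(row["_n2o_cum"]),
            deltas=DeltaSet(**kwargs),
        ))
    return Dataset(
        observations=observations,
        no_initial=config.no_initial_nmol,
        n_standard=config.n_standard,
        o_standard=config.o_standard,
    ).with_derived()


def dataset_to_frame(dataset: Dataset) -> pd.DataFrame:
    """Flatten a Dataset to the CSV schema (cumulative N2O variant)."""
    rows = []
    for o in dataset.observations:
        rows.append({
            "replicate_id": o.replicate_id,
            "time_min": o.time,
            "n2o_nmol_cumulative": o.n2o_cum,
            "d15N_bulk": o.deltas.d15n_bulk,
            "d15N_alpha": o.deltas.d15n_alpha,
            "d15N_beta": o.deltas.d15n_beta,
            "d18O": o.deltas.d18o,
            "d15N_SP": o.deltas.sp,
            "f": o.f,
            "abscissa": o.abscissa,
        })
    return pd.DataFrame(rows)


def write_observations(dataset: Dataset, path: str | Path) -> None:
    dataset_to_frame(dataset).to_csv(path, index=False)


def _fit_to_dict(fit) -> dict:
    return {
        "slope": fit.slope, "intercept": fit.intercept,
        "se_slope": fit.se_slope, "se_intercept": fit.se_intercept,
        "r2": fit.r2, "rmse": fit.rmse, "p_slope": fit.p_slope, "n": fit.n,
    }


def run_full_analysis(
    dataset: Dataset, config: RunConfig, bootstrap: bool = True
) -> dict:
    """Execute the full workflow on a raw dataset and return the report.

    Stages: filter -> pool -> bulk Rayleigh fit -> Grubbs outlier policy ->
    refit -> rho/tau -> position-specific conversion -> d18O slope ->
    SP trend -> bootstrap (optional).
    """
    filtered = filter_observations(
        dataset, config.min_conversion, config.plateau_fraction
    )
    fit0 = fit_rayleigh_linear(filtered, "d15n_bulk")
    screened, outlier = apply_outlier_policy(
        filtered, fit0, config.grubbs_alpha, config.outlier_policy
    )
    fit = (fit_rayleigh_linear(screened, "d15n_bulk")
           if outlier.removed else fit0)
    kie = bulk_kie(fit)
    rho_tau = estimate_rho_tau(screened, config.n_standard)
    ps = position_specific(rho_tau, fit)
    d18o_fit = fit_rayleigh_linear(screened, "d18o")
    sp = sp_trend(screened)

    report: dict = {
        "provenance": {
            "package_version": __version__,
            "config": config.to_dict(),
            "config_hash": config.digest(),
            "seed": config.seed,
        },
        "n_observations": len(screened),
        "table": [
            {
                "measurement": "15N",
                "epsilon": kie.epsilon, "se_epsilon": kie.se_epsilon,
                "kie": kie.kie, "se_kie": kie.se_kie,
                "r2": fit.r2, "linear_rmse": fit.rmse,
                "nonlinear_rmse": None,
                "p_epsilon": fit.p_slope, "p_rho": None, "p_tau": None,
            },
            {
                "measurement": "15N_alpha",
                "epsilon": ps.epsilon_na, "se_epsilon": ps.se_epsilon_na,
                "kie": ps.kie_na, "se_kie": ps.se_kie_na,
                "r2": fit.r2, "linear_rmse": fit.rmse,
                "nonlinear_rmse": rho_tau.nonlinear_rmse,
                "p_epsilon": fit.p_slope,
                "p_rho": rho_tau.p_rho, "p_tau": rho_tau.p_tau,
            },
            {
                "measurement": "15N_beta",
                "epsilon": ps.epsilon_nb, "se_epsilon": ps.se_epsilon_nb,
                "kie": ps.kie_nb, "se_kie": ps.se_kie_nb,
                "r2": fit.r2, "linear_rmse": fit.rmse,
                "nonlinear_rmse": rho_tau.nonlinear_rmse,
                "p_epsilon": fit.p_slope,
                "p_rho": rho_tau.p_rho, "p_tau": rho_tau.p_tau,
            },
        ],
        "bulk_fit": _fit_to_dict(fit),
        "d15n_s0": fit.intercept,
        "rho": {"estimate": rho_tau.rho, "se": rho_tau.se_rho,
                "p_vs_half": rho_tau.p_rho},
        "tau": {"estimate": rho_tau.tau, "se": rho_tau.se_tau,
                "p_vs_half": rho_tau.p_tau},
        "d18o_slope": _fit_to_dict(d18o_fit),  # a slope, not a true eps(18O)
        "sp": {"mean": sp.sp_mean, "sd": sp.sp_sd,
               "trend": _fit_to_dict(sp.fit)},
        "grubbs": {
            "g_statistic": outlier.g_statistic,
            "critical_value": outlier.critical_value,
            "alpha_level": outlier.alpha_level,
            "outlier_index": outlier.outlier_index,
            "removed": outlier.removed,
            "note": outlier.note,
        },
        "exclusion_log": screened.exclusion_log,
    }
    if bootstrap:
        bs = bootstrap_models(screened, config.n_boot, config.seed)
        report["bootstrap"] = dataclasses.asdict(bs)
    return report


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_sanitize(report), indent=2))


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _sanitize(obj):
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, float) and math.isnan(obj):
        return None
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj
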