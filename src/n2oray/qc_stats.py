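"""Outlier screening and bootstrap uncertainty for the Rayleigh fits.

Grubbs' one-outlier test is applied to the residuals of the bulk-15N linear
regression of the pooled dataset; at most one observation is removed. Because
the pooled datasets are small, goodness of fit and parameter uncertainty are
also assessed by resampling observations with replacement (1000 datasets of
the original size by default) and averaging the refitted quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .expanded_rayleigh import estimate_rho_tau, position_specific
from .rayleigh_bulk import LinearFitResult, fit_rayleigh_linear
from .reaction_accounting import Dataset

__all__ = [
    "OutlierReport",
    "BootstrapSummary",
    "grubbs_critical_value",
    "grubbs_one_outlier",
    "apply_outlier_policy",
    "bootstrap_models",
]


@dataclass(frozen=True)
class OutlierReport:
    g_statistic: float
    critical_value: float
    alpha_level: float
    outlier_index: int | None
    removed: bool
    note: str = ""


@dataclass(frozen=True)
class BootstrapSummary:
    n_boot: int
    seed: int
    n_failed_fits: int
    mean_kie_bulk: float
    sd_kie_bulk: float
    mean_kie_na: float
    sd_kie_na: float
    mean_kie_nb: float
    sd_kie_nb: float
    mean_epsilon_bulk: float
    mean_epsilon_na: float
    mean_epsilon_nb: float
    mean_linear_rmse: float
    mean_nonlinear_rmse: float
    warning: str = ""


def grubbs_critical_value(n: int, alpha_level: float = 0.05) -> float:
    """Two-sided Grubbs critical value from the Student-t quantile.

    G_crit = (n-1)/sqrt(n) * sqrt(t^2 / (n - 2 + t^2)) with
    t = t_{1 - alpha/(2n), n-2}.
    """
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    t = stats.t.ppf(1.0 - alpha_level / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t ** 2 / (n - 2 + t ** 2))


def grubbs_one_outlier(residuals, alpha_level: float = 0.05) -> OutlierReport:
    """Grubbs' test for a single outlier based on the sample mean.

    G = max|r_i - rbar| / s with s the n-1 sample SD; the most deviant
    point is flagged when G exceeds the two-sided critical value. Ties are
    broken by the first index. A zero-variance sample yields a no-outlier
    report with a note.
    """
    r = np.asarray(residuals, dtype=float)
    n = len(r)
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    s = r.std(ddof=1)
    crit = grubbs_critical_value(n, alpha_level)
    # residual spread at machine-rounding scale carries no outlier signal
    if s <= 1e-12 * max(1.0, float(np.abs(r).max())):
        return OutlierReport(
            g_statistic=0.0, critical_value=crit, alpha_level=alpha_level,
            outlier_index=None, removed=False,
            note="zero residual variance; test not applicable",
        )
    dev = np.abs(r - r.mean())
    idx = int(np.argmax(dev))  # argmax takes the first maximum on ties
    g = float(dev[idx] / s)
    flagged = g > crit
    return OutlierReport(
        g_statistic=g, critical_value=float(crit), alpha_level=alpha_level,
        outlier_index=idx if flagged else None, removed=flagged,
    )


def apply_outlier_policy(
    dataset: Dataset,
    fit: LinearFitResult,
    alpha_level: float = 0.05,
    policy: str = "remove",
) -> tuple[Dataset, OutlierReport]:
    """Screen the bulk-fit residuals and drop at most one flagged row.

    The whole observation (all delta channels) is removed and logged;
    re-fitting is the caller's responsibility. ``policy="keep"`` reports the
    flag without removing.
    """
    obs = dataset.observations
    resid = [
        o.deltas.d15n_bulk - (fit.intercept + fit.slope * o.abscissa)
        for o in obs
    ]
    report = grubbs_one_outlier(resid, alpha_level)
    if not report.removed or policy == "keep":
        if report.removed and policy == "keep":
            report = replace(report, removed=False,
                             note="flagged but retained by policy")
        return dataset, report
    i = report.outlier_index
    dropped = obs[i]
    log = list(dataset.exclusion_log)
    log.append({
        "replicate_id": dropped.replicate_id, "time": dropped.time,
        "reason": f"Grubbs outlier (G={report.g_statistic:.3f} > "
                  f"{report.critical_value:.3f})",
    })
    kept = [o for j, o in enumerate(obs) if j != i]
    return (
        Dataset(observations=kept, no_initial=dataset.no_initial,
                n_standard=dataset.n_standard, o_standard=dataset.o_standard,
                exclusion_log=log),
        report,
    )


def _resample_rng(seed: int, index: int) -> np.random.Generator:
    # Counter-based substream: same draws whether resamples run serially or
    # in parallel.
    return np.random.Generator(
        np.random.Philox(key=seed, counter=[0, 0, 0, index])
    )


def bootstrap_models(
    dataset: Dataset, n_boot: int = 1000, seed: int = 0
) -> BootstrapSummary:
    """Case-resampling bootstrap of the linear and expanded Rayleigh fits.

    Each of ``n_boot`` resamples draws ``n`` observations with replacement
    from the pooled dataset, refits both models and the position-specific
    conversion, and the per-resample KIEs, enrichment factors and RMSEs are
    averaged over the successful fits. Resamples with a degenerate abscissa
    or a failed nonlinear fit are counted and excluded.
    """
    obs = dataset.observations
    n = len(obs)
    if n < 5:
        raise ValueError(f"bootstrap needs >= 5 observations, got {n}")

    cols: dict[str, list[float]] = {k: [] for k in (
        "kie_bulk", "kie_na", "kie_nb", "eps_bulk", "eps_na", "eps_nb",
        "lin_rmse", "nl_rmse",
    )}
    n_failed = 0
    for b in range(n_boot):
        rng = _resample_rng(seed, b)
        idx = rng.integers(0, n, size=n)
        sample = Dataset(
            observations=[obs[i] for i in idx],
            no_initial=dataset.no_initial,
            n_standard=dataset.n_standard,
            o_standard=dataset.o_standard,
        )
        try:
            fit = fit_rayleigh_linear(sample, "d15n_bulk")
            rt = estimate_rho_tau(sample, dataset.n_standard)
            ps = position_specific(rt, fit)
        except (ValueError, RuntimeError):
            n_failed += 1
            continue
        cols["kie_bulk"].append(ps.kie_bulk)
        cols["kie_na"].append(ps.kie_na)
        cols["kie_nb"].append(ps.kie_nb)
        cols["eps_bulk"].append(ps.epsilon_bulk)
        cols["eps_na"].append(ps.epsilon_na)
        cols["eps_nb"].append(ps.epsilon_nb)
        cols["lin_rmse"].append(fit.rmse)
        cols["nl_rmse"].append(rt.nonlinear_rmse)

    if not cols["kie_bulk"]:
        raise RuntimeError("all bootstrap resamples failed to fit")
    arr = {k: np.array(v) for k, v in cols.items()}
    warning = ""
    if n_failed > 0.1 * n_boot:
        warning = f"{n_failed}/{n_boot} resamples failed to fit"
    return BootstrapSummary(
        n_boot=n_boot, seed=seed, n_failed_fits=n_failed,
        mean_kie_bulk=float(arr["kie_bulk"].mean()),
        sd_kie_bulk=float(arr["kie_bulk"].std(ddof=1)) if len(arr["kie_bulk"]) > 1 else 0.0,
        mean_kie_na=float(arr["kie_na"].mean()),
        sd_kie_na=float(arr["kie_na"].std(ddof=1)) if len(arr["kie_na"]) > 1 else 0.0,
        mean_kie_nb=float(arr["kie_nb"].mean()),
        sd_kie_nb=float(arr["kie_nb"].std(ddof=1)) if len(arr["kie_nb"]) > 1 else 0.0,
        mean_epsilon_bulk=float(arr["eps_bulk"].mean()),
        mean_epsilon_na=float(arr["eps_na"].mean()),
        mean_epsilon_nb=float(arr["eps_nb"].mean()),
        mean_linear_rmse=float(arr["lin_rmse"].mean()),
        mean_nonlinear_rmse=float(arr["nl_rmse"].mean()),
        warning=warning,
    )
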