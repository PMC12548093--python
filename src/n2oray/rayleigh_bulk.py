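"""Linearized (Mariotti) Rayleigh regressions for bulk 15N, 18O, and SP.

For a closed, well-mixed substrate pool consumed by a single irreversible
step with constant fractionation, the accumulated-product delta is linear in
the abscissa x = -f ln f / (1 - f):

    delta_p = delta_s0 - eps * x

so an OLS fit of product delta against x yields the enrichment factor eps as
the slope and the initial substrate delta as the intercept. For bulk 15N the
slope is the true enrichment factor; for 18O of N2O it is a composite slope
only (the second O atom is lost to water and fractionates independently).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .isotope_core import alpha_to_kie, epsilon_to_alpha
from .reaction_accounting import Dataset

__all__ = ["LinearFitResult", "BulkKie", "SpTrend",
           "fit_rayleigh_linear", "bulk_kie", "sp_trend"]


@dataclass(frozen=True)
class LinearFitResult:
    """OLS fit of a delta channel against the Rayleigh abscissa.

    ``rmse`` follows the sqrt(SSR/n) convention; coefficient standard errors
    use the usual OLS n-2 degrees of freedom. ``r2`` is 1 - SSR/SST and is
    reported as 0 (with ``degenerate_sst`` set) when the response is
    constant.
    """

    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    r2: float
    rmse: float
    p_slope: float
    n: int
    delta_field: str = ""
    degenerate_sst: bool = False


@dataclass(frozen=True)
class BulkKie:
    """Bulk enrichment factor and KIE derived from a Rayleigh slope."""

    epsilon: float
    se_epsilon: float
    alpha: float
    kie: float
    se_kie: float


@dataclass(frozen=True)
class SpTrend:
    """Site-preference trend line plus its pooled mean and SD."""

    fit: LinearFitResult
    sp_mean: float
    sp_sd: float


def _extract(dataset: Dataset, delta_field: str) -> tuple[np.ndarray, np.ndarray]:
    x = np.array([o.abscissa for o in dataset.observations], dtype=float)
    y = np.array(
        [getattr(o.deltas, delta_field) for o in dataset.observations],
        dtype=float,
    )
    if np.isnan(x).any():
        raise ValueError("abscissa not computed; call Dataset.with_derived()")
    return x, y


def fit_rayleigh_linear(dataset: Dataset, delta_field: str) -> LinearFitResult:
    """OLS of the selected delta channel against -f ln f / (1 - f).

    ``delta_field`` is an attribute of :class:`~n2oray.isotope_core.DeltaSet`
    (``d15n_bulk``, ``d15n_alpha``, ``d15n_beta``, ``d18o`` or ``sp``). For
    ``d15n_bulk`` the slope estimates eps and the intercept delta_s0.
    """
    x, y = _extract(dataset, delta_field)
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 observations to fit, got {n}")
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate abscissa: all values identical")

    model = sm.OLS(y, sm.add_constant(x)).fit()
    ssr = float(np.sum(model.resid ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    degenerate = sst == 0.0
    r2 = 0.0 if degenerate else 1.0 - ssr / sst
    return LinearFitResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        se_slope=float(model.bse[1]),
        se_intercept=float(model.bse[0]),
        r2=r2,
        rmse=float(np.sqrt(ssr / n)),
        p_slope=float(model.pvalues[1]),
        n=n,
        delta_field=delta_field,
        degenerate_sst=degenerate,
    )


def bulk_kie(fit: LinearFitResult) -> BulkKie:
    """Convert a bulk-15N Rayleigh slope to alpha and KIE with first-order SEs.

    alpha = 1 + slope/1000, KIE = 1/alpha, SE(KIE) = SE(slope)/1000/alpha^2.
    """
    alpha = epsilon_to_alpha(fit.slope)
    kie = alpha_to_kie(alpha)
    return BulkKie(
        epsilon=fit.slope,
        se_epsilon=fit.se_slope,
        alpha=alpha,
        kie=kie,
        se_kie=fit.se_slope / 1000.0 / alpha ** 2,
    )


def sp_trend(dataset: Dataset) -> SpTrend:
    """Site-preference vs abscissa trend plus mean +/- SD of SP.

    SP is expected to be roughly constant in f when the two per-site
    fractionation factors are constant; the mean is the source-signature
    summary, reported with the sample SD.
    """
    sp = np.array([o.deltas.sp for o in dataset.observations], dtype=float)
    fit = fit_rayleigh_linear(dataset, "sp")
    return SpTrend(fit=fit, sp_mean=float(sp.mean()), sp_sd=float(sp.std(ddof=1)))
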