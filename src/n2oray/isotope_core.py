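"""Delta-notation arithmetic, isotope-atom accounting, and epsilon/alpha/KIE conversions.

All delta values are per mil (‰) relative to an :class:`IsotopeStandard`;
isotope ratios R are heavy/light abundance ratios. Conversions follow the
standard definitions

    delta = (R_sample / R_standard - 1) * 1000
    epsilon = (alpha - 1) * 1000
    KIE = 1 / alpha

with alpha the instantaneous product/substrate fractionation factor and KIE
the ratio of light over heavy rate constants (KIE > 1 is a normal effect).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "IsotopeStandard",
    "AIR_N2",
    "VSMOW",
    "DeltaSet",
    "AtomAmounts",
    "ratio_from_delta",
    "delta_from_ratio",
    "epsilon_to_alpha",
    "alpha_to_epsilon",
    "alpha_to_kie",
    "kie_to_alpha",
    "beta_from_bulk_alpha",
    "site_preference",
    "atom_amounts",
]


@dataclass(frozen=True)
class IsotopeStandard:
    """International reference material defining the delta scale.

    Parameters
    ----------
    name
        Text label, e.g. ``"air-N2"`` or ``"VSMOW"``.
    r_standard
        Heavy/light isotope abundance ratio of the standard (dimensionless).
    """

    name: str
    r_standard: float

    def __post_init__(self) -> None:
        if not 0.0 < self.r_standard < 1.0:
            raise ValueError(
                f"r_standard must be in (0, 1), got {self.r_standard!r}"
            )


#: Atmospheric N2, the 15N/14N reference scale.
AIR_N2 = IsotopeStandard("air-N2", 0.0036765)

#: Vienna Standard Mean Ocean Water, the 18O/16O reference scale.
VSMOW = IsotopeStandard("VSMOW", 0.0020052)


def ratio_from_delta(delta: float, standard: IsotopeStandard) -> float:
    """Convert a delta value (‰) to an absolute isotope ratio R_sample."""
    if delta <= -1000.0:
        raise ValueError(
            f"delta = {delta} ‰ implies a non-positive isotope ratio"
        )
    return (delta / 1000.0 + 1.0) * standard.r_standard


def delta_from_ratio(ratio: float, standard: IsotopeStandard) -> float:
    """Convert an absolute isotope ratio to a delta value (‰)."""
    if ratio <= 0.0:
        raise ValueError(f"isotope ratio must be positive, got {ratio!r}")
    return (ratio / standard.r_standard - 1.0) * 1000.0


def epsilon_to_alpha(epsilon: float) -> float:
    """Enrichment factor (‰) to fractionation factor: alpha = 1 + eps/1000."""
    if epsilon <= -1000.0:
        raise ValueError(f"epsilon = {epsilon} ‰ implies alpha <= 0")
    return 1.0 + epsilon / 1000.0


def alpha_to_epsilon(alpha: float) -> float:
    """Fractionation factor to enrichment factor (‰)."""
    return (alpha - 1.0) * 1000.0


def alpha_to_kie(alpha: float) -> float:
    """Kinetic isotope effect KIE = 1/alpha (k_light / k_heavy)."""
    if alpha <= 0.0:
        raise ValueError(f"alpha must be positive, got {alpha!r}")
    return 1.0 / alpha


def kie_to_alpha(kie: float) -> float:
    """Inverse of :func:`alpha_to_kie`."""
    if kie <= 0.0:
        raise ValueError(f"KIE must be positive, got {kie!r}")
    return 1.0 / kie


def beta_from_bulk_alpha(d15n_bulk: float, d15n_alpha: float) -> float:
    """Terminal-N delta from bulk and central-N deltas.

    Bulk d15N of N2O is the site average (alpha + beta)/2, so
    beta = 2*bulk - alpha. Real measurements additionally carry a small
    mass-overlap correction applied upstream of this package, so derived
    values can differ from a lab's reported beta by a few hundredths ‰.
    """
    return 2.0 * d15n_bulk - d15n_alpha


def site_preference(d15n_alpha: float, d15n_beta: float) -> float:
    """Site preference SP = d15N(alpha) - d15N(beta), ‰."""
    return d15n_alpha - d15n_beta


@dataclass(frozen=True)
class DeltaSet:
    """One sample's measured/derived delta values (‰).

    ``d15n_beta`` and ``sp`` default to the values derived from bulk and
    alpha; pass them explicitly when measured/corrected values exist.
    """

    d15n_bulk: float
    d15n_alpha: float
    d18o: float
    d15n_beta: float = field(default=math.nan)
    sp: float = field(default=math.nan)

    def __post_init__(self) -> None:
        if math.isnan(self.d15n_beta):
            object.__setattr__(
                self, "d15n_beta",
                beta_from_bulk_alpha(self.d15n_bulk, self.d15n_alpha),
            )
        if math.isnan(self.sp):
            object.__setattr__(
                self, "sp", site_preference(self.d15n_alpha, self.d15n_beta)
            )


@dataclass(frozen=True)
class AtomAmounts:
    """Heavy/light nitrogen atom inventory of a cumulative N2O product pool.

    Bulk counts cover both N atoms per molecule; alpha counts cover the one
    central atom per molecule, so n15_bulk + n14_bulk = 2 * n2o and
    n15_alpha + n14_alpha = n2o.
    """

    n15_bulk: float
    n14_bulk: float
    n15_alpha: float
    n14_alpha: float

    @property
    def rho(self) -> float:
        """Share of product 15N sitting at the central (alpha) position."""
        return self.n15_alpha / self.n15_bulk

    @property
    def tau(self) -> float:
        """Share of product 14N sitting at the central (alpha) position."""
        return self.n14_alpha / self.n14_bulk


def atom_amounts(
    d15n_bulk: float,
    d15n_alpha: float,
    n2o: float,
    standard: IsotopeStandard = AIR_N2,
) -> AtomAmounts:
    """Exact heavy/light atom amounts (nmol) in ``n2o`` nmol of product.

    Uses the exact isotope fraction R/(1+R) rather than the small-R
    approximation, so atom totals are conserved exactly: the bulk pool holds
    2*n2o N atoms and the alpha site holds n2o atoms.
    """
    if n2o <= 0.0:
        raise ValueError(f"n2o amount must be positive, got {n2o!r}")
    r_b = ratio_from_delta(d15n_bulk, standard)
    r_a = ratio_from_delta(d15n_alpha, standard)
    n15_bulk = 2.0 * n2o * r_b / (1.0 + r_b)
    n15_alpha = n2o * r_a / (1.0 + r_a)
    return AtomAmounts(
        n15_bulk=n15_bulk,
        n14_bulk=2.0 * n2o - n15_bulk,
        n15_alpha=n15_alpha,
        n14_alpha=n2o - n15_alpha,
    )
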