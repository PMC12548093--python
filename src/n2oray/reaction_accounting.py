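"""Substrate accounting for the closed-system reduction 2 NO -> N2O + H2O.

Converts sampled N2O amounts into cumulative product, the fraction of the NO
pool remaining (f), and the Rayleigh abscissa -f ln f / (1 - f) against which
product deltas are regressed; applies the observation filters (minimum
conversion, post-plateau exclusion) and pools replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

from .isotope_core import AIR_N2, VSMOW, DeltaSet, IsotopeStandard

__all__ = [
    "Observation",
    "Dataset",
    "cumulative_n2o",
    "fraction_remaining",
    "rayleigh_abscissa",
    "filter_observations",
]


@dataclass(frozen=True)
class Observation:
    """One sampled time point of a closed-system reaction."""

    replicate_id: str
    time: float  # minutes
    n2o_cum: float  # nmol, cumulative enzymatic product incl. removed aliquots
    deltas: DeltaSet
    f: float = math.nan  # fraction of NO remaining
    abscissa: float = math.nan  # -f ln f / (1 - f)

    def with_f(self, no_initial: float) -> "Observation":
        f = fraction_remaining(self.n2o_cum, no_initial)
        return replace(self, f=f, abscissa=rayleigh_abscissa(f))


@dataclass
class Dataset:
    """Pooled observations plus run metadata and the exclusion audit log."""

    observations: list[Observation]
    no_initial: float  # nmol NO at t=0
    n_standard: IsotopeStandard = AIR_N2
    o_standard: IsotopeStandard = VSMOW
    exclusion_log: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.observations)

    def with_derived(self) -> "Dataset":
        """Return a copy with f and the abscissa filled on every row."""
        obs = [o.with_f(self.no_initial) for o in self.observations]
        return Dataset(
            observations=obs,
            no_initial=self.no_initial,
            n_standard=self.n_standard,
            o_standard=self.o_standard,
            exclusion_log=list(self.exclusion_log),
        )


def cumulative_n2o(
    in_bottle: Sequence[float], removed: Sequence[float] = ()
) -> list[float]:
    """Cumulative enzymatic N2O at each sampling point.

    Element i is the in-bottle amount at sampling i plus everything removed
    as aliquots at the previous sampling points (``removed[j]`` is the amount
    withdrawn at sampling j, so it contributes from sampling j+1 onward).
    """
    if any(a < 0 for a in in_bottle) or any(r < 0 for r in removed):
        raise ValueError("N2O amounts and removals must be non-negative")
    out: list[float] = []
    removed_so_far = 0.0
    for i, amount in enumerate(in_bottle):
        out.append(amount + removed_so_far)
        if i < len(removed):
            removed_so_far += removed[i]
    return out


def fraction_remaining(n2o_cum: float, no_initial: float) -> float:
    """Fraction of the initial NO pool remaining; each N2O consumes 2 NO."""
    if no_initial <= 0:
        raise ValueError("no_initial must be positive")
    if n2o_cum < 0 or 2.0 * n2o_cum > no_initial:
        raise ValueError(
            f"2 * n2o_cum = {2.0 * n2o_cum} nmol exceeds the NO pool "
            f"({no_initial} nmol) or is negative"
        )
    return (no_initial - 2.0 * n2o_cum) / no_initial


def rayleigh_abscissa(f: float) -> float:
    """Accumulated-product Rayleigh abscissa -f ln f / (1 - f).

    Strictly increasing on (0, 1) with limits 0 at f=0 and 1 at f=1 (the
    endpoint values are taken by continuity).
    """
    if f < 0.0 or f > 1.0:
        raise ValueError(f"f must lie in [0, 1], got {f!r}")
    if f == 0.0:
        return 0.0
    if f == 1.0:
        return 1.0
    return -f * math.log(f) / (1.0 - f)


def filter_observations(
    dataset: Dataset,
    min_conversion: float = 0.1,
    plateau_fraction: float = 0.01,
) -> Dataset:
    """Apply the early-reaction and post-plateau exclusions, then pool.

    Rows with conversion (1 - f) below ``min_conversion`` are dropped (the
    linearized Rayleigh model is least accurate near the start of the
    reaction). Within each replicate, the first row whose cumulative-N2O
    increment over the previous retained candidate is <= ``plateau_fraction``
    of its cumulative amount marks the production plateau; it and all later
    rows of that replicate are dropped. Every removal is logged with a reason.
    """
    data = dataset.with_derived()
    log = list(data.exclusion_log)
    kept: list[Observation] = []

    by_rep: dict[str, list[Observation]] = {}
    for o in data.observations:
        by_rep.setdefault(o.replicate_id, []).append(o)

    for rep, rows in by_rep.items():
        rows = sorted(rows, key=lambda o: o.time)
        plateau_hit = False
        prev_cum: float | None = None
        for o in rows:
            if plateau_hit:
                log.append(
                    {"replicate_id": rep, "time": o.time,
                     "reason": "after production plateau"}
                )
                continue
            if prev_cum is not None and (
                o.n2o_cum - prev_cum <= plateau_fraction * o.n2o_cum
            ):
                plateau_hit = True
                log.append(
                    {"replicate_id": rep, "time": o.time,
                     "reason": "production plateau"}
                )
                continue
            prev_cum = o.n2o_cum
            if (1.0 - o.f) < min_conversion:
                log.append(
                    {"replicate_id": rep, "time": o.time,
                     "reason": f"conversion below {min_conversion}"}
                )
                continue
            kept.append(o)

    if not kept:
        raise ValueError(
            "no observations remain after filtering "
            f"({len(log)} rows excluded)"
        )
    kept.sort(key=lambda o: (o.replicate_id, o.time))
    return Dataset(
        observations=kept,
        no_initial=data.no_initial,
        n_standard=data.n_standard,
        o_standard=data.o_standard,
        exclusion_log=log,
    )
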