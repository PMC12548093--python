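#!/usr/bin/env python
"""Parameter-recovery study: how well does the pipeline return known truth?

Simulates 200 independent noisy study-condition datasets, fits each with the
full linear + expanded Rayleigh chain, and summarizes bias, spread, and
one-SE coverage of the per-site enrichment factors. Also reports the
zero-noise fit, which isolates the systematic component: a delta-space
Rayleigh regression of exact closed-system data recovers the enrichment
factor scaled by roughly (1 + d15N_s0/1000) — about -4 % here — a known
limitation of the linearized model when the substrate delta is far from 0.

Writes results/recovery.csv and results/recovery_summary.json.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from n2oray import (
    estimate_rho_tau,
    fit_rayleigh_linear,
    generate_study_like,
    position_specific,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"
TRUE = {"eps_na": -7.2, "eps_nb": -9.9, "d15n_s0": -40.5}
ZERO_NOISE = dict(noise_sd_bulk=0.0, noise_sd_alpha=0.0, noise_sd_d18o=0.0)


def fit_one(sim):
    fit = fit_rayleigh_linear(sim.dataset, "d15n_bulk")
    ps = position_specific(estimate_rho_tau(sim.dataset), fit)
    return {"eps_bulk": ps.epsilon_bulk, "eps_na": ps.epsilon_na,
            "eps_nb": ps.epsilon_nb, "se_na": ps.se_epsilon_na,
            "se_nb": ps.se_epsilon_nb, "d15n_s0": fit.intercept}


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--n-seeds", type=int, default=200)
    args = ap.parse_args()

    RESULTS.mkdir(exist_ok=True)
    rows = [fit_one(generate_study_like(seed=s)) for s in range(args.n_seeds)]
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "recovery.csv", index_label="seed")

    zn = fit_one(generate_study_like(seed=0, **ZERO_NOISE))
    summary = {
        "n_seeds": args.n_seeds,
        "true_eps_na": TRUE["eps_na"], "true_eps_nb": TRUE["eps_nb"],
        "median_eps_na": float(df.eps_na.median()),
        "median_eps_nb": float(df.eps_nb.median()),
        "sd_eps_na": float(df.eps_na.std()),
        "sd_eps_nb": float(df.eps_nb.std()),
        "coverage_1se_na_pct": float(
            100 * np.mean(np.abs(df.eps_na - TRUE["eps_na"]) <= df.se_na)),
        "coverage_1se_nb_pct": float(
            100 * np.mean(np.abs(df.eps_nb - TRUE["eps_nb"]) <= df.se_nb)),
        "zero_noise_fit": zn,
    }
    (RESULTS / "recovery_summary.json").write_text(
        json.dumps(summary, indent=2))

    print(f"{args.n_seeds} noisy datasets fitted")
    print(f"eps 15N-alpha: median {summary['median_eps_na']:.2f} "
          f"(truth {TRUE['eps_na']}), SD {summary['sd_eps_na']:.2f}, "
          f"1-SE coverage {summary['coverage_1se_na_pct']:.0f} %")
    print(f"eps 15N-beta:  median {summary['median_eps_nb']:.2f} "
          f"(truth {TRUE['eps_nb']}), SD {summary['sd_eps_nb']:.2f}, "
          f"1-SE coverage {summary['coverage_1se_nb_pct']:.0f} %")
    print(f"zero-noise fit: eps_na {zn['eps_na']:.2f}, eps_nb "
          f"{zn['eps_nb']:.2f}, d15N_s0 {zn['d15n_s0']:.2f} — the residual "
          "offset from truth is the delta-space linearization systematic, "
          "about (1 + d15N_s0/1000) on the slope, smaller than the 0.5-0.7 "
          "permil measurement noise")
    print(f"wrote {RESULTS / 'recovery.csv'} and recovery_summary.json")


if __name__ == "__main__":
    main()
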