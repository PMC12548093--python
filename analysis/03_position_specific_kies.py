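#!/usr/bin/env python
"""Partition the bulk fractionation into per-site KIEs (expanded Rayleigh).

Estimates rho (15N-alpha share of product 15N) by nonlinear least squares and
tau (14N-alpha share of product 14N) by per-observation averaging, converts
to per-site fractionation factors, and writes the per-measurement table to
results/position_specific.csv.
"""

from pathlib import Path

import pandas as pd

from n2oray import filter_observations
from n2oray.interface_io import RunConfig, run_full_analysis, read_observations

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    config = RunConfig()
    dataset = read_observations(RESULTS / "synthetic_observations.csv", config)
    report = run_full_analysis(dataset, config, bootstrap=False)

    rho, tau = report["rho"], report["tau"]
    print(f"rho = {rho['estimate']:.4f} ± {rho['se']:.4f} "
          f"(p vs 0.5: {rho['p_vs_half']:.4f})")
    print(f"tau = {tau['estimate']:.6f} ± {tau['se']:.6f} "
          f"(p vs 0.5: {tau['p_vs_half']:.4f})")
    df = pd.DataFrame(report["table"])
    print(df.to_string(index=False,
                       float_format=lambda v: f"{v:.4f}"))
    nl = df.loc[df.measurement == "15N_alpha", "nonlinear_rmse"].iloc[0]
    lin = df.loc[df.measurement == "15N", "linear_rmse"].iloc[0]
    print(f"nonlinear RMSE {nl:.2f} vs linear RMSE {lin:.2f} permil "
          "(similar values mean both models describe the data comparably)")
    df.to_csv(RESULTS / "position_specific.csv", index=False)
    print(f"wrote {RESULTS / 'position_specific.csv'}")


if __name__ == "__main__":
    main()
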