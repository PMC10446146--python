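#!/usr/bin/env python
"""Estimate the chamber source rate from the simulated series.

Reads the series written by 01_generate_chamber_data.py (regenerating it
if absent), masks the infiltration-spike windows, averages into 15-minute
blocks, takes window-to-window derivatives and reports the emission rate
with its one-standard-deviation upper range. Also evaluates the same
estimator on the reported chamber derivative statistics (mean 1e-4,
sd 0.02 1/(cm3*s), V = 220 L), which gives the 4400 1/s upper range.
"""

import argparse
import dataclasses
from pathlib import Path

from nanorelease import io as nio
from nanorelease.inference import (
    DerivativeStats,
    block_average,
    derivative_stats,
    emission_bound,
    mask_series,
)
from nanorelease.units import round_sig

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--window-s", type=float, default=900.0)
    args = parser.parse_args()

    series_path = RESULTS / "chamber_series.csv"
    if not series_path.exists():
        from nanorelease.synth import ChamberSimConfig, gen_chamber_series

        cfg = ChamberSimConfig(seed=args.seed)
        series, truth = gen_chamber_series(cfg)
        RESULTS.mkdir(exist_ok=True)
        nio.write_series_csv(series, series_path)
        nio.write_exclusions_csv(truth.exclusions, RESULTS / "chamber_exclusions.csv")
    series = nio.read_series_csv(series_path, metric="number")
    exclusions = nio.read_exclusions_csv(RESULTS / "chamber_exclusions.csv")

    masked = mask_series(series, exclusions)
    averaged = block_average(masked, args.window_s)
    stats = derivative_stats(averaged)
    bound = emission_bound(stats, chamber_volume_m3=0.22, k_sigma=1.0)
    print(
        f"simulated chamber: derivative {stats.mean:.3e} +/- {stats.sd:.3e} "
        f"1/(cm3*s) over {stats.n_windows} windows -> source "
        f"{bound.point:.0f} 1/s, upper range {bound.upper:.0f} 1/s"
    )

    reported = DerivativeStats(
        mean=1e-4, sd=0.02, n_windows=288, window_length_s=900.0, metric="number"
    )
    reported_bound = emission_bound(reported, chamber_volume_m3=0.22, k_sigma=1.0)
    print(
        f"reported statistics (mean 1e-4, sd 0.02): upper range "
        f"{round_sig(reported_bound.upper, 2):.0f} 1/s"
    )

    nio.write_json_report(
        {
            "simulated": {
                "derivative_stats": dataclasses.asdict(stats),
                "emission": dataclasses.asdict(bound),
            },
            "reported_statistics": {
                "derivative_stats": dataclasses.asdict(reported),
                "emission": dataclasses.asdict(reported_bound),
                "upper_2sf": round_sig(reported_bound.upper, 2),
            },
        },
        RESULTS / "emission_estimate.json",
        config={"window_s": args.window_s, "volume_m3": 0.22, "k_sigma": 1.0},
    )


if __name__ == "__main__":
    main()
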