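"""Calibrate the first-year Weibull event-time models and validate them
against synthetic patient-level data.

The published model derives its transition probabilities from Weibull
regressions on trial patient-level data that are not public.  This script
shows the two routes agreeing: (a) exact calibration from the printed
first-year and conditional second-year probabilities, and (b) maximum
likelihood on synthetic individual patient data generated from the same
calibration, with administrative censoring at the 6-, 9- and 12-month
visits.  Writes results/weibull_calibration.csv.
"""

import sys
from pathlib import Path

import pandas as pd

from acs_cea import default_configs
from acs_cea.survival import (
    calibrate_from_probs,
    conditional_annual_prob,
    fit_weibull_mle,
    survival_at,
)
from acs_cea.synthetic import ENDPOINTS, generate_ipd

OUT = Path(__file__).resolve().parents[1] / "results"
N_PER_ARM = 50_000


def main(seed: int = 2013) -> None:
    cfg = default_configs()["overall"]
    year2 = {
        "mi": cfg.longterm.q_mi,
        "stroke": cfg.longterm.q_stroke,
        "death": cfg.longterm.q_cv_fatal,
    }
    rows = []
    for offset, arm_name in enumerate(("ticagrelor", "clopidogrel")):
        arm = cfg.arm(arm_name)
        p1 = {"mi": arm.p_mi, "stroke": arm.p_stroke, "death": arm.p_death}
        ipd = generate_ipd(arm, N_PER_ARM, seed=seed + offset, longterm=cfg.longterm)
        for endpoint in ENDPOINTS:
            cal = calibrate_from_probs(p1[endpoint], year2[endpoint])
            mle = fit_weibull_mle(ipd, endpoint)
            rows.append(
                {
                    "arm": arm_name,
                    "endpoint": endpoint,
                    "p_year1_target": p1[endpoint],
                    "shape_calibrated": cal.shape,
                    "scale_calibrated": cal.scale,
                    "shape_mle": mle.shape,
                    "scale_mle": mle.scale,
                    "p_year1_mle": 1 - survival_at(mle, 1.0),
                    "q_year2_calibrated": conditional_annual_prob(cal, 2),
                    "n_events": mle.n_events,
                }
            )
    table = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "weibull_calibration.csv", index=False)
    print(table.to_string(index=False, float_format=lambda x: f"{x:.4f}"))
    worst = (table["p_year1_mle"] - table["p_year1_target"]).abs().max()
    print(
        f"\nLargest |fitted - target| first-year probability across 12 fits: "
        f"{worst:.4f} (n = {N_PER_ARM} patients/arm)."
    )
    print(
        "Calibrated shapes below 1 reproduce the front-loaded event hazard of "
        "the first post-ACS year; the MLE route recovers them from censored "
        "synthetic data."
    )


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 2013)
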