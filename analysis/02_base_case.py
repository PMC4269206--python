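"""Deterministic base case: lifetime costs, life-years, QALYs and ICERs for
the three cohorts (overall ACS, NSTEMI/UA, STEMI; all low-dose ASA).

Start age 62, 72% male, German-2009 life-table reconstruction, 3% discount.
Writes results/base_case.csv in the layout of the published results table.
"""

from pathlib import Path

import pandas as pd

from acs_cea import bundled_life_table, default_configs, run_cea

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    lt = bundled_life_table("german_2009")
    rows = []
    for label, cfg in default_configs().items():
        res = run_cea(cfg, lt)
        rows += [
            {
                "cohort": label,
                "quantity": "costs_eur",
                "ticagrelor": round(res.ticagrelor.cost),
                "clopidogrel": round(res.clopidogrel.cost),
                "incremental": round(res.delta_cost),
                "icer": "",
            },
            {
                "cohort": label,
                "quantity": "life_years",
                "ticagrelor": round(res.ticagrelor.life_years, 4),
                "clopidogrel": round(res.clopidogrel.life_years, 4),
                "incremental": round(res.delta_ly, 4),
                "icer": round(res.icer_ly) if res.icer_ly else "",
            },
            {
                "cohort": label,
                "quantity": "qalys",
                "ticagrelor": round(res.ticagrelor.qalys, 4),
                "clopidogrel": round(res.clopidogrel.qalys, 4),
                "incremental": round(res.delta_qaly, 4),
                "icer": round(res.icer_qaly) if res.icer_qaly else "",
            },
        ]
    table = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "base_case.csv", index=False)
    print(table.to_string(index=False))
    overall = table[table["cohort"] == "overall"]
    icer = overall[overall["quantity"] == "life_years"]["icer"].iloc[0]
    print(
        f"\nTicagrelor adds ~EUR {overall[overall['quantity']=='costs_eur']['incremental'].iloc[0]} "
        f"per patient over lifetime and gains "
        f"{overall[overall['quantity']=='life_years']['incremental'].iloc[0]} life-years, "
        f"an ICER of ~EUR {icer} per life-year gained in the overall cohort."
    )


if __name__ == "__main__":
    main()
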