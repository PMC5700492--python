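"""One-way deterministic sensitivity analysis (scenario table).

Reruns the pipeline for each built-in scenario — time horizon 10/20
years, 0% discounting of effects or costs, log-logistic projection,
lower hazard ratios, no subsequent-line costs, post-progression
efficacy +/-20%, ibrutinib price +/-20% — and tabulates ICERs with the
percent change from the base case.

Output: results/dsa.csv
"""
from pathlib import Path

from wmcea.params import load_default_parameters
from wmcea.sensitivity import run_dsa, table_scenarios

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)


def main() -> None:
    params = load_default_parameters()
    table = run_dsa(params, table_scenarios())
    table.to_csv(RESULTS / "dsa.csv", index=False)

    shown = table[["description", "delta_cost", "delta_ly", "icer", "pct_vs_base"]]
    print(shown.to_string(index=False, float_format=lambda v: f"{v:,.2f}"))
    worst = table.loc[table.icer.idxmax()]
    best = table.loc[table.icer.idxmin()]
    print(
        f"\nICER range across scenarios: EUR {best.icer:,.0f}"
        f" ({best.description}) to EUR {worst.icer:,.0f} ({worst.description})"
    )


if __name__ == "__main__":
    main()
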