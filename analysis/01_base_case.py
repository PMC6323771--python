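"""Deterministic base case: lifetime costs, outcomes and the efficiency frontier.

Runs the monthly-cycle Markov cohort model for all six treatment options at
the point estimates of every input, accumulates discounted (3%/year) and
undiscounted lifetime costs, life years and QALYs, and labels dominance on
the cost-sorted efficiency frontier.

Writes results/base_case.csv and prints the results table with the frontier
ICERs (THB per QALY gained).
"""

from pathlib import Path

from gist_cua import default_life_table, default_parameters, efficiency_frontier, evaluate_options

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    params = default_parameters()
    life_table = default_life_table()
    results = evaluate_options(params, life_table)
    frontier = efficiency_frontier(results)

    df = frontier.to_frame(results)
    df["cost_undisc"] = [results[s].cost_undisc for s in df["strategy"]]
    df["qaly_undisc"] = [results[s].qaly_undisc for s in df["strategy"]]
    df = df[
        ["strategy", "cost_undisc", "cost_disc", "ly_undisc", "ly_disc",
         "qaly_undisc", "qaly_disc", "label", "icer_vs_previous"]
    ]
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "base_case.csv", index=False)

    print("Lifetime results per 60-year-old patient (THB 2014, discounted at 3%/yr):")
    print(df.to_string(index=False, float_format=lambda v: f"{v:,.2f}"))
    print()
    print(f"Efficiency frontier: options {' -> '.join(frontier.frontier)}")
    for sid, val in frontier.icers.items():
        if val is not None:
            print(f"  ICER option {sid} vs previous frontier member: {val:,.0f} THB/QALY")
    dominated = [s for s in frontier.order if frontier.labels[s] != "on_frontier"]
    print(f"Dominated options: {', '.join(dominated)}")
    r1, r22 = results["1"], results["2.2"]
    print(
        f"Option 2.2 vs option 1: +{r22.ly_disc - r1.ly_disc:.2f} discounted LY, "
        f"+{r22.qaly_disc - r1.qaly_disc:.2f} QALYs, "
        f"+{r22.cost_disc - r1.cost_disc:,.0f} THB"
    )
    print(f"wrote {OUT / 'base_case.csv'}")


if __name__ == "__main__":
    main()
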