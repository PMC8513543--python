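"""Probabilistic sensitivity analysis of the scenario comparisons.

Monte Carlo over the parameter distributions (beta utilities, gamma
costs, Dirichlet transition rows, 20%-SE effect size, 10%-SE
intervention cost), common random numbers across scenarios. Writes the
scenario summary, per-year incremental tables, CE-plane clouds and a
CE-plane figure. 1,000 draws keep this driver quick; the CLI defaults
to the full 5,000.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

import ktah_cea as k
from ktah_cea.params import load_parameters
from ktah_cea.psa import run_psa, summarize

RESULTS = Path(__file__).resolve().parent.parent / "results"
N_DRAWS = 1000
SEED = 2026


def main() -> None:
    params = load_parameters(RESULTS / "parameters.yaml")
    scenarios = [k.base_case(), k.optimistic(), k.pessimistic()]
    deterministic = {}
    for spec in scenarios:
        res = k.run_model(k.apply_intervention(params, spec))
        deterministic[spec.label] = (res.outcomes.total_cost, res.outcomes.total_qalys)

    psa = run_psa(params, scenarios, n_draws=N_DRAWS, seed=SEED)
    summary = summarize(psa, deterministic=deterministic)
    summary.scenario_table.to_csv(RESULTS / "psa_scenarios.csv", index=False)

    print(f"PSA: {N_DRAWS} draws, seed {SEED}")
    print(summary.scenario_table.to_string(index=False, float_format=lambda v: f"{v:,.0f}"))
    for comp in summary.comparisons:
        comp.per_year.to_csv(
            RESULTS / f"incremental_{comp.scenario}_vs_{comp.comparator}.csv", index=False
        )
        comp.ce_plane.to_csv(
            RESULTS / f"ce_plane_{comp.scenario}_vs_{comp.comparator}.csv", index=False
        )
        print(
            f"{comp.scenario} vs {comp.comparator}: "
            f"mean dCost EUR {comp.mean_delta_cost:,.0f}, mean dQALY {comp.mean_delta_qaly:,.1f}, "
            f"ICER (ratio of means) {comp.icer_ratio_of_means.ratio:,.0f} "
            f"[{comp.icer_ratio_of_means.classification}], "
            f"deterministic ICER {comp.deterministic_icer.ratio:,.0f}"
        )

    fig, ax = plt.subplots(figsize=(6, 5))
    for comp in summary.comparisons:
        ax.scatter(
            comp.ce_plane["delta_qaly"], comp.ce_plane["delta_cost"],
            s=4, alpha=0.3, label=f"{comp.scenario} vs {comp.comparator}",
        )
    ax.axhline(0, color="grey", lw=0.8)
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (EUR)")
    ax.set_title("Cost-effectiveness plane")
    ax.legend()
    fig.tight_layout()
    fig.savefig(RESULTS / "ce_plane.png", dpi=150)
    print(f"wrote CE plane to {RESULTS / 'ce_plane.png'}")


if __name__ == "__main__":
    main()
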