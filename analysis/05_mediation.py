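#!/usr/bin/env python
"""Mediation stage: does insula connectivity mediate the association between
extraversion and target-changing (fitted beta6)?  Runs the bootstrap screen
over the planted candidate edges.

Writes results/mediation.csv.
"""

from pathlib import Path

import pandas as pd

from catchball.mediation import mediation_screen

SEED = 20260131
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    profiles = pd.read_csv(OUT / "profiles.csv")
    betas = pd.read_csv(OUT / "betas.csv")
    edges = pd.read_csv(OUT / "candidate_edges.csv")

    cohort = (
        profiles[["participant_id", "extraversion", "iri_D"]]
        .merge(betas[["participant_id", "beta3", "beta6"]], on="participant_id")
        .merge(edges, on="participant_id")
    )
    edge_cols = [c for c in edges.columns if c != "participant_id"]
    candidates = [("extraversion", m, "beta6") for m in edge_cols]
    res = mediation_screen(candidates, cohort, n_boot=10_000, seed=SEED)
    res.to_csv(OUT / "mediation.csv", index=False)

    for r in res.itertuples():
        tag = "significant" if r.significant else ("marginal" if r.marginal else "ns")
        print(
            f"{r.x} -> {r.m} -> {r.y}: a = {r.a:+.3f}, b = {r.b:+.3f}, "
            f"a*b = {r.ab:+.3f}, c = {r.c:+.3f}, c' = {r.c_prime:+.3f}, "
            f"boot p = {r.boot_p_ab:.4f} [{tag}]"
        )


if __name__ == "__main__":
    main()
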