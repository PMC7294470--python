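#!/usr/bin/env python
"""Group-level behavioral statistics on the fitted cohort: one-sample tests
of each coefficient, session effects on strong balls to the instigators,
and trait regressions for the target-change and conformity parameters.

Writes results/group_tests.csv, results/trait_regressions.csv.
"""

from pathlib import Path

import pandas as pd

from catchball.group_stats import (
    beta_one_sample_tests,
    session_counts,
    session_effect_tests,
    trait_regression,
)
from catchball.io import read_records
from catchball.synthetic_cohort import BIG5, IRI

OUT = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"


def main() -> None:
    betas = pd.read_csv(OUT / "betas.csv")
    profiles = pd.read_csv(OUT / "profiles.csv")
    records = read_records(SCRATCH / "throws.csv", SCRATCH / "messages.csv")
    n = len(betas)

    one_sample = beta_one_sample_tests(betas)
    counts = session_counts(records)
    sess = session_effect_tests(counts)

    rows = [
        {"test": "one_sample_t", "parameter": r["parameter"], "statistic": r["t"],
         "df": r["df"], "p": r["p"]}
        for _, r in one_sample.iterrows()
    ]
    rows += [
        {"test": "rm_anova_strong_to_" + r["target"], "parameter": "session",
         "statistic": r["F"], "df": f"({r['df1']},{r['df2']})", "p": r["p"]}
        for _, r in sess["anova"].iterrows()
    ]
    rows += [
        {"test": f"paired_t_s{r['session_from']}to{r['session_to']}_" + r["target"],
         "parameter": "strong_count", "statistic": r["t"], "df": r["df"], "p": r["p"]}
        for _, r in sess["transitions"].iterrows()
    ]
    pd.DataFrame(rows).to_csv(OUT / "group_tests.csv", index=False)

    merged = profiles.drop(columns=[c for c in profiles.columns if c.startswith("beta")]).merge(
        betas, on="participant_id"
    )
    reg_rows = []
    for outcome, preds in (("beta6", list(BIG5)), ("beta3", list(IRI))):
        coef, corr = trait_regression(merged, outcome, preds)
        for _, r in coef.iterrows():
            reg_rows.append({"outcome": outcome, "kind": "ols", "predictor": r["predictor"],
                             "value": r["coef"], "t": r["t"], "p": r["p"]})
        for _, r in corr.iterrows():
            reg_rows.append({"outcome": outcome, "kind": "pearson", "predictor": r["predictor"],
                             "value": r["r"], "t": float("nan"), "p": r["p"]})
    pd.DataFrame(reg_rows).to_csv(OUT / "trait_regressions.csv", index=False)

    print(f"n = {n} (df = {n - 1} for one-sample tests)")
    for _, r in one_sample.iterrows():
        print(f"  {r['parameter']}: t({r['df']}) = {r['t']:+.3f}, p = {r['p']:.4f}")
    for _, r in sess["anova"].iterrows():
        print(f"  strong to {r['target']}: F({r['df1']},{r['df2']}) = {r['F']:.3f}, p = {r['p']:.4g}")
    for _, r in sess["transitions"].iterrows():
        print(
            f"  strong to {r['target']} s{r['session_from']}->s{r['session_to']}: "
            f"t({r['df']}) = {r['t']:+.3f}, p = {r['p']:.4g}"
        )
    ext = [r for r in reg_rows if r["outcome"] == "beta6" and r["predictor"] == "extraversion"]
    for r in ext:
        print(f"  extraversion vs beta6 ({r['kind']}): value = {r['value']:+.3f}, p = {r['p']:.4f}")


if __name__ == "__main__":
    main()
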