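#!/usr/bin/env python
"""Group statistics on the planted viability plate.

Reads results/data/plate_viability.csv (run 01_simulate_data.py first),
checks normality, runs the one-way ANOVA with Tukey HSD post hoc, and
reports each arm against the untreated control in the field's
fold / percent / stars convention.  Writes the comparison table under
results/plate_stats/.
"""

import argparse
from pathlib import Path

import pandas as pd

from neurocult import io, stats

IN = Path("results/data/plate_viability.csv")
OUT = Path("results/plate_stats")


def main():
    ap = argparse.ArgumentParser()
    ap.parse_args()
    if not IN.exists():
        raise SystemExit(f"{IN} missing - run analysis/01_simulate_data.py")
    OUT.mkdir(parents=True, exist_ok=True)

    table = stats.AssayTable.from_csv(IN, assay_name="viability")
    normality, any_bad = stats.test_normality(table)
    anova = stats.one_way_anova(table)
    pmat = stats.posthoc(table, method="tukey")
    print(f"normality: min Shapiro-Wilk p = {min(normality.values()):.3f}"
          f"{' (a group rejects normality)' if any_bad else ''}")
    print(f"one-way ANOVA: F({anova.df_between},{anova.df_within}) = "
          f"{anova.f_statistic:.2f}, p = {anova.p_value:.3g}")

    rows = []
    for g in table.groups:
        if g == "control":
            continue
        c = stats.fold_and_percent(table, g, "control", posthoc_p=pmat)
        rows.append({
            "group": g,
            "mean": c.mean_treatment, "sem": c.sem_treatment,
            "fold": c.fold_change, "percent": c.percent_change,
            "p": c.p_value, "stars": c.stars,
        })
        print(f"  {g:6s} vs control: "
              f"{stats.format_percent_change(c.percent_change)} "
              f"({stats.format_fold(c.fold_change)}; p = {c.p_value:.4g} "
              f"{c.stars})")
    io.write_csv(pd.DataFrame(rows), OUT / "comparisons.csv", seed=None)
    print(f"wrote {OUT / 'comparisons.csv'}")


if __name__ == "__main__":
    main()
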