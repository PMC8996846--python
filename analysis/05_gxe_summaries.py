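"""Genetic variance along the gradient and its environmental structure.

Computes ZGZ' (the reaction-norm genetic variance) and the sire
heritability at every herd-environment level, averages within levels of
each environmental category and within environmental groups, and tests the
level differences with trimmed one-way GLMs.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from rngxe.gxesummary import average_by_level, trim_and_test, zgz_gradient

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"


def main():
    argparse.ArgumentParser().parse_args()

    comp = pd.read_csv(OUT / "04_components_with_gxe.csv").set_index("term")["mean"]
    g0 = [[comp["sigma2_G"], comp["cov_G_GxE"]],
          [comp["cov_G_GxE"], comp["sigma2_GxE"]]]
    rv = [comp[f"residual_class_{c}"] for c in range(5)]
    gtab = pd.read_csv(OUT / "03_gradient.csv")
    env = pd.read_csv(OUT / "data" / "herd_environment.csv")

    grad_var = zgz_gradient(
        pd.DataFrame(g0).to_numpy(), gtab, residual_class_variances=rv,
        sigma2_pe=comp.get("pe", 0.0), sigma2_cg=comp.get("htd", comp.get("hyc", 0.0)),
    )
    grad_var.to_csv(OUT / "05_zgz_gradient.csv", index=False)

    means, tests = [], {}
    for grouping in ["area", "housing", "feeding", "pasture", "EG"]:
        means.append(average_by_level(grad_var, env, grouping))
        res = trim_and_test(grad_var, env, grouping)
        tests[grouping] = {"f": res["f_stat"], "df": list(res["df"]),
                           "p": res["p_overall"], "n_trimmed": res["n_trimmed"],
                           "skipped": res["skipped"]}
        if res["lsm"] is not None:
            res["lsm"].assign(grouping=grouping).to_csv(
                OUT / f"05_lsm_{grouping}.csv", index=False)
        if res["pairwise"] is not None:
            res["pairwise"].to_csv(OUT / f"05_pairwise_{grouping}.csv", index=False)
    pd.concat(means).to_csv(OUT / "05_zgz_by_level.csv", index=False)
    (OUT / "05_tests.json").write_text(json.dumps(tests, indent=2, default=float))

    for grouping, t in tests.items():
        flag = "skipped" if t["skipped"] else f"F = {t['f']:.2f}, p = {t['p']:.3g}"
        print(f"{grouping:8s} {flag}")


if __name__ == "__main__":
    main()
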