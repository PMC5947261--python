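#!/usr/bin/env python
"""Test whether individuals in larger groups occupy smaller relative niches.

Fits the individual-level mixed models — √RINI against group size
(continuous, then categorised small/large at 17 members) with age, sex and
the proportion of the group sampled as covariates and a group random
intercept — and the group-level ordinary linear model of pooled niche size
against group size.  Writes the tidy coefficient table and a JSON summary
under results/.
"""

import argparse
import json
import warnings
from pathlib import Path

import pandas as pd

from isoniche.pipeline import fit_rini_models


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--results", type=Path, default=Path("results"))
    args = parser.parse_args()

    ind_path = args.results / "individual_niche.csv"
    if not ind_path.exists():
        raise SystemExit(f"{ind_path} not found — run analysis/02_fit_niches.py first")
    individual = pd.read_csv(ind_path)
    group = pd.read_csv(args.results / "group_niche.csv")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results = fit_rini_models(individual, group)

    pd.concat(
        [r.to_frame().assign(model=name) for name, r in results.items()]
    ).to_csv(args.results / "niche_models.csv", index=False, float_format="%.10g")
    with open(args.results / "niche_models.json", "w") as fh:
        json.dump({n: r.to_json_dict() for n, r in results.items()}, fh, indent=1, sort_keys=True)

    cont = results["rini_continuous"]
    est, se = cont.coefficient("group_size")
    chi2, df, p, _ = cont.test("group_size")
    print(
        f"sqrt(RINI) ~ group size (continuous): beta = {est:+.4f} +/- {se:.4f}, "
        f"chi2_{df} = {chi2:.2f}, P = {p:.3g}, conditional r2 = {cont.r2_conditional:.2f}"
    )
    cat = results["rini_categorical"]
    est, se = cat.coefficient("large")
    chi2, df, p, _ = cat.test("group_size_class")
    print(
        f"sqrt(RINI) ~ group size (large vs small): beta = {est:+.3f} +/- {se:.3f}, "
        f"chi2_{df} = {chi2:.2f}, P = {p:.3g}"
    )
    if "group_ell95c_continuous" in results:
        glm = results["group_ell95c_continuous"]
        f_stat, df, p, _ = glm.test("group_size")
        print(
            f"group ell95c ~ group size: F = {f_stat:.3f}, P = {p:.2f} "
            "(group niche size itself need not track group size)"
        )
    direction = "smaller" if cont.coefficient("group_size")[0] < 0 else "larger"
    print(f"=> individuals in bigger groups occupy {direction} relative niches")


if __name__ == "__main__":
    main()
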