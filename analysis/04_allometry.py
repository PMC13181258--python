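#!/usr/bin/env python
"""Allometric scaling: per-group fits (eye height, ommatidia number, local
angles, relative eye investment vs head width) plus slope/intercept
difference tests between male morphs and between sexes.

Reads results/synthetic_inputs/specimens.csv, writes
results/allometry/{regression_panel.tsv,comparisons.tsv}.
"""
import argparse
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from eyemorph.allometry import (
    compare_intercepts,
    compare_slopes,
    fit_scaling,
    relative_investment,
)
from eyemorph.io import read_specimens, write_table

PANEL = [
    ("eye_height_mm", True),
    ("n_ommatidia", False),
    ("dphi_x_deg", False),
    ("dphi_y_deg", False),
]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--specimens", type=Path,
                    default=Path("results/synthetic_inputs/specimens.csv"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/allometry"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    df = read_specimens(args.specimens)
    males = df[df.group.isin(["small_male", "large_male"])]
    females = df[df.group == "female"]

    panel = []
    for response, loglog in PANEL:
        for grp, sub in df.groupby("group", sort=False):
            fit = fit_scaling(sub.head_width_mm, sub[response], log_log=loglog,
                              response=response, predictor="head_width_mm")
            panel.append({"group": grp} | asdict(fit))
            tag = f" b={fit.slope:.2f} ({fit.classification})" if loglog else \
                  f" slope={fit.slope:.3g}"
            print(f"{response} ~ head width, {grp}: R2={fit.r_squared:.2f},{tag}")
    rel = relative_investment(df)
    for grp, fit in rel["fits"].items():
        panel.append({"group": grp} | asdict(fit))
    write_table(pd.DataFrame(panel), args.out_dir / "regression_panel.tsv", sep="\t")

    comps = []
    sm = df[df.group == "small_male"]
    lm = df[df.group == "large_male"]
    tests = [
        ("eye_height slopes, morphs", sm, lm, "eye_height_mm", True, compare_slopes),
        ("ommatidia slopes, sexes", males, females, "n_ommatidia", False, compare_slopes),
        ("ommatidia intercepts, sexes", males, females, "n_ommatidia", False,
         compare_intercepts),
        ("rel eye height slopes, morphs", sm.assign(v=sm.eye_height_mm / sm.head_height_mm),
         lm.assign(v=lm.eye_height_mm / lm.head_height_mm), "v", False, compare_slopes),
    ]
    for label, a, b, col, loglog, fn in tests:
        F, dfree, p = fn(a.head_width_mm, a[col], b.head_width_mm, b[col], log_log=loglog)
        comps.append(dict(test=label, F=F, df=dfree, p=p))
        print(f"{label}: F={F:.2f}, df={dfree}, p={p:.3g}")
    write_table(pd.DataFrame(comps), args.out_dir / "comparisons.tsv", sep="\t")
    print(f"wrote {args.out_dir}/")


if __name__ == "__main__":
    main()
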