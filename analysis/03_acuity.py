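#!/usr/bin/env python
"""Inter-ommatidial angles and acuity: global (from ommatidia counts) and
local (radius-of-curvature method), with group comparisons.

Reads results/synthetic_inputs/, writes results/acuity/acuity.tsv and
comparisons.json, and prints the group means the way a results table would
show them.
"""
import argparse
import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from eyemorph.groupstats import compare_groups
from eyemorph.io import read_curvature, read_specimens, write_table
from eyemorph.optics import acuity_profile


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--in-dir", type=Path, default=Path("results/synthetic_inputs"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/acuity"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    specimens = read_specimens(args.in_dir / "specimens.csv")
    counts = dict(zip(specimens.specimen_id.astype(str), specimens.n_ommatidia))
    records = read_curvature(args.in_dir / "curvature.csv")

    by_spec: dict = {}
    for r in records:
        by_spec.setdefault((r.specimen_id, r.group), []).append(r)
    rows = [
        asdict(acuity_profile(n=counts.get(sid), records=rl, specimen_id=sid, group=grp))
        for (sid, grp), rl in by_spec.items()
    ]
    acuity = pd.DataFrame(rows)
    write_table(acuity, args.out_dir / "acuity.tsv", sep="\t")

    print("group means (dPhi_x / dPhi_y / dPhi_G, degrees):")
    for grp, sub in acuity.groupby("group", sort=False):
        print(
            f"  {grp:11s} {sub.dphi_x_deg.mean():.2f} / "
            f"{sub.dphi_y_deg.mean():.2f} / {sub.dphi_global_deg.mean():.2f}"
        )

    comparisons = []
    for var in ["dphi_x_deg", "dphi_y_deg", "dphi_global_deg"]:
        samples = {g: s[var].dropna().to_numpy() for g, s in acuity.groupby("group")}
        comp = compare_groups(samples, variable=var)
        row = asdict(comp)
        row["posthoc"] = [asdict(p) for p in comp.posthoc]
        comparisons.append(row)
        print(f"{var}: {comp.omnibus} statistic={comp.statistic:.2f} p={comp.p:.2g}")
    (args.out_dir / "comparisons.json").write_text(
        json.dumps(comparisons, indent=2, default=str) + "\n"
    )
    print(f"wrote {args.out_dir}/")


if __name__ == "__main__":
    main()
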