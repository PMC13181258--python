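#!/usr/bin/env python
"""Simulate the study's inputs: a 3-group specimen cohort, one eye cast per
group, and per-specimen curvature records.

Writes results/synthetic_inputs/: specimens.csv, curvature.csv, and
casts/<id>_{centers,outline}.csv.  Cast facet counts are scaled down from the
~11k facets of a real eye to 2,500 so the whole analysis chain reruns in
seconds; the spatial structure (hexagonal packing, dorsofrontal hotspot) is
unchanged.
"""
import argparse
from pathlib import Path

import numpy as np

from eyemorph.eyegen import EyeGenParams, generate_eye_cast, generate_specimen_cohort
from eyemorph.io import curvature_table, write_cast, write_table
from eyemorph.types import CurvatureRecord

GROUP_CAST_PARAMS = {
    # spacing mirrors the group mean facet diameters; amplitude the ratio of
    # largest to average diameter; females have the weaker, narrower hotspot
    "small_male": dict(lattice_spacing=0.0293, hotspot_amplitude=1.58),
    "large_male": dict(lattice_spacing=0.0304, hotspot_amplitude=1.56),
    "female": dict(lattice_spacing=0.0261, hotspot_amplitude=1.31),
}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=20180501)
    ap.add_argument("--out-dir", type=Path, default=Path("results/synthetic_inputs"))
    ap.add_argument("--n-per-group", type=int, default=10)
    ap.add_argument("--cast-facets", type=int, default=2500)
    args = ap.parse_args()

    out = args.out_dir
    (out / "casts").mkdir(parents=True, exist_ok=True)

    cohort = generate_specimen_cohort(n_per_group=args.n_per_group, seed=args.seed)
    write_table(cohort, out / "specimens.csv", seed=args.seed)
    print(f"cohort: {len(cohort)} specimens, head widths "
          f"{cohort.head_width_mm.min():.2f}-{cohort.head_width_mm.max():.2f} mm")

    rng = np.random.default_rng(args.seed + 1)
    for i, (group, cfg) in enumerate(GROUP_CAST_PARAMS.items()):
        sid = f"{group}_01"
        params = EyeGenParams(
            n_target=args.cast_facets, hotspot_center=(0.6, 0.45),
            gradient_scale=0.5, outline_shape=(3.4, 2.5),
            seed=args.seed + 10 + i, **cfg,
        )
        cast, true_d = generate_eye_cast(params, specimen_id=sid, group=group)
        write_cast(
            cast, out / "casts" / f"{sid}_centers.csv",
            out / "casts" / f"{sid}_outline.csv", true_diam_um=true_d,
        )
        print(f"cast {sid}: {cast.n_ommatidia} facets, "
              f"true diameters {true_d.min():.1f}-{true_d.max():.1f} um")

    # curvature records consistent with each specimen's local angles: with the
    # sampling angle a = 20 deg and a plausible arc b, D follows from dPhi
    records = []
    for _, row in cohort.iterrows():
        for axis, dphi in (("x", row.dphi_x_deg), ("y", row.dphi_y_deg)):
            b = float(rng.uniform(0.45, 0.65))
            d_um = dphi * b / 20.0 * 1000.0
            records.append(
                CurvatureRecord(
                    axis=axis, a_deg=20.0, b_mm=b, D_um=d_um,
                    specimen_id=row.specimen_id, group=row.group,
                    measurement_site="20 deg from inner edge, dorsofrontal",
                )
            )
    write_table(curvature_table(records), out / "curvature.csv", seed=args.seed)
    print(f"curvature: {len(records)} records -> {out / 'curvature.csv'}")


if __name__ == "__main__":
    main()
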