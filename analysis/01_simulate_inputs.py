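#!/usr/bin/env python
"""Generate the study inputs: template masks, a healthy-control database
cohort, and the 48 NC + 59 AD test cohort of uptake phantoms.

Volumes go to scratch/data/ (binary NIfTI intermediates); the manifests are
small CSVs. Downstream steps: 02 fits the normal database, 03 injects
attenuation-error fields and scores, 04 evaluates diagnostic accuracy.
"""

import argparse
from pathlib import Path

from petsim.phantom import PhantomParams, make_template_masks, simulate_cohort
from petsim.volumes import write_cohort, write_mask

GRID = (32, 32, 32)
N_DB_CONTROLS = 40
N_NC, N_AD = 48, 59


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--outdir", type=Path, default=Path("scratch/data"))
    args = parser.parse_args()

    params = PhantomParams(grid_shape=GRID)
    masks = make_template_masks(GRID)
    for label, m in zip(("brain", "preserved", "ad_pattern"), masks):
        args.outdir.mkdir(parents=True, exist_ok=True)
        write_mask(m, args.outdir / f"mask_{label}.nii.gz", params.voxel_size_mm)
    print(f"masks: brain={masks[0].n_voxels}, preserved={masks[1].n_voxels}, "
          f"ad_pattern={masks[2].n_voxels} voxels on {GRID} grid")

    db_cohort = simulate_cohort(params, masks, N_DB_CONTROLS, 0, seed=args.seed, id_prefix="db")
    write_cohort(db_cohort, args.outdir / "db")
    print(f"database cohort: {len(db_cohort)} healthy controls, "
          f"ages {db_cohort.ages.min():.1f}-{db_cohort.ages.max():.1f} y")

    cohort = simulate_cohort(params, masks, N_NC, N_AD, seed=args.seed + 1, id_prefix="sub")
    write_cohort(cohort, args.outdir / "study")
    print(f"study cohort: {len(cohort)} subjects ({N_NC} NC + {N_AD} AD), "
          f"AD hypometabolism severity {params.ad_severity:.0%}")


if __name__ == "__main__":
    main()
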