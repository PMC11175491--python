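#!/usr/bin/env python
"""Imaging pipeline on a synthetic cohort with known ground truth.

Generates a 21-subject cohort (label volumes with density, paired US/CT
thrombus fractions), then runs the volumetry side: class volumes and
volumetric thrombus fraction per subject, lumen position index, fraction
clustering, density summaries per cluster, and the US-vs-CT Spearman
concordance.  Everything is checked against the generator's manifest.

With the default disagreement noise (US sd 0.05, CT sd 0.02 on the
fraction scale) the rank correlation lands around 0.9; increasing
--us-noise pushes it down toward the weaker concordance regime seen with
hand-measured fractions.
"""

import json
import sys
import tempfile
import time
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from aaa_ilt.imaging import (  # noqa: E402
    CLASS_LUMEN,
    CLASS_THROMBUS,
    LabelVolume,
    class_volume,
    cluster_by_fraction,
    density_stats,
    lumen_position_index,
    spearman_rank,
    thrombus_fraction_volume,
)
from aaa_ilt.synthdata import CohortSpec, write_cohort  # noqa: E402

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    seed = int(sys.argv[sys.argv.index("--seed") + 1]) if "--seed" in sys.argv else 0
    us_noise = float(sys.argv[sys.argv.index("--us-noise") + 1]) if "--us-noise" in sys.argv else 0.05
    t0 = time.time()
    spec = CohortSpec(n_subjects=21, us_noise_sd=us_noise, seed=seed)
    with tempfile.TemporaryDirectory() as tmp:
        manifest = write_cohort(spec, tmp, volume_slices=4, spacing=(0.8, 0.8, 2.0),
                                overwrite=True)
        rows = []
        for rec in manifest["subjects"]:
            vol = LabelVolume.from_nifti(
                Path(tmp) / rec["volume"],
                Path(tmp) / rec["volume"].replace(".nii.gz", "_density.nii.gz"),
            )
            rows.append({
                "subject": rec["subject"],
                "true_fraction": rec["fraction"],
                "ct_fraction": thrombus_fraction_volume(vol),
                "lumen_volume_mm3": class_volume(vol, CLASS_LUMEN),
                "thrombus_volume_mm3": class_volume(vol, CLASS_THROMBUS),
                "position_index": lumen_position_index(vol),
                "density_median": density_stats(vol).median,
                "density_cluster": rec["density_cluster"][0],
            })
        vols = pd.DataFrame(rows)
        paired = pd.read_csv(Path(tmp) / "paired_fractions.csv")

    vols["cluster"] = cluster_by_fraction(vols["ct_fraction"])
    rho, p = spearman_rank(paired["us_fraction"], paired["ct_fraction"])
    recovery_err = float(np.abs(vols["ct_fraction"] - vols["true_fraction"]).max())
    med_by_cluster = vols.groupby("density_cluster")["density_median"].median()

    OUT.mkdir(exist_ok=True)
    vols.to_csv(OUT / "cohort_volumetry.csv", index=False)
    summary = {
        "n_subjects": len(vols),
        "spearman_rho": rho,
        "spearman_p": p,
        "max_fraction_recovery_error": recovery_err,
        "cluster_counts": vols["cluster"].value_counts().to_dict(),
        "density_median_by_cluster": {str(k): float(v) for k, v in med_by_cluster.items()},
    }
    (OUT / "cohort_summary.json").write_text(json.dumps(summary, indent=1) + "\n")

    print(f"cohort of {len(vols)} subjects analysed in {time.time() - t0:.0f} s")
    print(f"  volumetric fraction recovers truth to |err| <= {recovery_err:.3f} (voxelization)")
    print(f"  US-vs-CT Spearman rho = {rho:.3f} (p = {p:.2e}) at US noise sd {us_noise}")
    print(f"  fraction clusters: {summary['cluster_counts']}")
    print(f"  thrombus density medians by generator cluster: "
          f"{summary['density_median_by_cluster']} (ratio ~2 by construction)")
    print(f"tables in {OUT}/cohort_volumetry.csv")
    return 0


if __name__ == "__main__":
    sys.exit(main())
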