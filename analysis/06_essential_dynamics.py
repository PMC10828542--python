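#!/usr/bin/env python
"""Essential dynamics and conformational clustering of the two systems.

PCA of the wild-type trajectory defines the essential subspace; the
split system is projected onto it over the shared residues so both
occupy one PC1-PC2 plane.  Gromos clustering of the final 40% of each
trajectory extracts a representative (medoid) snapshot.  Writes
results/essential_dynamics_summary.tsv and PC1-PC2 projections.
"""

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull

import splitperox as sp
from splitperox.essential_dynamics import (
    gromos_cluster,
    pca,
    project_onto,
    shared_calpha_selections,
)
from splitperox.stability_metrics import last_fraction_window

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
RESULTS.mkdir(exist_ok=True)

SYSTEMS = {"wildtype": (0.6, 2024), "split": (0.2, 2025)}
N_FRAMES = 400


def main() -> None:
    helix = sp.make_helix(25)
    aligned = {}
    for name, (sigma, seed) in SYSTEMS.items():
        traj, _ = sp.make_trajectory(
            helix, sp.SyntheticSpec(n_frames=N_FRAMES, sigma=sigma, rot_deg=5.0,
                                    trans_ang=1.0, seed=seed),
        )
        aligned[name] = sp.align_trajectory(traj)

    reference = pca(aligned["wildtype"], k=2)
    _, shared_split = shared_calpha_selections(aligned["wildtype"], aligned["split"])
    proj = {
        "wildtype": reference.projections,
        "split": project_onto(reference, aligned["split"], shared_split)[:, :2],
    }
    rows = []
    for name in SYSTEMS:
        np.savetxt(RESULTS / f"pca_projections_{name}.tsv", np.round(proj[name], 3),
                   fmt="%.3f", header="PC1 PC2 (A), wild-type essential subspace")
        start, stop = last_fraction_window(N_FRAMES, 0.4)
        tail = aligned[name].with_frames(aligned[name].frames[start:stop])
        clustering = gromos_cluster(tail, rmsd_cutoff=1.0)
        rows.append(
            {
                "system": name,
                "pc12_area_A2": round(float(ConvexHull(proj[name]).volume), 2),
                "pc12_explained": round(float(reference.explained_fraction[:2].sum()), 3)
                if name == "wildtype" else np.nan,
                "n_clusters_last40pct": clustering.n_clusters,
                "top_cluster_size": int(clustering.sizes[0]),
                "representative_frame": int(start + clustering.representatives[0]),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "essential_dynamics_summary.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    wt_area = df.loc[df.system == "wildtype", "pc12_area_A2"].item()
    sp_area = df.loc[df.system == "split", "pc12_area_A2"].item()
    print(f"finding: in the shared essential subspace the split system "
          f"occupies {sp_area:.1f} A^2 against the wild type's {wt_area:.1f} A^2 — "
          f"the lower-fluctuation system shows the smallest structural "
          f"variation, and its most populated cluster supplies the "
          f"representative snapshot.")


if __name__ == "__main__":
    main()
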