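#!/usr/bin/env python
"""Fibril structural stability: build the hexameric toy fibril, verify its
planted contacts/H-bonds/salt bridges with the geometric operators, then
follow subunit distances and secondary structure along a dissociation
trajectory (the destabilisation signature: the terminal subunit drifts
away while the rest of the stack holds together)."""

from pathlib import Path

import numpy as np

from synucleo import fibril_metrics as fm
from synucleo import structio
from synucleo import synthetic_data as sd

OUT = Path(__file__).resolve().parents[1] / "results" / "fibril"
OUT.mkdir(parents=True, exist_ok=True)
SEED = 1

st, truth = sd.make_fibril(sd.FibrilSpec(n_subunits=6), seed=SEED)
structio.write_structure(st, OUT / "fibril_synthetic.pdb")
print(f"built fibril: {len(st.chains)} subunits, {st.n_atoms} atoms")

hbonds = fm.detect_hbonds(st)
intra = sum(b.is_intra_subunit for b in hbonds)
inter = fm.inter_subunit_hbonds(len(hbonds), intra)
sb_inter = fm.count_salt_bridges(st, scope="inter")
print(f"H-bonds: {len(hbonds)} total, {intra} intra, {inter} inter "
      f"(ground truth {truth.n_inter_hbonds})")
print(f"salt bridges (inter-subunit): {sb_inter} (ground truth "
      f"{truth.n_inter_salt_bridges})")

cm = fm.contact_map(st)
print(f"contact map: {cm.n_contacts} residue contacts at {cm.cutoff} Å cutoff")
labels = [f"{c}{r}" for c, r in cm.residue_labels]
structio.write_table(
    [{"residue_a": labels[i], "residue_b": labels[j]}
     for i in range(len(labels)) for j in range(i + 1, len(labels))
     if cm.contacts[i, j]],
    OUT / "contacts.csv",
)

traj = sd.make_dissociation_trajectory(st, n_frames=30,
                                       displacement_per_frame=0.1, seed=SEED)
series = fm.compute_subunit_distances(traj)
structio.write_table(
    [{"pair": f"{s.chain_pair[0]}-{s.chain_pair[1]}", "frame": k, "distance_A": v}
     for s in series for k, v in enumerate(s.values)],
    OUT / "subunit_distances.csv",
)
s12 = series[0].values
print(f"S1-S2 distance: {s12[0]:.2f} -> {s12[-1]:.2f} Å over {traj.n_frames} "
      f"frames (strictly increasing: {bool(np.all(np.diff(s12) > 0))})")
for s in series[1:]:
    assert np.ptp(s.values) < 1e-6
print("all other adjacent pairs constant — dissociation confined to S1")

ss = fm.average_ss_fractions(traj)
structio.write_table(
    [{"chain": c, "residue": r,
      "frac_H": ss.averaged_fractions[k, 0],
      "frac_E": ss.averaged_fractions[k, 1],
      "frac_C": ss.averaged_fractions[k, 2]}
     for k, (c, r) in enumerate(ss.residue_labels)],
    OUT / "secondary_structure.csv",
)
print(f"wrote tables to {OUT}")
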