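#!/usr/bin/env python
"""Persistent interface contacts and the difference map between two systems.

Plants an interface in which one bulky residue (Ile-93 of a PIP2-like
monomer) makes several persistent contacts with the partner's TM4-TM5
residues, and a second system where the equivalent position (Ala-103 of
a PIP1-like monomer, mapped via the paralog alignment offset) loses most
of them — then recovers exactly that difference with the 4 Å / 70%
criterion and the contact difference map.  Writes
results/contacts_maps.csv and results/contacts_difference.csv.
"""

from pathlib import Path

import pandas as pd

from chanflux.contacts import contact_difference_map, persistent_contact_map
from chanflux.synthetic import gen_interface_toy

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

# PIP2-like interface: residue 93 contacts four TM4-TM5 partners
pip2_like, truth2 = gen_interface_toy(
    persistent_pairs=[(93, 190), (93, 194), (93, 220), (93, 221), (50, 150)],
    transient_pairs=[(60, 160, 0.40)],
    n_frames=100, seed=21,
)
# PIP1-like interface: the small residue at the equivalent position (103)
# keeps only one of those contacts
pip1_like, truth1 = gen_interface_toy(
    persistent_pairs=[(103, 220), (50, 150)],
    transient_pairs=[(60, 160, 0.40)],
    n_frames=100, seed=22,
)

m2 = persistent_contact_map(pip2_like, "chain A", "chain B")
m1 = persistent_contact_map(pip1_like, "chain A", "chain B")
assert m2.persistent_pairs == truth2["persistent_set"]
assert m1.persistent_pairs == truth1["persistent_set"]

maps = pd.concat([
    m2.to_dataframe().assign(system="PIP2-like"),
    m1.to_dataframe().assign(system="PIP1-like"),
])
maps.to_csv(OUT / "contacts_maps.csv", index=False)

# map the PIP1-like numbering (103) onto the PIP2-like frame (93)
diff = contact_difference_map(m2, m1, residue_map={103: 93, 50: 50, 60: 60})
diff.to_csv(OUT / "contacts_difference.csv", index=False)
print(maps.to_string(index=False))
print("\ndifference map (PIP2-like minus PIP1-like, PIP2 numbering):")
print(diff.to_string(index=False))
gained = diff[diff.delta_frequency > 0]
print(f"\n{len(gained)} contacts are unique to the bulky-residue interface — "
      "all involve residue 93, reproducing the expected Ile-93 hub")
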