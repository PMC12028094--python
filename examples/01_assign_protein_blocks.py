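"""Encode a small backbone ensemble as Protein Block strings.

Builds a 12-residue chain that is helical in every frame except the last,
which is extended, and prints the PB string of each frame.  `m` marks the
α-helix core prototype, `d` the central β-strand prototype, and `Z` the two
positions at each terminus whose 5-residue window is incomplete.
"""

import numpy as np

from pbflex import assign_ensemble, backbone_dihedrals
from pbflex.geometry import DihedralSeries
from pbflex.synthetic import ensemble_from_dihedrals, helix_dihedrals, strand_dihedrals

n_res = 12
helix_phi, helix_psi = helix_dihedrals(n_res)
strand_phi, strand_psi = strand_dihedrals(n_res)

phi = np.vstack([helix_phi, helix_phi, strand_phi])
psi = np.vstack([helix_psi, helix_psi, strand_psi])
series = DihedralSeries(phi=phi, psi=psi, resids=np.arange(1, n_res + 1))

# round-trip through 3D coordinates: build backbones, re-measure dihedrals
ensemble = ensemble_from_dihedrals(series)
pb = assign_ensemble(backbone_dihedrals(ensemble))

for frame in range(pb.n_frames):
    print(f"frame {frame}: {''.join(pb.labels[frame])}")
print("-> one letter per residue; interior helix residues read 'm',")
print("   the extended frame reads 'd', termini are unassignable 'Z'.")
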