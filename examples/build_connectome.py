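"""Build a weighted structural connectivity matrix from streamline records.

Each streamline contributes the inverse of its length (in mm) to the
weight of the region pair it connects; a per-subject scale factor
corrects for seed density, and weak edges are pruned at a threshold of 1.
"""

from svdnet import Parcellation, StreamlineSet, build_connectivity_matrix

parcellation = Parcellation(
    ("Frontal_Sup_L", "Precuneus_L", "Temporal_Mid_L"),
    rich_club_labels=("Frontal_Sup_L", "Precuneus_L"),
)

# two streamlines between the same pair, plus one weak long-range path
streamlines = StreamlineSet(
    [
        ("Frontal_Sup_L", "Precuneus_L", 2.0),   # contributes 1/2
        ("Frontal_Sup_L", "Precuneus_L", 4.0),   # contributes 1/4
        ("Precuneus_L", "Temporal_Mid_L", 80.0),  # contributes 1/80
    ],
    scale=2.0,  # seed-density correction factor
)

raw = build_connectivity_matrix(streamlines, parcellation, threshold=0.0)
pruned = build_connectivity_matrix(streamlines, parcellation, threshold=1.0)

print("raw weight Frontal_Sup_L - Precuneus_L :", raw.weights[0, 1])
print("raw weight Precuneus_L - Temporal_Mid_L:", raw.weights[1, 2])
print("after threshold 1, weak edge weight    :", pruned.weights[1, 2])

# The strong pair gets 2 * (1/2 + 1/4) = 1.5 mm^-1 and survives the
# threshold; the long, sparsely connected pair (2/80 = 0.025) is pruned
# as a likely false-positive connection.
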