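"""Parcel labels for the AAL-116 parcellation.

The 116-region Automated Anatomical Labeling atlas (90 cerebral regions,
18 cerebellar hemispheric regions, 8 vermal regions) is the default node
set for connectomes built by this package.  The historical spelling
``Cerebelum`` is kept because it is the label shipped with the atlas and
used throughout the literature.
"""

from __future__ import annotations

_CEREBRAL = [
    "Precentral", "Frontal_Sup", "Frontal_Sup_Orb", "Frontal_Mid",
    "Frontal_Mid_Orb", "Frontal_Inf_Oper", "Frontal_Inf_Tri",
    "Frontal_Inf_Orb", "Rolandic_Oper", "Supp_Motor_Area", "Olfactory",
    "Frontal_Sup_Medial", "Frontal_Med_Orb", "Rectus", "Insula",
    "Cingulum_Ant", "Cingulum_Mid", "Cingulum_Post", "Hippocampus",
    "ParaHippocampal", "Amygdala", "Calcarine", "Cuneus", "Lingual",
    "Occipital_Sup", "Occipital_Mid", "Occipital_Inf", "Fusiform",
    "Postcentral", "Parietal_Sup", "Parietal_Inf", "SupraMarginal",
    "Angular", "Precuneus", "Paracentral_Lobule", "Caudate", "Putamen",
    "Pallidum", "Thalamus", "Heschl", "Temporal_Sup", "Temporal_Pole_Sup",
    "Temporal_Mid", "Temporal_Pole_Mid", "Temporal_Inf",
]

_CEREBELLAR = [
    "Cerebelum_Crus1", "Cerebelum_Crus2", "Cerebelum_3", "Cerebelum_4_5",
    "Cerebelum_6", "Cerebelum_7b", "Cerebelum_8", "Cerebelum_9",
    "Cerebelum_10",
]

_VERMIS = [
    "Vermis_1_2", "Vermis_3", "Vermis_4_5", "Vermis_6", "Vermis_7",
    "Vermis_8", "Vermis_9", "Vermis_10",
]

AAL116_LABELS: list[str] = (
    [f"{name}_{side}" for name in _CEREBRAL for side in ("L", "R")]
    + [f"{name}_{side}" for name in _CEREBELLAR for side in ("L", "R")]
    + list(_VERMIS)
)

assert len(AAL116_LABELS) == 116


def default_labels(n_parcels: int) -> list[str]:
    """AAL-116 names when the panel has 116 parcels, generic names otherwise."""
    if n_parcels == 116:
        return list(AAL116_LABELS)
    return [f"Parcel_{i:03d}" for i in range(n_parcels)]
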