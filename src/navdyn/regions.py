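"""The fixed 46-region bilateral parcellation used throughout.

23 large-scale cortical regions per hemisphere (HCP-MMP-derived grouping,
taken as a fixed label set). Region labels are ``<name>_<hemi>`` with hemi in
{L, R}. The medial temporal lobe (MTL) comprises the hippocampal formation and
the parahippocampal region.
"""

from __future__ import annotations

# Ordered roughly by typical intersubject similarity (visual stream first).
REGION_NAMES: tuple[str, ...] = (
    "dorsal_visual_area",
    "ventral_visual_area",
    "early_visual_cortex",
    "superior_parietal_lobe",
    "middle_temporal_lateral_occipital",
    "precuneus_parieto_occipital_sulcus",
    "premotor_cortex",
    "temporo_parieto_occipital_junction",
    "inferior_parietal_lobe",
    "dorsolateral_prefrontal",
    "paracentral_lobule_midcingulate",
    "parahippocampal_region",
    "inferior_frontal_cortex",
    "lateral_temporal_lobe",
    "posterior_opercular_cortex",
    "posterior_cingulate_cortex",
    "anterior_cingulate_medial_prefrontal",
    "auditory_association_area",
    "somatosensory_motor_cortex",
    "early_auditory_cortex",
    "insular_frontal_opercular",
    "orbitofrontal_frontopolar",
    "hippocampal_formation",
)

HEMISPHERES: tuple[str, str] = ("L", "R")

#: All 46 region labels, L/R interleaved per name.
REGION_LABELS: tuple[str, ...] = tuple(
    f"{name}_{hemi}" for name in REGION_NAMES for hemi in HEMISPHERES
)

HIPPOCAMPAL_FORMATION: tuple[str, str] = (
    "hippocampal_formation_L",
    "hippocampal_formation_R",
)

MTL_REGIONS: tuple[str, ...] = (
    "hippocampal_formation_L",
    "hippocampal_formation_R",
    "parahippocampal_region_L",
    "parahippocampal_region_R",
)


def split_label(label: str) -> tuple[str, str]:
    """Split ``<name>_<hemi>`` into (name, hemisphere)."""
    name, _, hemi = label.rpartition("_")
    if hemi not in HEMISPHERES or name not in REGION_NAMES:
        raise KeyError(f"unknown region label: {label!r}")
    return name, hemi


def bilateral_pair(label: str) -> tuple[str, str]:
    """Both hemisphere labels for the region a label belongs to."""
    name, _ = split_label(label)
    return (f"{name}_L", f"{name}_R")
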