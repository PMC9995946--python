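"""Morphometric feature registry.

Two feature families are used throughout:

* VBM (voxel-based morphometry): subcortical/global segmentation volumes
  plus Desikan-Killiany cortical parcellation volumes, expressed as a
  percentage of total intracranial volume after bilateral averaging.
  Feature names are prefixed ``vol_``.
* SBM (surface-based morphometry): Desikan-Killiany cortical thickness
  (mm, prefix ``thick_``) and surface area (mm^2, prefix ``area_``),
  bilaterally averaged.

The default registry therefore holds 45 VBM columns (11 subcortical/global
+ 34 cortical) and 68 SBM columns (34 + 34).
"""

from __future__ import annotations

__all__ = [
    "DK_REGIONS",
    "SUBCORTICAL_STRUCTURES",
    "vbm_feature_names",
    "sbm_feature_names",
    "default_feature_names",
    "feature_set_columns",
    "cortical_volume_columns",
    "FEATURE_SETS",
]

#: The 34 cortical regions of the Desikan-Killiany atlas (FreeSurfer aparc names).
DK_REGIONS: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "frontalpole",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "insula",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "paracentral",
    "parahippocampal",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "temporalpole",
    "transversetemporal",
)

#: Bilateral subcortical/global structures taken from the aseg segmentation.
SUBCORTICAL_STRUCTURES: tuple[str, ...] = (
    "hippocampus",
    "amygdala",
    "thalamus",
    "putamen",
    "caudate",
    "pallidum",
    "accumbens",
    "lateral_ventricle",
    "inferior_lateral_ventricle",
    "cerebral_white_matter",
    "cerebral_cortex",
)

FEATURE_SETS: tuple[str, ...] = ("VBM", "SBM", "VBM+SBM")


def vbm_feature_names() -> list[str]:
    """Volume features, % of TIV: subcortical/global then DK cortical."""
    return [f"vol_{s}" for s in SUBCORTICAL_STRUCTURES] + [f"vol_{r}" for r in DK_REGIONS]


def sbm_feature_names() -> list[str]:
    """Surface features: DK cortical thickness then surface area."""
    return [f"thick_{r}" for r in DK_REGIONS] + [f"area_{r}" for r in DK_REGIONS]


def default_feature_names() -> list[str]:
    return vbm_feature_names() + sbm_feature_names()


def feature_set_columns(feature_names, feature_set: str) -> list[str]:
    """Subset ``feature_names`` to one morphometry family.

    ``feature_set`` is ``"VBM"``, ``"SBM"`` or ``"VBM+SBM"``; membership is
    decided by the name prefix so real and synthetic pipelines share it.
    """
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {feature_set!r}; known: {FEATURE_SETS}")
    vbm = [n for n in feature_names if n.startswith("vol_")]
    sbm = [n for n in feature_names if n.startswith(("thick_", "area_"))]
    if feature_set == "VBM":
        return vbm
    if feature_set == "SBM":
        return sbm
    return vbm + sbm


def cortical_volume_columns(feature_names) -> list[str]:
    """The DK cortical parcellation volume columns present in ``feature_names``."""
    dk = {f"vol_{r}" for r in DK_REGIONS}
    return [n for n in feature_names if n in dk]
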