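"""Region-of-interest naming conventions for the morphometry feature set.

The feature space is the hemisphere-averaged FreeSurfer parcellation used
throughout the package: 34 Desikan-Killiany cortical regions measured by
cortical thickness (mm) and seven subcortical gray-matter structures
measured by volume (mm^3), for 41 features in total.  Wide input tables
carry one column per hemisphere with ``lh_``/``rh_`` prefixes; the internal
matrix is always hemisphere-averaged.
"""

from __future__ import annotations

# 34 cortical labels of the Desikan-Killiany atlas (FreeSurfer aparc order).
CORTICAL_ROIS: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "parahippocampal",
    "paracentral",
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
    "frontalpole",
    "temporalpole",
    "transversetemporal",
    "insula",
)

# Seven subcortical gray-matter structures (FreeSurfer aseg naming, without
# the Left-/Right- prefix; wide tables use lh_/rh_ like the cortical ROIs).
SUBCORTICAL_ROIS: tuple[str, ...] = (
    "thalamus",
    "caudate",
    "putamen",
    "pallidum",
    "hippocampus",
    "amygdala",
    "accumbens",
)

ALL_ROIS: tuple[str, ...] = CORTICAL_ROIS + SUBCORTICAL_ROIS

#: feature kind per ROI: "thickness" (mm) or "volume" (mm^3)
ROI_KIND: dict[str, str] = {
    **{r: "thickness" for r in CORTICAL_ROIS},
    **{r: "volume" for r in SUBCORTICAL_ROIS},
}

N_FEATURES = len(ALL_ROIS)

assert len(CORTICAL_ROIS) == 34 and len(SUBCORTICAL_ROIS) == 7


def roi_kinds(rois: list[str] | tuple[str, ...]) -> list[str]:
    """Kind tag ("thickness"/"volume") for each ROI name, in order."""
    unknown = [r for r in rois if r not in ROI_KIND]
    if unknown:
        raise KeyError(f"unknown ROI name(s): {unknown}")
    return [ROI_KIND[r] for r in rois]
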