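"""Atlas labels and resting-state-network (RSN) definitions.

The cortical parcellation follows the automated anatomical labelling (AAL)
scheme: 90 cerebral parcels, of which 12 subcortical structures (bilateral
hippocampus, amygdala, caudate, putamen, pallidum, thalamus) are removed,
leaving the 78 cortical regions of interest used for connectivity.

The shipped RSN memberships are best-effort reconstructions of the
literature-based networks used in resting-state work (default mode network,
left/right fronto-parietal, executive, sensorimotor, temporo-parietal,
visual), with two conventional modifications that keep within-network
connections unique: the superior parietal gyrus stands in for the precuneus
in the fronto-parietal networks, and the inferior frontal gyrus is split,
pars opercularis going to the temporo-parietal network and pars
triangularis to the fronto-parietal networks.  They are configuration, not
ground truth: callers may supply their own membership JSON.
"""

from __future__ import annotations

#: 45 cerebral AAL region stems; each exists as _L and _R (90 labels total).
_AAL_STEMS: tuple[str, ...] = (
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
)

#: The 90-label cerebral parcellation (left/right interleaved).
AAL90_LABELS: tuple[str, ...] = tuple(
    f"{stem}_{side}" for stem in _AAL_STEMS for side in ("L", "R"))

_SUBCORTICAL_STEMS = ("Hippocampus", "Amygdala", "Caudate", "Putamen",
                      "Pallidum", "Thalamus")

#: The 12 subcortical labels removed before connectivity analysis.
SUBCORTICAL_LABELS: tuple[str, ...] = tuple(
    f"{stem}_{side}" for stem in _SUBCORTICAL_STEMS for side in ("L", "R"))


def cortical_labels() -> tuple[str, ...]:
    """The 78 cortical ROI labels (90 cerebral minus 12 subcortical)."""
    sub = set(SUBCORTICAL_LABELS)
    return tuple(lab for lab in AAL90_LABELS if lab not in sub)


def _bilateral(*stems: str) -> list[str]:
    return [f"{stem}_{side}" for stem in stems for side in ("L", "R")]


#: Default RSN memberships over the 78-ROI cortical atlas.  No ROI appears in
#: more than one network, so within-network connections are pairwise unique.
DEFAULT_RSNS: dict[str, list[str]] = {
    "default_mode": _bilateral("Frontal_Sup_Medial", "Cingulum_Post",
                               "Precuneus", "Angular"),
    "fronto_parietal_left": ["Frontal_Mid_L", "Frontal_Inf_Tri_L",
                             "Parietal_Sup_L", "Parietal_Inf_L"],
    "fronto_parietal_right": ["Frontal_Mid_R", "Frontal_Inf_Tri_R",
                              "Parietal_Sup_R", "Parietal_Inf_R"],
    "executive": _bilateral("Frontal_Sup", "Cingulum_Ant", "Cingulum_Mid"),
    "sensorimotor": _bilateral("Precentral", "Postcentral", "Supp_Motor_Area"),
    "temporo_parietal": _bilateral("Temporal_Sup", "Temporal_Mid",
                                   "Frontal_Inf_Oper", "SupraMarginal"),
    "visual": _bilateral("Calcarine", "Cuneus", "Lingual", "Occipital_Sup",
                         "Occipital_Mid", "Occipital_Inf"),
}


def validate_rsns(rsns: dict[str, list[str]], labels) -> None:
    """Check RSN memberships against an atlas label set.

    Raises ``ValueError`` naming the offending network/label if a member is
    unknown, duplicated, or a network has fewer than two ROIs.
    """
    known = set(labels)
    for name, members in rsns.items():
        if len(members) < 2:
            raise ValueError(f"RSN {name!r} has fewer than 2 ROIs")
        if len(set(members)) != len(members):
            raise ValueError(f"RSN {name!r} contains duplicate ROI labels")
        for lab in members:
            if lab not in known:
                raise ValueError(
                    f"RSN {name!r} references unknown ROI label {lab!r}")
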