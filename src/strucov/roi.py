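"""ROI schemes and region-pair enumeration.

The canonical region set combines seven subcortical gray-matter nuclei
(thalamus, caudate, putamen, pallidum, hippocampus, amygdala, accumbens) with
the 34 Desikan-Killiany cortical parcels per hemisphere (68 in total).  The
subcortical nuclei can be represented either bilaterally averaged
(``bilateral7``) or split by hemisphere (``lateralized14``); cortical parcels
are always lateralized.

Region names, their FreeSurfer label equivalents, and the lobe ordering live
in a plain-text registry (``registry/roi_registry.yaml``) so that atlas
renames are data edits, not code edits.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources
from typing import Literal

import yaml

from .exceptions import SchemaError

SchemeMode = Literal["bilateral7", "lateralized14"]

SUBCORTICAL_NAMES = (
    "thalamus",
    "caudate",
    "putamen",
    "pallidum",
    "hippocampus",
    "amygdala",
    "accumbens",
)

#: Families of association tests; sizes for the bilateral7 scheme are
#: 7, 21, 476, 68 and 2278 respectively.
FAMILIES = (
    "single_subcortical",
    "intra_subcortical",
    "subcortico_cortical",
    "single_cortical",
    "cortico_cortical",
)


@dataclass(frozen=True)
class ROI:
    """One region of interest.

    ``hemisphere`` is ``"bilateral"`` for averaged subcortical structures and
    ``"left"``/``"right"`` otherwise.  ``lobe_tag`` is set for cortical
    parcels only.
    """

    name: str
    tissue_class: Literal["subcortical", "cortical"]
    hemisphere: Literal["left", "right", "bilateral"]
    lobe_tag: str | None = None


@dataclass(frozen=True)
class ROIScheme:
    """An ordered, validated collection of ROIs.

    Column order in every volume table follows the order of ``rois``:
    subcortical structures first (registry order, left before right when
    lateralized), then left-hemisphere cortical parcels in lobe order, then
    right-hemisphere parcels in the same order.
    """

    rois: tuple[ROI, ...]
    mode: SchemeMode

    def __post_init__(self) -> None:
        names = [r.name for r in self.rois]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate ROI names in scheme")
        sub = self.subcortical_names
        expected = 7 if self.mode == "bilateral7" else 14
        if len(sub) != expected:
            raise SchemaError(
                f"{self.mode} scheme requires {expected} subcortical ROIs, got {len(sub)}"
            )
        if len(self.cortical_names) != 68:
            raise SchemaError(
                f"scheme requires 68 cortical ROIs, got {len(self.cortical_names)}"
            )

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.rois]

    @property
    def subcortical_names(self) -> list[str]:
        return [r.name for r in self.rois if r.tissue_class == "subcortical"]

    @property
    def cortical_names(self) -> list[str]:
        return [r.name for r in self.rois if r.tissue_class == "cortical"]


def _load_registry() -> dict:
    text = resources.files("strucov").joinpath("registry/roi_registry.yaml").read_text()
    return yaml.safe_load(text)


def load_scheme(mode: SchemeMode = "bilateral7") -> ROIScheme:
    """Build the canonical ROI scheme from the shipped registry.

    Parameters
    ----------
    mode
        ``"bilateral7"`` for hemisphere-averaged subcortical structures (the
        primary analysis) or ``"lateralized14"`` for per-hemisphere nuclei
        (the follow-up analysis).
    """
    if mode not in ("bilateral7", "lateralized14"):
        raise SchemaError(f"unknown scheme mode {mode!r}")
    reg = _load_registry()
    rois: list[ROI] = []
    for entry in reg["subcortical"]:
        if mode == "bilateral7":
            rois.append(ROI(entry["name"], "subcortical", "bilateral"))
        else:
            for hemi in ("left", "right"):
                rois.append(ROI(f"{entry['name']}_{hemi}", "subcortical", hemi))
    for hemi in ("left", "right"):
        for entry in reg["cortical"]:
            rois.append(ROI(f"{entry['name']}_{hemi}", "cortical", hemi, entry["lobe"]))
    return ROIScheme(tuple(rois), mode)


def freesurfer_label_map() -> dict[str, str]:
    """Map canonical lateralized ROI names to FreeSurfer stats labels.

    Subcortical entries map e.g. ``thalamus_left`` -> ``Left-Thalamus-Proper``
    (aseg.stats); cortical entries map e.g. ``entorhinal_left`` ->
    ``entorhinal`` (the StructName inside lh.aparc.stats).
    """
    reg = _load_registry()
    out: dict[str, str] = {}
    for entry in reg["subcortical"]:
        out[f"{entry['name']}_left"] = f"Left-{entry['freesurfer']}"
        out[f"{entry['name']}_right"] = f"Right-{entry['freesurfer']}"
    for entry in reg["cortical"]:
        for hemi in ("left", "right"):
            out[f"{entry['name']}_{hemi}"] = entry["freesurfer"]
    return out


def intra_subcortical_pairs(scheme: ROIScheme) -> list[tuple[str, str]]:
    """All unordered subcortical region pairs (21 for bilateral7, 91 for lateralized14)."""
    return list(itertools.combinations(scheme.subcortical_names, 2))


def subcortico_cortical_pairs(scheme: ROIScheme) -> list[tuple[str, str]]:
    """All subcortical x cortical pairs (476 for bilateral7, 952 for lateralized14)."""
    return [
        (s, c)
        for s in scheme.subcortical_names
        for c in scheme.cortical_names
    ]


def cortico_cortical_pairs(scheme: ROIScheme) -> list[tuple[str, str]]:
    """All unordered cortical region pairs (C(68, 2) = 2278)."""
    return list(itertools.combinations(scheme.cortical_names, 2))


def family_pairs(scheme: ROIScheme, family: str) -> list[tuple[str, str]]:
    """Region pairs for a pairwise family name."""
    if family == "intra_subcortical":
        return intra_subcortical_pairs(scheme)
    if family == "subcortico_cortical":
        return subcortico_cortical_pairs(scheme)
    if family == "cortico_cortical":
        return cortico_cortical_pairs(scheme)
    raise SchemaError(f"{family!r} is not a pairwise family")
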