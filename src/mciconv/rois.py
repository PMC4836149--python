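"""Desikan–Killiany cortical parcellation: ROI names and canonical ordering.

The FreeSurfer ``aparc`` atlas parcellates each hemisphere into 34 cortical
regions.  Every feature produced by this package is indexed by one of the 68
resulting ROIs, written ``{ABBR}_{HEMI}`` (e.g. ``IPC_L`` for the left
inferior parietal cortex).  The canonical ordering — the 34 abbreviations in
a fixed reading order, left-hemisphere block before right — gives every
downstream matrix a deterministic column index.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ROI_ABBREVIATIONS",
    "ROI_FULL_NAMES",
    "HEMISPHERES",
    "ALL_ROI_NAMES",
    "N_ROIS_PER_HEMISPHERE",
    "N_ROIS",
    "ROIName",
]

#: Full anatomical name for each abbreviation.
ROI_FULL_NAMES: dict[str, str] = {
    "BSTS": "Banks superior temporal sulcus",
    "cACC": "Caudal anterior cingulate cortex",
    "cMFG": "Caudal middle frontal gyrus",
    "CUN": "Cuneus cortex",
    "ENT": "Entorhinal cortex",
    "FG": "Fusiform gyrus",
    "IPC": "Inferior parietal cortex",
    "ITG": "Inferior temporal gyrus",
    "IstCC": "Isthmus of cingulate cortex",
    "LOC": "Lateral occipital cortex",
    "ORBlat": "Lateral orbital frontal cortex",
    "LING": "Lingual gyrus",
    "ORBmid": "Medial orbital frontal cortex",
    "MTG": "Middle temporal gyrus",
    "PHG": "Parahippocampal gyrus",
    "PCL": "Paracentral lobule",
    "POperc": "Pars Opercularis",
    "PORB": "Pars Orbitalis",
    "PTri": "Pars Triangularis",
    "PCAL": "Pericalcarine cortex",
    "PoCG": "Postcentral gyrus",
    "PCC": "Posterior cingulate cortex",
    "PreCG": "Precentral gyrus",
    "PCUN": "Precuneus cortex",
    "rACC": "Rostral anterior cingulate cortex",
    "rMFG": "Rostral middle frontal gyrus",
    "SFG": "Superior frontal gyrus",
    "SPC": "Superior parietal cortex",
    "STG": "Superior temporal gyrus",
    "SMG": "Supramarginal gyrus",
    "FP": "Frontal pole",
    "TP": "Temporal pole",
    "TTC": "Transverse temporal cortex",
    "INS": "Insula",
}

#: The 34 per-hemisphere abbreviations in canonical order.
ROI_ABBREVIATIONS: tuple[str, ...] = tuple(ROI_FULL_NAMES)

HEMISPHERES: tuple[str, str] = ("L", "R")

N_ROIS_PER_HEMISPHERE: int = len(ROI_ABBREVIATIONS)
N_ROIS: int = N_ROIS_PER_HEMISPHERE * len(HEMISPHERES)

#: All 68 ROI name strings, left block then right block.
ALL_ROI_NAMES: tuple[str, ...] = tuple(
    f"{abbr}_{hemi}" for hemi in HEMISPHERES for abbr in ROI_ABBREVIATIONS
)

_ROI_INDEX: dict[str, int] = {name: i for i, name in enumerate(ALL_ROI_NAMES)}


@dataclass(frozen=True, order=True)
class ROIName:
    """A single cortical ROI: Desikan–Killiany abbreviation plus hemisphere."""

    region: str
    hemisphere: str

    def __post_init__(self) -> None:
        if self.region not in ROI_FULL_NAMES:
            raise ValueError(
                f"unknown ROI abbreviation {self.region!r}; expected one of "
                f"the {N_ROIS_PER_HEMISPHERE} Desikan-Killiany abbreviations"
            )
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(
                f"hemisphere must be 'L' or 'R', got {self.hemisphere!r}"
            )

    @classmethod
    def parse(cls, name: str) -> "ROIName":
        """Parse ``'IPC_L'`` style strings."""
        region, _, hemi = name.rpartition("_")
        if not region:
            raise ValueError(f"malformed ROI name {name!r}; expected 'ABBR_HEMI'")
        return cls(region, hemi)

    @property
    def full_name(self) -> str:
        return ROI_FULL_NAMES[self.region]

    @property
    def index(self) -> int:
        """Position of this ROI in the canonical 68-name ordering."""
        return _ROI_INDEX[str(self)]

    def __str__(self) -> str:
        return f"{self.region}_{self.hemisphere}"


def roi_index(name: str) -> int:
    """Canonical column index of an ROI name string; raises on unknown names."""
    try:
        return _ROI_INDEX[name]
    except KeyError:
        ROIName.parse(name)  # produce the specific error
        raise
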