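"""Lead order, anatomy map and diagnostic class definitions for the 12-lead system.

The conventional clinical lead order is used everywhere: three standard limb
leads (I, II, III), three augmented limb leads (aVR, aVL, aVF), then the six
precordial leads (V1..V6).  Genomes, feature banks and excitation reports all
index leads in this order.
"""

from __future__ import annotations

LEAD_NAMES: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

LEAD_INDEX: dict[str, int] = {name: i for i, name in enumerate(LEAD_NAMES)}

#: Anatomical aspect of the heart seen by each lead group.
ANATOMY: dict[str, tuple[str, ...]] = {
    "Anterior": ("V3", "V4"),
    "Septal": ("V1", "V2"),
    "Lateral": ("I", "aVL", "V5", "V6"),
    "Inferior": ("II", "III", "aVF"),
    "Endocardial": ("aVR",),
}

#: Full class set: healthy control plus the six location-based MI subcategories.
CLASS_ORDER: tuple[str, ...] = ("HC", "AMI", "ASMI", "ALMI", "IMI", "ILMI", "OMI")

#: Classes used for the 6-way localization task (OMI is a catch-all and excluded).
LOCALIZATION_CLASSES: tuple[str, ...] = ("HC", "AMI", "ASMI", "ALMI", "IMI", "ILMI")

#: Leads that carry each MI subcategory's signature, as unions of anatomical
#: aspects: anterior (AMI), antero-septal (ASMI), antero-lateral (ALMI),
#: inferior (IMI), infero-lateral (ILMI).  OMI is a per-seed random 2-lead
#: subset and HC is clean, so neither appears here.
CLASS_LEADS: dict[str, tuple[str, ...]] = {
    "HC": (),
    "AMI": ANATOMY["Anterior"],
    "ASMI": ANATOMY["Anterior"] + ANATOMY["Septal"],
    "ALMI": ANATOMY["Anterior"] + ANATOMY["Lateral"],
    "IMI": ANATOMY["Inferior"],
    "ILMI": ANATOMY["Inferior"] + ANATOMY["Lateral"],
}


def lead_indices(names) -> list[int]:
    """Map lead names to their positions in the conventional order."""
    return [LEAD_INDEX[n] for n in names]
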