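"""The ten-class tissue label schema used for OCT segmentation masks.

Every pixel of a segmentation frame carries exactly one of these codes.
Only a subset (lumen, intima, lipid) drives plaque quantification; the
remaining classes are carried through so that externally produced masks
with the full schema round-trip unchanged.
"""

from __future__ import annotations

BACKGROUND = 0
GUIDEWIRE = 1
LUMEN = 2
INTIMA = 3
MEDIA = 4
LIPID = 5
CALCIUM = 6
SIDE_BRANCH = 7
PLAQUE_RUPTURE = 8
THROMBUS = 9

N_CLASSES = 10

CLASS_NAMES = {
    BACKGROUND: "background",
    GUIDEWIRE: "guidewire",
    LUMEN: "lumen",
    INTIMA: "intima",
    MEDIA: "media",
    LIPID: "lipid",
    CALCIUM: "calcium",
    SIDE_BRANCH: "side_branch",
    PLAQUE_RUPTURE: "plaque_rupture",
    THROMBUS: "thrombus",
}
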