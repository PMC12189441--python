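"""Fixed categorical vocabularies for the mass-lesion tabular schema.

The manifest schema mirrors the public CBIS-DDSM mass subset: ordinal
breast density (1-4), laterality, view, abnormality id, a 20-category mass
shape vocabulary, a 19-category mass margins vocabulary, BI-RADS 0-5,
subtlety 1-5 and a three-way pathology label. The *sizes* of the shape and
margin vocabularies are load-bearing (they fix the 44-column encoded
feature layout); the names are conventional composites of the base
radiological descriptors.
"""

from __future__ import annotations

MISSING = "MISSING"
UNKNOWN = "UNKNOWN"

LATERALITIES = ("LEFT", "RIGHT")
VIEWS = ("CC", "MLO")
PATHOLOGIES = ("BENIGN", "BENIGN_WITHOUT_CALLBACK", "MALIGNANT")

# 20 mass-shape categories: 8 base descriptors plus 12 composites.
MASS_SHAPES = (
    "ARCHITECTURAL_DISTORTION",
    "ASYMMETRIC_BREAST_TISSUE",
    "ASYMMETRIC_BREAST_TISSUE-FOCAL_ASYMMETRIC_DENSITY",
    "FOCAL_ASYMMETRIC_DENSITY",
    "IRREGULAR",
    "IRREGULAR-ARCHITECTURAL_DISTORTION",
    "IRREGULAR-FOCAL_ASYMMETRIC_DENSITY",
    "LOBULATED",
    "LOBULATED-ARCHITECTURAL_DISTORTION",
    "LOBULATED-IRREGULAR",
    "LOBULATED-LYMPH_NODE",
    "LOBULATED-OVAL",
    "LYMPH_NODE",
    "OVAL",
    "OVAL-LOBULATED",
    "OVAL-LYMPH_NODE",
    "ROUND",
    "ROUND-IRREGULAR-ARCHITECTURAL_DISTORTION",
    "ROUND-LOBULATED",
    "ROUND-OVAL",
)

# 19 mass-margin categories: 5 base descriptors plus 14 composites.
MASS_MARGINS = (
    "CIRCUMSCRIBED",
    "CIRCUMSCRIBED-ILL_DEFINED",
    "CIRCUMSCRIBED-MICROLOBULATED",
    "CIRCUMSCRIBED-MICROLOBULATED-ILL_DEFINED",
    "CIRCUMSCRIBED-OBSCURED",
    "CIRCUMSCRIBED-OBSCURED-ILL_DEFINED",
    "CIRCUMSCRIBED-SPICULATED",
    "ILL_DEFINED",
    "ILL_DEFINED-SPICULATED",
    "MICROLOBULATED",
    "MICROLOBULATED-ILL_DEFINED",
    "MICROLOBULATED-ILL_DEFINED-SPICULATED",
    "MICROLOBULATED-SPICULATED",
    "OBSCURED",
    "OBSCURED-CIRCUMSCRIBED-ILL_DEFINED",
    "OBSCURED-ILL_DEFINED",
    "OBSCURED-ILL_DEFINED-SPICULATED",
    "OBSCURED-SPICULATED",
    "SPICULATED",
)

assert len(MASS_SHAPES) == 20
assert len(MASS_MARGINS) == 19

MANIFEST_COLUMNS = (
    "breast_density",
    "laterality",
    "view",
    "abnormality_id",
    "mass_shape",
    "mass_margins",
    "birads",
    "subtlety",
    "pathology",
    "image_path",
    "label",
)
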