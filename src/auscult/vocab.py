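"""Class vocabulary and dataset bookkeeping constants.

The fixed 11-class vocabulary covers six respiratory conditions (bronchiectasis BA,
bronchiolitis BO, chronic obstructive pulmonary disease COPD, healthy H, pneumonia P,
upper respiratory tract infection URTI) and five cardiac ones (aortic stenosis AS,
mitral regurgitation MR, mitral stenosis MS, mitral valve prolapse MVP, normal N).

``CLASSES`` fixes both the confusion-matrix ordering and the deterministic tie-break
order used by the forest's plurality vote.
"""

CLASSES = ("BA", "BO", "COPD", "H", "P", "URTI", "AS", "MR", "MS", "MVP", "N")

LUNG_CLASSES = ("BA", "BO", "COPD", "H", "P", "URTI")
HEART_CLASSES = ("AS", "MR", "MS", "MVP", "N")

CLASS_INDEX = {c: i for i, c in enumerate(CLASSES)}

#: Per-class record counts of the combined public corpora before augmentation.
ORIGINAL_COUNTS = {
    "AS": 200, "MS": 200, "MVP": 200, "MR": 200, "N": 200,
    "COPD": 793, "P": 37, "H": 35, "URTI": 23, "BA": 16, "BO": 13,
}

#: Per-class targets after VAE class balancing (the default augmentation plan).
BALANCED_COUNTS = {
    "AS": 800, "MS": 800, "MVP": 800, "MR": 800, "N": 800,
    "COPD": 793, "P": 667, "H": 665, "URTI": 653, "BA": 646, "BO": 643,
}


def require_known(label: str) -> str:
    if label not in CLASS_INDEX:
        raise ValueError(f"unknown class label {label!r}; expected one of {CLASSES}")
    return label
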