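"""Synthetic ICD-10-style comorbidity phrase dictionary.

A small fixed catalogue of disease descriptions in the style of ICD-10
code titles.  The phrases are synthetic stand-ins written for this
package; they are not a copy of the ICD-10 catalogue.  ``RISK_PHRASES``
is the designated subset whose sampling odds are multiplied for sepsis
patients, so the generated EMR text carries a learnable (weak) signal.
"""

RISK_PHRASES: tuple[str, ...] = (
    "type 2 diabetes mellitus without complications",
    "chronic kidney disease stage 3",
    "congestive heart failure unspecified",
    "chronic obstructive pulmonary disease with acute exacerbation",
    "immunodeficiency unspecified",
    "malignant neoplasm of bronchus and lung",
    "pressure ulcer of sacral region stage 2",
    "urinary tract infection site not specified",
)

BACKGROUND_PHRASES: tuple[str, ...] = (
    "essential primary hypertension",
    "hyperlipidemia unspecified",
    "gastro esophageal reflux disease without esophagitis",
    "anxiety disorder unspecified",
    "major depressive disorder single episode",
    "osteoarthritis of knee unspecified",
    "low back pain",
    "migraine without aura not intractable",
    "asthma uncomplicated",
    "hypothyroidism unspecified",
    "atrial fibrillation unspecified",
    "obstructive sleep apnea adult",
    "iron deficiency anemia unspecified",
    "vitamin d deficiency unspecified",
    "benign prostatic hyperplasia without lower urinary tract symptoms",
    "glaucoma unspecified",
)

ALL_PHRASES: tuple[str, ...] = RISK_PHRASES + BACKGROUND_PHRASES
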