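"""Medication and diagnosis-code vocabularies used by the filter algorithms.

The drug-name table maps common generic and brand names to the drug classes
the screening rules read.  It is deliberately small: the algorithms only need
to distinguish insulin, metformin, the seven "T2D-specific" classes, and
systemic steroids; unknown names map to class ``other`` with a warning rather
than an error, so real-world extracts with exotic names still flow through.
"""

from __future__ import annotations

import logging

from .ehr_model import DrugClass

logger = logging.getLogger(__name__)

#: Classes whose use is considered specific to type 2 diabetes treatment.
#: Metformin and insulin are intentionally absent: metformin is used in
#: prediabetes and PCOS, insulin in any diabetes type.
T2D_SPECIFIC_CLASSES = frozenset({
    DrugClass.sulfonylurea, DrugClass.meglitinide, DrugClass.TZD,
    DrugClass.DPP4i, DrugClass.AGI, DrugClass.GLP1RA, DrugClass.SGLT2i,
})

#: All glucose-lowering classes (used when counting non-insulin diabetes
#: medications during chart summarisation).
DIABETES_MED_CLASSES = T2D_SPECIFIC_CLASSES | {DrugClass.metformin, DrugClass.insulin}

DRUG_NAME_TO_CLASS: dict[str, DrugClass] = {
    # insulins
    "insulin": DrugClass.insulin,
    "insulin glargine": DrugClass.insulin,
    "insulin detemir": DrugClass.insulin,
    "insulin degludec": DrugClass.insulin,
    "insulin lispro": DrugClass.insulin,
    "insulin aspart": DrugClass.insulin,
    "insulin nph": DrugClass.insulin,
    "insulin regular": DrugClass.insulin,
    "lantus": DrugClass.insulin,
    "levemir": DrugClass.insulin,
    "humalog": DrugClass.insulin,
    "novolog": DrugClass.insulin,
    "basal insulin": DrugClass.insulin,
    # biguanide
    "metformin": DrugClass.metformin,
    "glucophage": DrugClass.metformin,
    # sulfonylureas
    "glipizide": DrugClass.sulfonylurea,
    "glyburide": DrugClass.sulfonylurea,
    "glimepiride": DrugClass.sulfonylurea,
    # meglitinides
    "repaglinide": DrugClass.meglitinide,
    "nateglinide": DrugClass.meglitinide,
    # thiazolidinediones
    "pioglitazone": DrugClass.TZD,
    "rosiglitazone": DrugClass.TZD,
    # DPP-4 inhibitors
    "sitagliptin": DrugClass.DPP4i,
    "saxagliptin": DrugClass.DPP4i,
    "linagliptin": DrugClass.DPP4i,
    "alogliptin": DrugClass.DPP4i,
    # alpha-glucosidase inhibitors
    "acarbose": DrugClass.AGI,
    "miglitol": DrugClass.AGI,
    # GLP-1 receptor agonists
    "liraglutide": DrugClass.GLP1RA,
    "semaglutide": DrugClass.GLP1RA,
    "dulaglutide": DrugClass.GLP1RA,
    "exenatide": DrugClass.GLP1RA,
    # SGLT2 inhibitors
    "empagliflozin": DrugClass.SGLT2i,
    "canagliflozin": DrugClass.SGLT2i,
    "dapagliflozin": DrugClass.SGLT2i,
    # systemic steroids
    "prednisone": DrugClass.systemic_steroid,
    "prednisolone": DrugClass.systemic_steroid,
    "dexamethasone": DrugClass.systemic_steroid,
    "hydrocortisone": DrugClass.systemic_steroid,
    "methylprednisolone": DrugClass.systemic_steroid,
}


def classify_drug(drug_name: str) -> DrugClass:
    """Resolve a drug name to its class; unknown names map to ``other``."""
    cls = DRUG_NAME_TO_CLASS.get(drug_name.strip().lower())
    if cls is None:
        logger.warning("unknown drug name %r mapped to class 'other'", drug_name)
        return DrugClass.other
    return cls


#: Cystic fibrosis diagnosis-code prefixes: ICD-9 277.0x and ICD-10 E84.*.
CF_CODE_PREFIXES = ("277.0", "E84")


def is_cf_code(code: str, prefixes: tuple[str, ...] = CF_CODE_PREFIXES) -> bool:
    return code.strip().upper().startswith(tuple(p.upper() for p in prefixes))
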