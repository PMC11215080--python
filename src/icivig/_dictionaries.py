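"""Bundled vocabularies: ICI drug synonyms, indication-organ keywords, TCGA map.

These are editable data tables, kept in source so they are versioned with the
package. Matching is case-insensitive; callers normalise before lookup.
"""

from __future__ import annotations

# Generic agent -> ICI class.
AGENT_CLASS: dict[str, str] = {
    "nivolumab": "ANTI_PD1",
    "pembrolizumab": "ANTI_PD1",
    "cemiplimab": "ANTI_PD1",
    "atezolizumab": "ANTI_PDL1",
    "avelumab": "ANTI_PDL1",
    "durvalumab": "ANTI_PDL1",
    "ipilimumab": "ANTI_CTLA4",
    "tremelimumab": "ANTI_CTLA4",
}

# Fixed display/iteration order for agents (class-major).
AGENT_ORDER: tuple[str, ...] = (
    "nivolumab",
    "pembrolizumab",
    "cemiplimab",
    "atezolizumab",
    "avelumab",
    "durvalumab",
    "ipilimumab",
    "tremelimumab",
)

# Synonym (normalised lowercase) -> generic agent. Brand names from the public
# US labels of the eight agents; a few common verbatim-name variants included.
DRUG_SYNONYMS: dict[str, str] = {
    "nivolumab": "nivolumab",
    "opdivo": "nivolumab",
    "pembrolizumab": "pembrolizumab",
    "keytruda": "pembrolizumab",
    "cemiplimab": "cemiplimab",
    "cemiplimab rwlc": "cemiplimab",
    "libtayo": "cemiplimab",
    "atezolizumab": "atezolizumab",
    "tecentriq": "atezolizumab",
    "avelumab": "avelumab",
    "bavencio": "avelumab",
    "durvalumab": "durvalumab",
    "imfinzi": "durvalumab",
    "ipilimumab": "ipilimumab",
    "yervoy": "ipilimumab",
    "tremelimumab": "tremelimumab",
    "tremelimumab actl": "tremelimumab",
    "imjudo": "tremelimumab",
}

# Indication-organ categories (display order mirrors the characteristics table).
ORGAN_CATEGORIES: tuple[str, ...] = (
    "Lung",
    "Skin",
    "Bladder",
    "Kidney",
    "Stomach",
    "Lymphoid",
    "Pleura",
    "Head and neck",
    "Hematologic",
    "Liver",
    "Uterus",
    "Brain",
    "Esophagus",
    "Breast",
    "Ovary",
    "Large intestine",
    "Oropharynx",
    "Prostate",
    "Unspecified",
    "Missing",
)

# Ordered keyword -> organ map. First hit wins, so the more specific keywords
# (oropharynx before the generic head-and-neck terms) come first.
ORGAN_KEYWORDS: tuple[tuple[str, str], ...] = (
    ("oropharyn", "Oropharynx"),
    ("lung", "Lung"),
    ("bronch", "Lung"),
    ("nsclc", "Lung"),
    ("melanoma", "Skin"),
    ("skin", "Skin"),
    ("merkel", "Skin"),
    ("cutaneous", "Skin"),
    ("bladder", "Bladder"),
    ("urothelial", "Bladder"),
    ("urinary tract", "Bladder"),
    ("renal", "Kidney"),
    ("kidney", "Kidney"),
    ("gastric", "Stomach"),
    ("stomach", "Stomach"),
    ("gastro-oesophageal", "Stomach"),
    ("gastroesophageal", "Stomach"),
    ("lymphoma", "Lymphoid"),
    ("lymphoid", "Lymphoid"),
    ("mesothelioma", "Pleura"),
    ("pleura", "Pleura"),
    ("head and neck", "Head and neck"),
    ("laryn", "Head and neck"),
    ("nasopharyn", "Head and neck"),
    ("hypopharyn", "Head and neck"),
    ("leukaemia", "Hematologic"),
    ("leukemia", "Hematologic"),
    ("myeloma", "Hematologic"),
    ("myelodysplastic", "Hematologic"),
    ("hepat", "Liver"),
    ("liver", "Liver"),
    ("endometri", "Uterus"),
    ("uter", "Uterus"),
    ("cervi", "Uterus"),
    ("glio", "Brain"),
    ("brain", "Brain"),
    ("astrocytoma", "Brain"),
    ("oesophag", "Esophagus"),
    ("esophag", "Esophagus"),
    ("breast", "Breast"),
    ("ovar", "Ovary"),
    ("fallopian", "Ovary"),
    ("colorect", "Large intestine"),
    ("colon", "Large intestine"),
    ("rect", "Large intestine"),
    ("large intestine", "Large intestine"),
    ("caecum", "Large intestine"),
    ("prostat", "Prostate"),
)

# Indication organ -> study-cohort abbreviation used for the pan-cancer stage.
# Lung is reported as a single combined label because FAERS indications do not
# carry the histology needed to split adeno from squamous disease.
ORGAN_TO_CANCER_TYPE: dict[str, str] = {
    "Skin": "SKCM",
    "Lung": "LUNG",
    "Bladder": "BLCA",
    "Kidney": "KIRC",
    "Stomach": "STAD",
    "Lymphoid": "DLBC",
    "Pleura": "MESO",
    "Head and neck": "HNSC",
    "Oropharynx": "HNSC",
    "Hematologic": "LAML",
    "Liver": "LIHC",
    "Uterus": "UCEC",
    "Brain": "LGG",
    "Esophagus": "ESCA",
    "Breast": "BRCA",
    "Ovary": "OV",
    "Large intestine": "COAD",
    "Prostate": "PRAD",
}
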