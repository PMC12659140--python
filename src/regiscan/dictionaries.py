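"""Bundled toy code dictionaries.

The full Swedish ICD-10 and ATC dictionaries are licensed and are not
shipped; users point :func:`regiscan.trees.read_dictionary` at their own
extracts.  The toy dictionaries below carry a representative slice of
each hierarchy — enough chapters, blocks, categories and subcategories
to exercise masking, chapter exclusion and scanning end to end — and are
the default trees of the synthetic-registry pipeline.

Block and chapter codes use en-dash ranges (e.g. ``H65–H75``), matching
the convention of Swedish register extracts.
"""

from __future__ import annotations

import pandas as pd

from .trees import ClassificationSystem, ClassificationTree, build_tree

__all__ = ["toy_icd10_dictionary", "toy_atc_dictionary", "load_toy_tree"]

_ICD_ROWS: list[tuple[str, str, str, str]] = [
    # code, parent, label, level
    ("ICD10", "", "ICD-10 root", "root"),
    # chapter I — infections
    ("A00–B99", "ICD10", "Certain infectious and parasitic diseases", "chapter"),
    ("A00–A09", "A00–B99", "Intestinal infectious diseases", "block"),
    ("A04", "A00–A09", "Other bacterial intestinal infections", "category"),
    ("A08", "A00–A09", "Viral intestinal infections", "category"),
    ("B25–B34", "A00–B99", "Other viral diseases", "block"),
    ("B25", "B25–B34", "Cytomegaloviral disease", "category"),
    ("B27", "B25–B34", "Infectious mononucleosis", "category"),
    ("B34", "B25–B34", "Viral infection of unspecified site", "category"),
    # chapter III — blood
    ("D50–D89", "ICD10", "Diseases of the blood and blood-forming organs", "chapter"),
    ("D55–D59", "D50–D89", "Haemolytic anaemias", "block"),
    ("D56", "D55–D59", "Thalassaemia", "category"),
    ("D59", "D55–D59", "Acquired haemolytic anaemia", "category"),
    ("D70–D77", "D50–D89", "Other diseases of blood", "block"),
    ("D72", "D70–D77", "Other disorders of white blood cells", "category"),
    # chapter VI — nervous system
    ("G00–G99", "ICD10", "Diseases of the nervous system", "chapter"),
    ("G00–G09", "G00–G99", "Inflammatory diseases of the central nervous system", "block"),
    ("G00", "G00–G09", "Bacterial meningitis", "category"),
    ("G04", "G00–G09", "Encephalitis, myelitis and encephalomyelitis", "category"),
    ("G40–G47", "G00–G99", "Episodic and paroxysmal disorders", "block"),
    ("G40", "G40–G47", "Epilepsy", "category"),
    # chapter VII — eye (chapter-level in register extracts)
    ("H00–H59", "ICD10", "Diseases of the eye and adnexa", "chapter"),
    # chapter VIII — ear
    ("H60–H95", "ICD10", "Diseases of the ear and mastoid process", "chapter"),
    ("H65–H75", "H60–H95", "Diseases of middle ear and mastoid", "block"),
    ("H65", "H65–H75", "Nonsuppurative otitis media", "category"),
    ("H66", "H65–H75", "Suppurative and unspecified otitis media", "category"),
    ("H660", "H66", "Acute suppurative otitis media", "subcategory"),
    ("H669", "H66", "Otitis media, unspecified", "subcategory"),
    ("H90–H95", "H60–H95", "Other disorders of ear", "block"),
    ("H90", "H90–H95", "Conductive and sensorineural hearing loss", "category"),
    # chapter X — respiratory
    ("J00–J99", "ICD10", "Diseases of the respiratory system", "chapter"),
    ("J00–J06", "J00–J99", "Acute upper respiratory infections", "block"),
    ("J03", "J00–J06", "Acute tonsillitis", "category"),
    ("J06", "J00–J06", "Acute upper respiratory infection", "category"),
    ("J069", "J06", "Acute upper respiratory infection, unspecified", "subcategory"),
    ("J20–J22", "J00–J99", "Other acute lower respiratory infections", "block"),
    ("J21", "J20–J22", "Acute bronchiolitis", "category"),
    # chapter XIII — musculoskeletal
    ("M00–M99", "ICD10", "Diseases of the musculoskeletal system", "chapter"),
    ("M40–M54", "M00–M99", "Dorsopathies", "block"),
    ("M43", "M40–M54", "Other deforming dorsopathies", "category"),
    ("M54", "M40–M54", "Dorsalgia", "category"),
    # chapter XVI — perinatal (chapter-level in register extracts)
    ("P00–P96", "ICD10", "Certain conditions originating in the perinatal period", "chapter"),
    # chapter XVII — congenital (block-level in register extracts)
    ("Q00–Q99", "ICD10", "Congenital malformations and chromosomal abnormalities", "chapter"),
    ("Q00–Q07", "Q00–Q99", "Congenital malformations of the nervous system", "block"),
    ("Q20–Q28", "Q00–Q99", "Congenital malformations of the circulatory system", "block"),
    # chapter XVIII — symptoms and signs
    ("R00–R99", "ICD10", "Symptoms, signs and abnormal findings", "chapter"),
    ("R50–R69", "R00–R99", "General symptoms and signs", "block"),
    ("R56", "R50–R69", "Convulsions, not elsewhere classified", "category"),
    ("R62", "R50–R69", "Lack of expected normal physiological development", "category"),
    ("R620", "R62", "Delayed milestone", "subcategory"),
    # excluded chapters (kept so exclusion is exercised against real nodes)
    ("S00–T98", "ICD10", "Injury, poisoning and consequences of external causes", "chapter"),
    ("S00–S09", "S00–T98", "Injuries to the head", "block"),
    ("S06", "S00–S09", "Intracranial injury", "category"),
    ("Z00–Z99", "ICD10", "Factors influencing health status", "chapter"),
    ("Z00–Z13", "Z00–Z99", "Persons encountering health services for examination", "block"),
    ("Z00", "Z00–Z13", "General examination of persons without complaint", "category"),
]

_ATC_ROWS: list[tuple[str, str, str, str]] = [
    ("ATC", "", "ATC root", "root"),
    ("A", "ATC", "Alimentary tract and metabolism", "level1"),
    ("A11", "A", "Vitamins", "level2"),
    ("A11C", "A11", "Vitamin A and D", "level3"),
    ("A11CC", "A11C", "Vitamin D and analogues", "level4"),
    ("B", "ATC", "Blood and blood forming organs", "level1"),
    ("B03", "B", "Antianemic preparations", "level2"),
    ("B03B", "B03", "Vitamin B12 and folic acid", "level3"),
    ("B03BB", "B03B", "Folic acid and derivatives", "level4"),
    ("D", "ATC", "Dermatologicals", "level1"),
    ("D04", "D", "Antipruritics", "level2"),
    ("J", "ATC", "Antiinfectives for systemic use", "level1"),
    ("J01", "J", "Antibacterials for systemic use", "level2"),
    ("J01C", "J01", "Beta-lactam antibacterials, penicillins", "level3"),
    ("J01CA", "J01C", "Penicillins with extended spectrum", "level4"),
    ("J01CA04", "J01CA", "Amoxicillin", "level5"),
    ("J01D", "J01", "Other beta-lactam antibacterials", "level3"),
    ("J01DD", "J01D", "Third-generation cephalosporins", "level4"),
    ("J01DD14", "J01DD", "Ceftibuten", "level5"),
    ("J01E", "J01", "Sulfonamides and trimethoprim", "level3"),
    ("J01EA", "J01E", "Trimethoprim and derivatives", "level4"),
    ("J01EA01", "J01EA", "Trimethoprim", "level5"),
    ("J07", "J", "Vaccines", "level2"),
    ("J07B", "J07", "Viral vaccines", "level3"),
    ("J07BC", "J07B", "Hepatitis vaccines", "level4"),
    ("J07BC20", "J07BC", "Combinations, hepatitis vaccines", "level5"),
    ("N", "ATC", "Nervous system", "level1"),
    ("N02", "N", "Analgesics", "level2"),
    ("N02B", "N02", "Other analgesics and antipyretics", "level3"),
    ("N02BE", "N02B", "Anilides", "level4"),
    ("R", "ATC", "Respiratory system", "level1"),
    ("R03", "R", "Drugs for obstructive airway diseases", "level2"),
    ("R05", "R", "Cough and cold preparations", "level2"),
]


def _frame(rows: list[tuple[str, str, str, str]]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["code", "parent", "label", "level"])


def toy_icd10_dictionary() -> pd.DataFrame:
    """A ~55-node slice of the ICD-10 hierarchy as a dictionary table."""
    return _frame(_ICD_ROWS)


def toy_atc_dictionary() -> pd.DataFrame:
    """A ~34-node slice of the ATC hierarchy as a dictionary table."""
    return _frame(_ATC_ROWS)


def load_toy_tree(system: ClassificationSystem) -> ClassificationTree:
    system = ClassificationSystem(system)
    table = (
        toy_icd10_dictionary()
        if system is ClassificationSystem.ICD10
        else toy_atc_dictionary()
    )
    return build_tree(table, system)
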