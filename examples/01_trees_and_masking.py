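"""Build the bundled classification trees, apply the registry masking
rules and enumerate scan cuts.

Every non-root node of the ICD-10/ATC hierarchy is a candidate cluster
("cut") for the tree scan.  Registry extracts deliver some chapters only
at coarse granularity, so raw codes are first masked onto the level the
extract actually carries.
"""

import regiscan as rs
from regiscan.trees import ClassificationSystem

icd = rs.load_toy_tree("ICD10")
atc = rs.load_toy_tree("ATC")
print(f"toy ICD-10 tree: {len(icd)} nodes, {len(rs.enumerate_cuts(icd))} cuts")
print(f"toy ATC tree:    {len(atc)} nodes, {len(rs.enumerate_cuts(atc))} cuts")

rules = rs.default_icd10_mask_rules()
for raw in ("H66.9", "H00.1", "Q03.1", "B34"):
    masked = rs.apply_mask(raw, ClassificationSystem.ICD10, rules, icd)
    print(f"  ICD {raw:6s} -> {masked}")
# H66.9 lands on the 3-character category H66 (ear chapter is category-
# masked), H00.1 on the whole eye chapter, Q03.1 on its congenital block,
# and B34 passes through untouched.

atc_rules = rs.default_atc_mask_rules()
for raw in ("J01DD14", "N02BE01", "R05CB01"):
    print(f"  ATC {raw:8s} -> "
          f"{rs.apply_mask(raw, ClassificationSystem.ATC, atc_rules, atc)}")
# Anti-infectives (J) keep 7-character detail; N is truncated to 5
# characters; the incompletely characterised class R collapses to R05.
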