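# Header lexicon for clinical-note section segmentation.
# One rule per line: header-phrase <TAB> section_type.
# Matching is case-insensitive, anchored to line starts; the header must be
# followed by a colon or the end of its line.  Longest match wins, then order.
FAMILY HISTORY	family_history
FAM HX	family_history
IMPRESSION/REPORT/PLAN	diagnosis_impression
IMPRESSION	diagnosis_impression
DIAGNOSIS	diagnosis_impression
ASSESSMENT	diagnosis_impression
CHIEF COMPLAINT	chief_complaint
HISTORY OF PRESENT ILLNESS	hpi
HPI	hpi
ALLERGIES	allergies
SOCIAL HISTORY	social_history
MEDICATIONS	medications
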