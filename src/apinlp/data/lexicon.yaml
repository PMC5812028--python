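# Concept lexicon and assertion trigger lists for the API pipeline.
# Everything here is editable: patterns are literal phrases matched
# whole-word and case-insensitively inside allowed sections.
concepts:
  WHEEZE:
    patterns: [wheeze, wheezes, wheezing, wheezy, expiratory wheeze, expiratory wheezes]
    sections: null          # null = any section
  COLD:
    patterns: [cold, colds, common cold, head cold, URI, upper respiratory infection, nasopharyngitis]
    sections: null
  ECZEMA:
    patterns: [eczema, atopic dermatitis]
    sections: null
  ALLERGIC_RHINITIS:
    patterns: [allergic rhinitis, hay fever, seasonal allergies]
    sections: null
  ASTHMA:
    patterns: [asthma, asthmatic, reactive airway disease, RAD]
    sections: null

negation_triggers:
  - "no"
  - "not"
  - "without"
  - denies
  - denied
  - "no evidence of"
  - "no history of"
  - negative for
  - never had
  - free of
  - resolved without

hypothetical_triggers:
  - "if"
  - should
  - risk of
  - risk for
  - at risk
  - rule out
  - r/o
  - concern for
  - possible
  - watch for
  - in case
  - may develop
  - return for

parent_terms:
  [mother, mom, mother's, father, dad, father's, parent, parents, parental, maternal, paternal]

other_relative_terms:
  [sibling, siblings, brother, sister, grandmother, grandfather, grandparent,
   grandma, grandpa, aunt, uncle, cousin, half-brother, half-sister]

scope_terminators: [but, however, although, though, except]

scope_window_tokens: 6
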