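# Corpus file formats

## Patient corpus (JSON Lines)

One patient object per line. Dates are ISO-8601 strings (`YYYY-MM-DD`).
Unknown top-level keys are never dropped: on read they are moved into the
`extras` map, which is preserved verbatim on write.

```json
{
  "patient_id": "P00001",
  "sex": "male",                      // male | female | unknown
  "race": "white",                    // white | nonwhite | unknown
  "gestational_age_weeks": 36.4,      // number or null
  "birth_date": "2003-04-17",
  "notes":  [{"note_id": "P00001-n000", "date": "2005-01-09", "text": "HPI: ..."}],
  "labs":   [{"date": "2005-02-01", "analyte": "eosinophil_pct", "value": 5.1, "units": "%"}],
  "ppi":    [{"date": "2004-11-20", "field": "mother_asthma", "value": "yes"}],
  "covariates": {"family_history_asthma": 1, "maternal_smoking": 0},
  "extras": {}
}
```

Constraints enforced on load:

* `patient_id` unique within the file (duplicate → error naming the line);
* malformed JSON or a missing `patient_id` → error naming the line;
* a note/lab/PPI dated before `birth_date` → warning, record kept;
* notes and labs are date-sorted after loading;
* `eosinophil_pct` values must lie in [0, 100] (reported by
  `validate_record`, not raised);
* `analyte` values other than the known ones use `"other"`; their raw
  payload can ride along in `extras`.

Character offsets reported anywhere by the package (sections, mentions)
are 0-based half-open into the raw `text` field.

## Results (JSON Lines)

One object per patient, written by `classify`:

```json
{"patient_id": "P00001", "status": "positive", "index_date": "2005-06-02",
 "majors_met": 1, "minors_met": 0,
 "criteria": [{"criterion": "FREQ_WHEEZE", "satisfied_date": "2005-06-02",
               "support": ["wheeze_episode:2005-01-09", "wheeze_episode:2005-06-02"]}, ...],
 "error": null}
```

## Gold labels (CSV)

Header `patient_id,status,index_date`; `status` is `positive`/`negative`,
`index_date` is ISO or empty (present only for positives).

## Header rules (TSV)

`pattern<TAB>section_type`, one per line, `#` comments allowed. Patterns
match case-insensitively at line starts and must be followed by a colon or
the end of the line. See `src/apinlp/data/section_headers.tsv`.

## Lexicon (YAML)

Concept surface patterns, allowed sections, and trigger lists; see
`src/apinlp/data/lexicon.yaml` for the shipped default and field names.
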