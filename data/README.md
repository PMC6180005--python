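# User-supplied reference data

The release-dependent acceptance tests look here for inputs that cannot be
bundled with the package:

* `go-2016-09-10.obo` — the archived Gene Ontology release of
  2016-09-10 (`go-basic.obo` from the GO release archive).
* `sgd_tryptophan_annotations.tsv` — annotations for the
  tryptophan-degradation pathway genes (ADH1–ADH5, SFA1, PDC1, PDC5, PDC6,
  ARO10, ARO8, ARO9) from SGD, in the simple dialect
  `gene<TAB>GO:ID;GO:ID;…<TAB>evidence` restricted to experimental evidence
  codes (EXP, IDA, IPI, IMP, IGI, IEP).

Without these files the corresponding tests in `tests/test_acceptance.py`
fail with a message pointing back to this note; all other tests are
self-contained.
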