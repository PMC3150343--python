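# Bundled data fixtures

## Signature fixtures

* `toy_signature.tsv` — a 12-probe synthetic signature (8 up-in-G3 + 4
  up-in-G1) used throughout the test suite and examples.  Its probe
  identifiers match the defaults of `rankgrade.simulate.toy_signature`.
* `original_signature_synthetic.tsv` — a **synthetic stand-in** for the
  published 128-probe grade signature: 112 up-in-G3 and 16 up-in-G1 probes
  with synthetic Affymetrix-style identifiers.  The probe identifiers are
  *not* the published ones (the published lists are distributed only inside
  supplementary material of the original studies and are not redistributed
  here); only the set structure is reproduced.
* `optimized_signature_synthetic.tsv` — a **synthetic stand-in** for the
  rebalanced 91-probe signature: the same fixture with 37 probes removed
  from the up-in-G3 set (75 + 16 probes), mirroring the published
  optimisation in structure.

Because the identifiers are synthetic, these fixtures support structural
checks (set sizes, differences, file-format round-trips) and simulated-data
workflows; they cannot be used to grade real Affymetrix profiles.  To grade
real data, supply the published probe lists in the same two-column TSV
format (`probe_id<TAB>direction`, direction `G3up`/`G1up`).

## Published agreement counts

* `published_cohort_counts.json` — the 2×3 genomic-vs-histological agreement
  counts reported for five public breast-cancer cohorts (Uppsala, Stockholm,
  Guys Hospital, Oxford, NKI).  These printed counts are used as
  worked-example inputs for the percentage and pooled-accuracy conventions
  of `rankgrade.evaluate`.
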