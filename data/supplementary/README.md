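# Published supplementary tables (not redistributed)

The acceptance tests that reproduce the published per-tissue counts
(differential proteins 252 up / 133 down in retina and 554 up / 599 down
in vitreous; 4765 and 4987 quantified proteins) read the journal's
supplementary protein-quantification datasets from this directory:

- `retina.tsv` (or `.csv`) — the retina protein report (Dataset S1 shape)
- `vitreous.tsv` (or `.csv`) — the vitreous protein report (Dataset S2 shape)

Convert the published spreadsheets to delimited text with one row per
protein. Either layout is accepted:

1. per-sample abundance columns whose headers contain `control` /
   `glaucoma` (or supply a group map via the API), plus a protein
   identifier column; or
2. precomputed `fold change` and `p-value` columns plus an identifier.

Without these files the corresponding tests fail; everything else in the
package is self-contained.
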