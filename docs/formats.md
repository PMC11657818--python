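# Input and output formats

All readers produce a `PartitionSet`: an ordered list of partitions of
one common label set, in file order, with optional per-model supports.
Readers never reorder; unknown per-model fields are preserved into
`Partition.metadata`. All files are UTF-8.

## generic-json

Either a bare list of partitions, each a list of lists of label strings:

```json
[
  [["a", "b"], ["c", "d"]],
  [["a"], ["b"], ["c", "d"]]
]
```

or an object form carrying labels, supports and metadata:

```json
{
  "partitions": [
    {"label": "m1", "subsets": [["a", "b", "c", "d"]], "support": 0.9},
    {"label": "m2", "subsets": [["a", "b"], ["c", "d"]], "support": 0.1,
     "metadata": {"note": "free-form"}}
  ]
}
```

Bare-list partitions are labeled `pt_1`, `pt_2`, … in file order.
`write_generic_json` always emits the object form.

## delineate-json

A fixture-backed subset of the ranked-results dialect emitted by
DELINEATE-style model-averaging inference. Recognized fields per model:

```json
{
  "partitions": [
    {"species_leafsets": [["a", "b"], ["c"]],
     "unconstrained_probability": 0.6},
    {"species_leafsets": [["a"], ["b"], ["c"]],
     "unconstrained_probability": 0.3}
  ]
}
```

`species_leafsets` (required) are the species blocks;
`unconstrained_probability` (or `probability`) is required and maps to
support. Any other per-model field (e.g. `constrained_probability`) is
kept in metadata. This subset is defined by this package's fixtures, not
by the upstream tool's full schema; convert richer files externally if
they deviate.

## spart-xml

A subset of the SPART-XML species-delimitation exchange format:

```xml
<spart>
  <individuals_block>
    <individuals>
      <individual id="i1"/> <individual id="i2"/> ...
    </individuals>
  </individuals_block>
  <spartitions>
    <spartition label="coarse" spartitionScore="0.7">
      <subsets>
        <subset label="1">
          <individual ref="i1"/> <individual ref="i2"/>
        </subset>
        ...
      </subsets>
    </spartition>
  </spartitions>
</spart>
```

Every individual must be assigned to exactly one subset within each
spartition (missing or doubly-assigned individuals are validation
errors); `spartitionScore`, when present, maps to support.

## Comparison table

TSV (CSV via flag), one header row then one row per ordered pair of
models (self-pairs included), columns exactly:

```
label_1  label_2  support_1  support_2  H_1  H_2  mutual_information
joint_entropy  vi_distance  vi_normalized  match_ratio
```

Floats carry 9 significant digits. Row order is the input (file) order
of the pair grid.

## Distance matrix

A square labeled matrix for one chosen metric column, rows and columns
in partition-set order; symmetric, zero diagonal for VI/NVI, unit
diagonal for match ratio.

## Regionalized grid

TSV with one row per support-quantile cell: `support_bin_1`,
`support_bin_2` (0 = below the 0.25 quantile … 3 = above the 0.75
quantile), `pair_count`, and the cell's mean metric value (empty string,
not 0, for cells with no pairs).
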