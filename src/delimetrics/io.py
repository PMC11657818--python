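"""Readers and writers for partition exchange formats and result tables.

Three input dialects are supported, all carrying the same information —
an ordered list of partitions of one label set, optionally with per-model
support values:

* **generic-json** — either a bare JSON list of partitions (each a list
  of lists of label strings) or an object ``{"partitions": [...]}`` whose
  items carry ``label``, ``subsets``, and optional ``support`` /
  ``metadata``.
* **delineate-json** — the ranked candidate-model results dialect of
  DELINEATE-style inference: an object with a ``partitions`` array whose
  items carry ``species_leafsets`` and an ``unconstrained_probability``
  mapped to support.
* **spart-xml** — a subset of the SPART-XML species-delimitation
  exchange format: an ``individuals`` list plus one or more
  ``spartition`` elements assigning every individual to a subset.

The exact subset of each external schema that is recognized is documented
in ``docs/formats.md``; unknown fields are preserved into partition
metadata rather than dropped.  Readers never reorder: file order is the
authoritative index for all downstream tables.

Outputs are the pairwise comparison table (one row per ordered pair) and
square labeled distance matrices, TSV by default.
"""

from __future__ import annotations

import json
import os
import xml.etree.ElementTree as ET
from typing import IO, Any, Sequence

import pandas as pd

from .metrics import ComparisonRecord
from .partition import (
    IncomparableDomainsError,
    Partition,
    PartitionError,
    PartitionSet,
)

__all__ = [
    "FormatError",
    "read_generic_json",
    "write_generic_json",
    "read_delineate_json",
    "write_delineate_json",
    "read_spart_xml",
    "write_spart_xml",
    "read_partitions",
    "detect_format",
    "write_comparison_table",
    "read_comparison_table",
    "write_distance_matrix",
]

FORMAT_NAMES = ("generic-json", "delineate-json", "spart-xml")


class FormatError(PartitionError):
    """A document does not conform to the recognized schema subset."""


def _load_text(source: str | os.PathLike | IO[str]) -> str:
    if hasattr(source, "read"):
        return source.read()  # type: ignore[union-attr]
    with open(source, "r", encoding="utf-8") as fh:
        return fh.read()


def _dump_text(text: str, destination: str | os.PathLike | IO[str]) -> None:
    if hasattr(destination, "write"):
        destination.write(text)  # type: ignore[union-attr]
        return
    with open(destination, "w", encoding="utf-8") as fh:
        fh.write(text)


def _parse_json(source) -> Any:
    text = _load_text(source)
    try:
        return json.loads(text)
    except json.JSONDecodeError as exc:
        raise FormatError(
            f"malformed JSON at line {exc.lineno}, column {exc.colno}: {exc.msg}"
        ) from exc


# ---------------------------------------------------------------------------
# generic JSON


def read_generic_json(source) -> PartitionSet:
    """Read the generic JSON dialect into a :class:`PartitionSet`."""
    doc = _parse_json(source)
    partitions: list[Partition] = []
    if isinstance(doc, list):
        for idx, subsets in enumerate(doc, start=1):
            if not isinstance(subsets, list):
                raise FormatError(
                    f"partitions[{idx - 1}]: expected a list of subsets"
                )
            partitions.append(Partition(subsets, label=f"pt_{idx}"))
    elif isinstance(doc, dict) and "partitions" in doc:
        for idx, item in enumerate(doc["partitions"], start=1):
            if not isinstance(item, dict) or "subsets" not in item:
                raise FormatError(
                    f"partitions[{idx - 1}]: expected an object with 'subsets'"
                )
            partitions.append(
                Partition(
                    item["subsets"],
                    label=item.get("label", f"pt_{idx}"),
                    support=item.get("support"),
                    metadata=item.get("metadata"),
                )
            )
    else:
        raise FormatError(
            "generic JSON must be a list of partitions or an object with a "
            "'partitions' array"
        )
    try:
        return PartitionSet(partitions, source="generic-json")
    except IncomparableDomainsError as exc:
        offenders = [
            p.label for p in partitions if p.elements != partitions[0].elements
        ]
        exc.args = (f"{exc.args[0]} (offending partitions: {offenders})",)
        raise


def write_generic_json(ps: PartitionSet, destination, indent: int = 2) -> None:
    """Write a :class:`PartitionSet` as the generic JSON object dialect."""
    doc = {
        "partitions": [
            {
                "label": p.label,
                "subsets": [list(b) for b in p.blocks],
                **({"support": p.support} if p.support is not None else {}),
                **({"metadata": p.metadata} if p.metadata else {}),
            }
            for p in ps
        ]
    }
    _dump_text(json.dumps(doc, indent=indent) + "\n", destination)


# ---------------------------------------------------------------------------
# DELINEATE-style results


def read_delineate_json(source) -> PartitionSet:
    """Read a DELINEATE-style ranked results document.

    Expects an object with a ``partitions`` array; each item must carry
    ``species_leafsets`` (list of lists of lineage labels) and a
    probability under ``unconstrained_probability`` (or ``probability``),
    which becomes the partition's support.  Other per-model fields are
    preserved into metadata.
    """
    doc = _parse_json(source)
    if not isinstance(doc, dict) or "partitions" not in doc:
        raise FormatError("delineate results: missing top-level 'partitions' array")
    partitions = []
    for idx, item in enumerate(doc["partitions"], start=1):
        path = f"partitions[{idx - 1}]"
        if "species_leafsets" not in item:
            raise FormatError(f"{path}: missing 'species_leafsets'")
        leafsets = item["species_leafsets"]
        if not leafsets or any(not s for s in leafsets):
            raise PartitionError(f"{path}: empty species leafset")
        prob = item.get("unconstrained_probability", item.get("probability"))
        if prob is None:
            raise FormatError(
                f"{path}: missing 'unconstrained_probability' (or 'probability')"
            )
        extra = {
            k: v
            for k, v in item.items()
            if k
            not in {
                "species_leafsets",
                "unconstrained_probability",
                "probability",
                "label",
            }
        }
        partitions.append(
            Partition(
                leafsets,
                label=item.get("label", f"pt_{idx}"),
                support=float(prob),
                metadata=extra,
            )
        )
    return PartitionSet(partitions, source="delineate-json")


def write_delineate_json(ps: PartitionSet, destination, indent: int = 2) -> None:
    """Write a :class:`PartitionSet` in the DELINEATE-style dialect.

    Partitions without a support are given probability 0.0 (the dialect
    requires one).
    """
    doc = {
        "partitions": [
            {
                "label": p.label,
                "species_leafsets": [list(b) for b in p.blocks],
                "unconstrained_probability": (
                    p.support if p.support is not None else 0.0
                ),
                **p.metadata,
            }
            for p in ps
        ]
    }
    _dump_text(json.dumps(doc, indent=indent) + "\n", destination)


# ---------------------------------------------------------------------------
# SPART-XML subset


def read_spart_xml(source) -> PartitionSet:
    """Read the SPART-XML subset: individuals plus one or more spartitions.

    Each ``<spartition>`` yields one partition; its ``label`` attribute
    maps to the partition label and ``spartitionScore`` (if present) to
    support.  Every individual must be assigned to exactly one subset
    within each spartition.
    """
    text = _load_text(source)
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise FormatError(f"malformed XML: {exc}") from exc
    individuals = [
        el.get("id")
        for el in root.findall(".//individuals/individual")
    ]
    if not individuals or any(i is None for i in individuals):
        raise FormatError("spart-xml: missing or malformed 'individuals' list")
    domain = set(individuals)
    partitions = []
    sparts = root.findall(".//spartitions/spartition")
    if not sparts:
        raise FormatError("spart-xml: no 'spartition' elements found")
    for idx, sp in enumerate(sparts, start=1):
        label = sp.get("label", f"spartition_{idx}")
        score = sp.get("spartitionScore")
        blocks: list[list[str]] = []
        assigned: set[str] = set()
        for sub in sp.findall(".//subset"):
            members = []
            for ind in sub.findall("individual"):
                ref = ind.get("ref")
                if ref not in domain:
                    raise PartitionError(
                        f"spartition {label!r}: unknown individual reference {ref!r}"
                    )
                if ref in assigned:
                    raise PartitionError(
                        f"spartition {label!r}: individual {ref!r} assigned to "
                        "more than one subset"
                    )
                assigned.add(ref)
                members.append(ref)
            blocks.append(members)
        missing = domain - assigned
        if missing:
            raise PartitionError(
                f"spartition {label!r} is not jointly comprehensive: "
                f"individuals {sorted(missing)} unassigned"
            )
        partitions.append(
            Partition(
                blocks,
                label=label,
                support=float(score) if score is not None else None,
            )
        )
    return PartitionSet(partitions, source="spart-xml")


def write_spart_xml(ps: PartitionSet, destination) -> None:
    """Write a :class:`PartitionSet` in the SPART-XML subset."""
    root = ET.Element("spart")
    inds = ET.SubElement(ET.SubElement(root, "individuals_block"), "individuals")
    for lab in sorted(ps.element_domain):
        ET.SubElement(inds, "individual", id=lab)
    sps = ET.SubElement(root, "spartitions")
    for p in ps:
        attrs = {"label": p.label or ""}
        if p.support is not None:
            attrs["spartitionScore"] = repr(p.support)
        sp = ET.SubElement(sps, "spartition", **attrs)
        subsets = ET.SubElement(sp, "subsets")
        for bi, blk in enumerate(p.blocks, start=1):
            sub = ET.SubElement(subsets, "subset", label=str(bi))
            for lab in blk:
                ET.SubElement(sub, "individual", ref=lab)
    ET.indent(root)
    _dump_text(
        ET.tostring(root, encoding="unicode", xml_declaration=True) + "\n",
        destination,
    )


# ---------------------------------------------------------------------------
# format detection and dispatch


def detect_format(source) -> str:
    """Sniff a document's format from its content."""
    text = _load_text(source).lstrip()
    if text.startswith("<"):
        return "spart-xml"
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise FormatError(f"unrecognized format (not XML, not valid JSON): {exc}")
    if isinstance(doc, dict) and "partitions" in doc:
        items = doc["partitions"]
        if items and isinstance(items[0], dict) and "species_leafsets" in items[0]:
            return "delineate-json"
    return "generic-json"


_READERS = {
    "generic-json": read_generic_json,
    "delineate-json": read_delineate_json,
    "spart-xml": read_spart_xml,
}


def read_partitions(source, format_name: str | None = None) -> PartitionSet:
    """Read any supported format, auto-detecting unless *format_name* given."""
    if format_name is None:
        text = _load_text(source)
        format_name = detect_format_text(text)
        return _READERS[format_name](_StringSource(text))
    if format_name not in _READERS:
        raise FormatError(
            f"unknown format {format_name!r}; expected one of {FORMAT_NAMES}"
        )
    return _READERS[format_name](source)


class _StringSource:
    def __init__(self, text: str) -> None:
        self._text = text

    def read(self) -> str:
        return self._text


def detect_format_text(text: str) -> str:
    return detect_format(_StringSource(text))


# ---------------------------------------------------------------------------
# result tables

TABLE_COLUMNS = (
    "label_1",
    "label_2",
    "support_1",
    "support_2",
    "H_1",
    "H_2",
    "mutual_information",
    "joint_entropy",
    "vi_distance",
    "vi_normalized",
    "match_ratio",
)


def records_to_dataframe(records: Sequence[ComparisonRecord]) -> pd.DataFrame:
    if not records:
        raise PartitionError("no comparison records")
    return pd.DataFrame(
        [{col: getattr(r, col) for col in TABLE_COLUMNS} for r in records],
        columns=list(TABLE_COLUMNS),
    )


def write_comparison_table(
    records: Sequence[ComparisonRecord],
    destination,
    delimiter: str = "\t",
) -> None:
    """Write the pairwise comparison table.

    One header row, then one row per record in input order; floats are
    rendered with 9 significant digits, which round-trips every metric
    value well past the package's internal tolerance.
    """
    df = records_to_dataframe(records)
    df.to_csv(destination, sep=delimiter, index=False, float_format="%.9g")


def read_comparison_table(source, delimiter: str = "\t") -> pd.DataFrame:
    """Read a comparison table back into a DataFrame."""
    df = pd.read_csv(source, sep=delimiter)
    missing = set(TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(
            f"comparison table is missing columns: {sorted(missing)}"
        )
    return df


def _grid_labels(records: Sequence[ComparisonRecord]) -> list[str]:
    labels: list[str] = []
    for r in records:
        if r.label_1 not in labels:
            labels.append(r.label_1)
    return labels


def distance_matrix(
    records: Sequence[ComparisonRecord],
    metric_column: str = "vi_distance",
) -> pd.DataFrame:
    """Square labeled matrix for one metric from a full ordered-pair grid."""
    if metric_column not in ComparisonRecord.METRIC_COLUMNS:
        raise PartitionError(
            f"unknown metric column {metric_column!r}; expected one of "
            f"{ComparisonRecord.METRIC_COLUMNS}"
        )
    labels = _grid_labels(records)
    k = len(labels)
    if len(records) != k * k:
        raise PartitionError(
            f"records do not form a full ordered-pair grid: {len(records)} "
            f"records for {k} labels (need {k * k})"
        )
    idx = {lab: i for i, lab in enumerate(labels)}
    mat = pd.DataFrame(
        data=[[float("nan")] * k for _ in range(k)], index=labels, columns=labels
    )
    for r in records:
        mat.iloc[idx[r.label_1], idx[r.label_2]] = getattr(r, metric_column)
    if mat.isna().any().any():
        raise PartitionError("records do not cover every ordered pair")
    return mat


def write_distance_matrix(
    records: Sequence[ComparisonRecord],
    destination,
    metric_column: str = "vi_distance",
    delimiter: str = "\t",
) -> None:
    """Write the square labeled matrix for one metric column."""
    mat = distance_matrix(records, metric_column)
    mat.to_csv(destination, sep=delimiter, float_format="%.9g", index_label="")
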