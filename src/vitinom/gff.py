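"""Stamp registry identifiers into GFF3 gene models.

Rewrites the ``ID=``, ``Name=`` and ``Parent=`` attribute values of
``gene`` / ``mRNA`` / ``CDS`` features from an old→new identifier mapping,
working at the text level so every byte outside the replaced attribute
values — ordering, comments, unrelated features, whitespace — passes
through identical.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, Iterator, Mapping

__all__ = ["stamp_gff3_lines", "stamp_gff3_file", "read_mapping"]

STAMPED_FEATURES = {"gene", "mRNA", "CDS"}
STAMPED_ATTRIBUTES = ("ID", "Name", "Parent")


def stamp_gff3_lines(lines: Iterable[str],
                     mapping: Mapping[str, str]) -> Iterator[str]:
    """Yield GFF3 lines with mapped identifiers substituted in place."""
    for line in lines:
        if line.startswith("#") or not line.strip():
            yield line
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 9 or fields[2] not in STAMPED_FEATURES:
            yield line
            continue
        attributes = fields[8].split(";")
        for i, attribute in enumerate(attributes):
            key, sep, value = attribute.partition("=")
            if sep and key in STAMPED_ATTRIBUTES and value in mapping:
                attributes[i] = f"{key}={mapping[value]}"
        fields[8] = ";".join(attributes)
        newline = "\n" if line.endswith("\n") else ""
        yield "\t".join(fields) + newline


def stamp_gff3_file(in_path: str | Path, out_path: str | Path,
                    mapping: Mapping[str, str]) -> None:
    with open(in_path) as src, open(out_path, "w") as dst:
        for line in stamp_gff3_lines(src, mapping):
            dst.write(line)


def read_mapping(path: str | Path) -> Dict[str, str]:
    """Two-column TSV (old id, new id); a header row of `old\tnew` or
    `old_id\tnew_id` is skipped."""
    mapping: Dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            old, _, new = line.partition("\t")
            if old.lower() in {"old", "old_id"}:
                continue
            if not new:
                raise ValueError(f"mapping line without a new id: {line!r}")
            mapping[old] = new
    return mapping
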