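"""Plain-text persistence for sample profiles and comparison documents.

Every output file starts with ``#`` provenance lines recording the tool
version, the subcommand and the full parameter set, then a
``class_id<TAB>class_name<TAB>count`` body (profiles) or a wide classes
x samples table (comparisons).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .binning import SampleProfile
from .comparison import ComparisonDocument, MetadataTable
from .taxonomy import Taxonomy

__all__ = [
    "provenance_header",
    "write_profile",
    "read_profile",
    "write_comparison",
    "read_comparison",
]


def provenance_header(subcommand: str, parameters: Mapping[str, object]) -> list[str]:
    lines = [f"#lcabin={__version__}", f"#subcommand={subcommand}"]
    for key in sorted(parameters):
        lines.append(f"#{key}={parameters[key]}")
    return lines


def write_profile(
    profile: SampleProfile,
    path: str | Path,
    subcommand: str = "bin",
    tax: Taxonomy | None = None,
) -> None:
    params = dict(profile.parameters)
    params["sample"] = profile.sample_name
    params["classification"] = profile.classification_name
    params["total_reads"] = profile.total_reads
    with open(path, "w") as fh:
        for line in provenance_header(subcommand, params):
            fh.write(line + "\n")
        for cid in sorted(profile.counts, key=str):
            name = str(cid)
            if tax is not None and isinstance(cid, int) and cid in tax:
                name = tax.node(cid).name
            fh.write(f"{cid}\t{name}\t{profile.counts[cid]:g}\n")


def _read_headers(lines: list[str]) -> tuple[dict[str, str], list[str]]:
    meta: dict[str, str] = {}
    body = []
    for line in lines:
        if line.startswith("#"):
            if "=" in line:
                key, _, value = line[1:].partition("=")
                meta[key.strip()] = value.strip()
        elif line.strip():
            body.append(line.rstrip("\n"))
    return meta, body


def read_profile(path: str | Path) -> SampleProfile:
    meta, body = _read_headers(Path(path).read_text().splitlines())
    classification = meta.get("classification", "Taxonomy")
    counts: dict[object, float] = {}
    for line in body:
        fields = line.split("\t")
        cid: object = fields[0]
        if classification == "Taxonomy" and str(cid).lstrip("-").isdigit():
            cid = int(cid)
        counts[cid] = float(fields[2]) if len(fields) > 2 else float(fields[1])
    reserved = {"lcabin", "subcommand", "sample", "classification", "total_reads"}
    return SampleProfile(
        sample_name=meta.get("sample", Path(path).stem),
        classification_name=classification,
        counts=counts,
        total_reads=int(float(meta.get("total_reads", sum(counts.values())))),
        parameters={k: v for k, v in meta.items() if k not in reserved},
    )


def write_comparison(
    doc: ComparisonDocument, path: str | Path, subcommand: str = "compare",
    parameters: Mapping[str, object] | None = None,
) -> None:
    params = dict(parameters or {})
    params["classification"] = doc.classification_name
    params["normalization"] = doc.normalization
    with open(path, "w") as fh:
        for line in provenance_header(subcommand, params):
            fh.write(line + "\n")
        fh.write("class_id\t" + "\t".join(map(str, doc.samples)) + "\n")
        for cid, row in doc.matrix.iterrows():
            fh.write(str(cid) + "\t" + "\t".join(f"{v:g}" for v in row) + "\n")


def read_comparison(path: str | Path) -> ComparisonDocument:
    meta, body = _read_headers(Path(path).read_text().splitlines())
    classification = meta.get("classification", "Taxonomy")
    header = body[0].split("\t")
    samples = header[1:]
    index = []
    rows = []
    for line in body[1:]:
        fields = line.split("\t")
        cid: object = fields[0]
        if classification == "Taxonomy" and str(cid).lstrip("-").isdigit():
            cid = int(cid)
        index.append(cid)
        rows.append([float(v) for v in fields[1:]])
    matrix = pd.DataFrame(rows, index=index, columns=samples)
    return ComparisonDocument(
        matrix,
        classification,
        MetadataTable(),
        meta.get("normalization", "none"),
    )
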