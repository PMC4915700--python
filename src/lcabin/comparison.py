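"""Multi-sample comparison documents with metadata.

Per-sample profiles are combined into a single comparison document — a
classes x samples count matrix (pandas DataFrame) plus a merged metadata
table — supporting normalization to the smallest sample, total/core
biome extraction, and grouping of samples by a metadata attribute.
Metadata follows the common tool-interchange CSV convention: first
column ``#SampleID``, remaining columns attributes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import math
import pandas as pd

from .binning import SampleProfile, UNASSIGNED, UNRESOLVED

__all__ = [
    "ComparisonDocument",
    "MetadataTable",
    "ComparisonError",
    "merge_samples",
    "normalize_to_smallest",
    "total_biome",
    "core_biome",
    "group_by_attribute",
    "read_metadata_csv",
]

_SENTINELS = (UNASSIGNED, UNRESOLVED)


class ComparisonError(ValueError):
    pass


@dataclass
class MetadataTable:
    """Sample x attribute table; missing cells are NA."""

    frame: pd.DataFrame = field(default_factory=lambda: pd.DataFrame())

    @property
    def attributes(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def samples(self) -> list[str]:
        return list(self.frame.index)

    def value(self, sample: str, attribute: str):
        if sample not in self.frame.index or attribute not in self.frame.columns:
            return None
        v = self.frame.at[sample, attribute]
        return None if pd.isna(v) else v


def read_metadata_csv(source) -> MetadataTable:
    """Read the interchange metadata CSV (first column ``#SampleID``)."""
    if isinstance(source, str) and "\n" in source:
        frame = pd.read_csv(io.StringIO(source), dtype=object)
    else:
        frame = pd.read_csv(source, dtype=object)
    if frame.columns[0].lstrip("#").lower() not in ("sampleid", "sample_id", "sample"):
        raise ComparisonError(
            f"metadata CSV must start with a #SampleID column, got {frame.columns[0]!r}"
        )
    frame = frame.set_index(frame.columns[0])
    frame.index = frame.index.astype(str)
    frame.index.name = "#SampleID"
    # keep numbers numeric where the whole column parses
    for col in frame.columns:
        converted = pd.to_numeric(frame[col], errors="coerce")
        if converted.notna().sum() == frame[col].notna().sum():
            frame[col] = converted
    return MetadataTable(frame)


@dataclass
class ComparisonDocument:
    """classes x samples count matrix plus merged metadata."""

    matrix: pd.DataFrame  # index: class_id, columns: sample names
    classification_name: str
    metadata: MetadataTable = field(default_factory=MetadataTable)
    normalization: str = "none"  # {none, to-smallest}

    @property
    def samples(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def class_ids(self) -> list[object]:
        return list(self.matrix.index)

    def counts_for(self, sample: str) -> pd.Series:
        return self.matrix[sample]

    def classified_matrix(self) -> pd.DataFrame:
        """Matrix without the UNASSIGNED/UNRESOLVED bookkeeping bins."""
        keep = [c for c in self.matrix.index if c not in _SENTINELS]
        return self.matrix.loc[keep]

    def sample_profile(self, sample: str) -> SampleProfile:
        col = self.matrix[sample]
        counts = {cid: float(v) for cid, v in col.items() if v != 0}
        return SampleProfile(
            sample_name=sample,
            classification_name=self.classification_name,
            counts=counts,
            total_reads=int(round(col.sum())),
            parameters={"normalization": self.normalization},
        )


def merge_samples(
    profiles: Sequence[SampleProfile],
    metadata_sources: Iterable[MetadataTable] = (),
) -> ComparisonDocument:
    """Combine per-sample profiles into one comparison document.

    Class ids are unioned across samples (absent cells read 0); metadata
    tables are merged by attribute name with NA for missing cells.
    Mixed classifications or duplicate sample names are errors.
    """
    if not profiles:
        raise ComparisonError("no profiles to merge")
    classification = profiles[0].classification_name
    names = [p.sample_name for p in profiles]
    if len(set(names)) != len(names):
        raise ComparisonError(f"duplicate sample names in {names}")
    for p in profiles:
        if p.classification_name != classification:
            raise ComparisonError(
                f"cannot mix classifications {classification!r} and {p.classification_name!r}"
            )
    matrix = pd.DataFrame(
        {p.sample_name: pd.Series(p.counts, dtype=float) for p in profiles}
    ).fillna(0.0)
    matrix = matrix.sort_index(key=lambda idx: idx.map(str))

    tables = [m.frame for m in metadata_sources if not m.frame.empty]
    if tables:
        merged = pd.concat(tables, axis=0)
        merged = merged.groupby(level=0).first()  # one row per sample
        merged = merged.reindex([s for s in names if s in merged.index])
    else:
        merged = pd.DataFrame(index=pd.Index([], name="#SampleID"))
    return ComparisonDocument(matrix, classification, MetadataTable(merged))


def normalize_to_smallest(doc: ComparisonDocument) -> ComparisonDocument:
    """Scale every sample to the smallest sample's classified total.

    Idempotent: once totals are equal the scale factors are all 1.
    A sample with zero classified counts is an error.
    """
    classified = doc.classified_matrix()
    totals = classified.sum(axis=0)
    zero = [s for s, t in totals.items() if t <= 0]
    if zero:
        raise ComparisonError(f"sample(s) with zero classified total: {zero}")
    target = totals.min()
    scaled = doc.matrix.mul(target / totals, axis=1)
    return ComparisonDocument(scaled, doc.classification_name, doc.metadata, "to-smallest")


def total_biome(doc: ComparisonDocument) -> SampleProfile:
    """The union of all samples: per-class sum over samples."""
    sums = doc.matrix.sum(axis=1)
    counts = {cid: float(v) for cid, v in sums.items() if v != 0}
    return SampleProfile(
        sample_name="total-biome",
        classification_name=doc.classification_name,
        counts=counts,
        total_reads=int(round(sums.sum())),
        parameters={"normalization": doc.normalization},
    )


def core_biome(
    doc: ComparisonDocument,
    min_fraction_of_samples: float,
    detection_min: float = 1.0,
) -> SampleProfile:
    """Classes present in at least a given fraction of the samples.

    Presence in a sample means count >= *detection_min*; a class is in
    the core when present in >= ceil(fraction x sample count) samples.
    Its reported count sums over the samples in which it is present.
    """
    if not 0 < min_fraction_of_samples <= 1:
        raise ComparisonError("min_fraction_of_samples must be in (0, 1]")
    needed = math.ceil(min_fraction_of_samples * len(doc.samples))
    present = doc.matrix >= detection_min
    prevalence = present.sum(axis=1)
    core = prevalence[prevalence >= needed].index
    counts = {
        cid: float(doc.matrix.loc[cid][present.loc[cid]].sum()) for cid in core
    }
    return SampleProfile(
        sample_name=f"core-biome(f>={min_fraction_of_samples})",
        classification_name=doc.classification_name,
        counts=counts,
        total_reads=int(round(sum(counts.values()))),
        parameters={
            "min_fraction_of_samples": min_fraction_of_samples,
            "detection_min": detection_min,
        },
    )


def group_by_attribute(doc: ComparisonDocument, attribute: str) -> ComparisonDocument:
    """Merge samples sharing a metadata attribute value into pseudo-samples.

    Samples without a value for the attribute form the "NA" group.
    Counts are summed within each group; the grouped document's metadata
    carries the attribute with the group value.
    """
    if attribute not in doc.metadata.attributes:
        raise ComparisonError(f"unknown metadata attribute {attribute!r}")
    groups: dict[str, list[str]] = {}
    for sample in doc.samples:
        value = doc.metadata.value(sample, attribute)
        key = "NA" if value is None else str(value)
        groups.setdefault(key, []).append(sample)
    matrix = pd.DataFrame(
        {key: doc.matrix[members].sum(axis=1) for key, members in sorted(groups.items())}
    )
    meta = pd.DataFrame(
        {attribute: {key: key for key in groups}},
    )
    meta.index.name = "#SampleID"
    return ComparisonDocument(
        matrix, doc.classification_name, MetadataTable(meta), doc.normalization
    )


def write_comparison_tsv(doc: ComparisonDocument, path, header_lines: Iterable[str] = ()) -> None:
    """Export the wide classes x samples table with `#` provenance lines."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"#{line}\n" if not line.startswith("#") else f"{line}\n")
        fh.write("class_id\t" + "\t".join(map(str, doc.samples)) + "\n")
        for cid, row in doc.matrix.iterrows():
            fh.write(str(cid) + "\t" + "\t".join(f"{v:g}" for v in row) + "\n")
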