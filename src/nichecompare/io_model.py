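"""Data model and tabular I/O for the niche-comparison pipeline.

The pipeline operates on three tables: an OTU-by-sample integer count
matrix, per-sample metadata (dog, oral niche, sampling occasion, mouth
side) and per-OTU annotation (taxonomy, phylum, Gram-stain status,
oxygen requirement).  Counts are read/written as TSV (OTUs as rows,
samples as columns) or as dense BIOM 1.0 JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NICHES",
    "SIDED_NICHES",
    "FormatError",
    "ValidationError",
    "CountTable",
    "ProportionTable",
    "SampleRecord",
    "TaxonRecord",
    "DesignSummary",
    "read_count_table",
    "write_count_table",
    "to_proportions",
    "study_wide_proportions",
    "read_samples",
    "write_samples",
    "samples_to_frame",
    "samples_from_frame",
    "read_taxa",
    "write_taxa",
    "taxa_to_frame",
    "taxa_from_frame",
    "summarize_design",
]

#: The four oral niches, in canonical order.
NICHES: tuple[str, ...] = ("plaque", "buccal", "tongue", "saliva")

#: Niches sampled separately on the left and right side of the mouth.
SIDED_NICHES = frozenset({"plaque", "buccal"})

GRAM_LEVELS = ("positive", "negative", "unknown")
OXYGEN_LEVELS = ("aerobe", "anaerobe", "facultative", "unknown")

#: Default sample-QC read-count threshold (strict "<" exclusion).
QC_MIN_READS = 1000


class FormatError(ValueError):
    """A file does not conform to the expected tabular format."""


class ValidationError(ValueError):
    """Parsed data violate a data-model invariant."""


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------


@dataclass
class CountTable:
    """OTU x sample matrix of non-negative integer read counts.

    Parameters
    ----------
    otu_ids, sample_ids
        Unique ordered identifiers for rows and columns.
    counts
        ``(n_otus, n_samples)`` integer array.
    """

    otu_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.otu_ids = [str(o) for o in self.otu_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if counts.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.otu_ids)} OTUs x {len(self.sample_ids)} samples"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.isfinite(counts)) or np.any(counts != np.round(counts)):
                raise ValidationError("counts must be integers")
        counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            raise ValidationError("counts must be >= 0")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise FormatError("duplicate otu_ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample_ids")
        self.counts = counts

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def column_totals(self) -> np.ndarray:
        """Total reads per sample."""
        return self.counts.sum(axis=0)

    def row_totals(self) -> np.ndarray:
        """Total reads per OTU across the study."""
        return self.counts.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.otu_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountTable":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def select_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in sample_ids]
        return CountTable(list(self.otu_ids), list(sample_ids), self.counts[:, cols])

    def select_otus(self, otu_ids: Sequence[str]) -> "CountTable":
        idx = {o: i for i, o in enumerate(self.otu_ids)}
        rows = [idx[o] for o in otu_ids]
        return CountTable(list(otu_ids), list(self.sample_ids), self.counts[rows, :])

    def __eq__(self, other: object) -> bool:  # value semantics
        if not isinstance(other, CountTable):
            return NotImplemented
        return (
            self.otu_ids == other.otu_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass
class ProportionTable:
    """Per-sample relative abundances on the same axes as a :class:`CountTable`.

    Columns sum to 1; samples whose total read count was zero are dropped
    at construction and listed in ``dropped_samples``.
    """

    otu_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    dropped_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise ValidationError("values shape does not match axes")
        if self.values.size:
            colsums = self.values.sum(axis=0)
            if np.any(np.abs(colsums - 1.0) > 1e-9):
                raise ValidationError("sample proportions must sum to 1")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.otu_ids, columns=self.sample_ids)


def to_proportions(ct: CountTable) -> ProportionTable:
    """Convert counts to per-sample proportions.

    Each value is the count of an OTU divided by its sample's total read
    count.  Samples with zero total are excluded and flagged.
    """
    totals = ct.column_totals()
    if ct.n_samples == 0 or not np.any(totals > 0):
        raise ValidationError("cannot compute proportions of an all-zero table")
    keep = totals > 0
    dropped = [s for s, k in zip(ct.sample_ids, keep) if not k]
    vals = ct.counts[:, keep] / totals[keep]
    kept_ids = [s for s, k in zip(ct.sample_ids, keep) if k]
    return ProportionTable(list(ct.otu_ids), kept_ids, vals, dropped)


def study_wide_proportions(ct: CountTable) -> pd.Series:
    """Study-wide relative abundance per OTU: row total / grand total.

    This is the arithmetic behind "proportion of total sequence reads"
    abundance rankings.
    """
    grand = int(ct.counts.sum())
    if grand == 0:
        raise ValidationError("cannot compute proportions of an all-zero table")
    return pd.Series(ct.row_totals() / grand, index=ct.otu_ids, name="proportion")


# ---------------------------------------------------------------------------
# sample and taxon metadata
# ---------------------------------------------------------------------------


@dataclass
class SampleRecord:
    """Metadata for one collected sample.

    ``side`` is "left"/"right" only for the duplicated niches (plaque,
    buccal mucosa), "none" otherwise.  ``amplified`` is False for samples
    that failed DNA amplification and therefore never produced counts;
    ``qc_pass`` is False exactly when ``total_reads`` is below the QC
    threshold.
    """

    sample_id: str
    dog_id: str
    niche: str
    occasion: int
    side: str = "none"
    total_reads: int = 0
    qc_pass: bool = False
    amplified: bool = True

    def __post_init__(self) -> None:
        if self.niche not in NICHES:
            raise ValidationError(f"unknown niche {self.niche!r}")
        if self.niche in SIDED_NICHES:
            if self.side not in ("left", "right"):
                raise ValidationError(
                    f"{self.niche} sample {self.sample_id} must have side left/right"
                )
        elif self.side != "none":
            raise ValidationError(
                f"{self.niche} sample {self.sample_id} must have side 'none'"
            )
        if self.occasion < 1:
            raise ValidationError("occasion index starts at 1")


def apply_qc_flags(
    samples: list[SampleRecord], threshold: int = QC_MIN_READS
) -> list[SampleRecord]:
    """Recompute qc_pass from total_reads with a strict '<' threshold."""
    return [replace(s, qc_pass=s.total_reads >= threshold) for s in samples]


@dataclass
class TaxonRecord:
    """Annotation for one OTU (or the pooled "RARE" unit)."""

    otu_id: str
    taxonomy_label: str = ""
    phylum: str = ""
    percent_identity: float = 100.0
    oral_taxon_id: str = ""
    gram: str = "unknown"
    oxygen: str = "unknown"
    is_rare: bool = False

    def __post_init__(self) -> None:
        if self.gram not in GRAM_LEVELS:
            raise ValidationError(f"gram must be one of {GRAM_LEVELS}")
        if self.oxygen not in OXYGEN_LEVELS:
            raise ValidationError(f"oxygen must be one of {OXYGEN_LEVELS}")
        if not 0.0 <= float(self.percent_identity) <= 100.0:
            raise ValidationError("percent_identity must be in [0, 100]")


@dataclass
class DesignSummary:
    """Per-niche sample counts at each bookkeeping stage."""

    collected: dict[str, int]
    sequenced: dict[str, int]
    qc_pass: dict[str, int]

    @property
    def total_collected(self) -> int:
        return sum(self.collected.values())

    @property
    def total_sequenced(self) -> int:
        return sum(self.sequenced.values())

    @property
    def total_qc_pass(self) -> int:
        return sum(self.qc_pass.values())


def summarize_design(samples: Iterable[SampleRecord]) -> DesignSummary:
    """Count samples per niche at the collected / sequenced / QC stages."""
    collected = {n: 0 for n in NICHES}
    sequenced = {n: 0 for n in NICHES}
    qc = {n: 0 for n in NICHES}
    for s in samples:
        collected[s.niche] += 1
        if s.amplified:
            sequenced[s.niche] += 1
            if s.qc_pass:
                qc[s.niche] += 1
    return DesignSummary(collected, sequenced, qc)


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------


def _read_tsv_counts(path: Path) -> CountTable:
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{path}: empty count table")
    header = lines[0].split("\t")
    if len(header) < 1 or header[0] != "otu_id":
        raise FormatError(f"{path}: first column must be 'otu_id'")
    sample_ids = header[1:]
    otu_ids: list[str] = []
    rows: list[list[int]] = []
    for ln in lines[1:]:
        cells = ln.split("\t")
        if len(cells) != len(header):
            raise FormatError(f"{path}: ragged row {cells[0]!r}")
        otu_ids.append(cells[0])
        row = []
        for c in cells[1:]:
            try:
                v = int(c)
            except ValueError as e:
                raise ValidationError(f"{path}: non-integer count {c!r}") from e
            if v < 0:
                raise ValidationError(f"{path}: negative count {v}")
            row.append(v)
        rows.append(row)
    counts = np.array(rows, dtype=np.int64) if rows else np.zeros((0, len(sample_ids)), dtype=np.int64)
    return CountTable(otu_ids, sample_ids, counts)


def _read_biom_json(path: Path) -> CountTable:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"{path}: not valid JSON") from e
    try:
        if doc.get("matrix_type") != "dense":
            raise FormatError(f"{path}: only dense BIOM matrices are supported")
        otu_ids = [r["id"] for r in doc["rows"]]
        sample_ids = [c["id"] for c in doc["columns"]]
        data = np.asarray(doc["data"])
    except (KeyError, TypeError) as e:
        raise FormatError(f"{path}: malformed BIOM document") from e
    return CountTable(otu_ids, sample_ids, data)


def read_count_table(path: str | Path, format: str = "tsv") -> CountTable:
    """Read a count table from ``tsv`` or ``biom-json``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        return _read_tsv_counts(path)
    if format == "biom-json":
        return _read_biom_json(path)
    raise ValueError(f"unknown format {format!r}")


def write_count_table(
    ct: CountTable,
    path: str | Path,
    format: str = "tsv",
    header_comment: str | None = None,
) -> None:
    """Write a count table; an optional '#' comment line records provenance."""
    path = Path(path)
    if format == "tsv":
        with path.open("w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            fh.write("otu_id\t" + "\t".join(ct.sample_ids) + "\n")
            for otu, row in zip(ct.otu_ids, ct.counts):
                fh.write(otu + "\t" + "\t".join(str(int(v)) for v in row) + "\n")
    elif format == "biom-json":
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": header_comment or "nichecompare",
            "matrix_type": "dense",
            "matrix_element_type": "int",
            "shape": [ct.n_otus, ct.n_samples],
            "rows": [{"id": o, "metadata": None} for o in ct.otu_ids],
            "columns": [{"id": s, "metadata": None} for s in ct.sample_ids],
            "data": ct.counts.tolist(),
        }
        Path(path).write_text(json.dumps(doc))
    else:
        raise ValueError(f"unknown format {format!r}")


_SAMPLE_COLS = ["sample_id", "dog_id", "niche", "occasion", "side", "total_reads", "qc_pass", "amplified"]


def samples_to_frame(samples: list[SampleRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in samples], columns=_SAMPLE_COLS)


def samples_from_frame(df: pd.DataFrame) -> list[SampleRecord]:
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        out.append(
            SampleRecord(
                sample_id=str(d["sample_id"]),
                dog_id=str(d["dog_id"]),
                niche=str(d["niche"]),
                occasion=int(d["occasion"]),
                side=str(d.get("side", "none") or "none"),
                total_reads=int(d.get("total_reads", 0)),
                qc_pass=bool(d.get("qc_pass", False)),
                amplified=bool(d.get("amplified", True)),
            )
        )
    ids = [s.sample_id for s in out]
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate sample_ids in metadata table")
    return out


def write_samples(samples: list[SampleRecord], path: str | Path, header_comment: str | None = None) -> None:
    _write_frame(samples_to_frame(samples), path, header_comment)


def read_samples(path: str | Path) -> list[SampleRecord]:
    return samples_from_frame(pd.read_csv(path, sep="\t", comment="#"))


_TAXA_COLS = ["otu_id", "taxonomy_label", "phylum", "percent_identity", "oral_taxon_id", "gram", "oxygen", "is_rare"]


def taxa_to_frame(taxa: list[TaxonRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(t) for t in taxa], columns=_TAXA_COLS)


def taxa_from_frame(df: pd.DataFrame) -> list[TaxonRecord]:
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        out.append(
            TaxonRecord(
                otu_id=str(d["otu_id"]),
                taxonomy_label=str(d.get("taxonomy_label", "") or ""),
                phylum=str(d.get("phylum", "") or ""),
                percent_identity=float(d.get("percent_identity", 100.0)),
                oral_taxon_id=str(d.get("oral_taxon_id", "") or ""),
                gram=str(d.get("gram", "unknown") or "unknown"),
                oxygen=str(d.get("oxygen", "unknown") or "unknown"),
                is_rare=bool(d.get("is_rare", False)),
            )
        )
    ids = [t.otu_id for t in out]
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate otu_ids in taxon table")
    return out


def write_taxa(taxa: list[TaxonRecord], path: str | Path, header_comment: str | None = None) -> None:
    _write_frame(taxa_to_frame(taxa), path, header_comment)


def read_taxa(path: str | Path) -> list[TaxonRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
    return taxa_from_frame(df)


def _write_frame(df: pd.DataFrame, path: str | Path, header_comment: str | None) -> None:
    with Path(path).open("w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)
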