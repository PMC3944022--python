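"""Tabular input/output for the pipeline.

Three plain TSV dialects are consumed and emitted:

* a MAF-like somatic mutation table (one row per variant call per sample),
* a SEG-like segment table with an integer total copy number and an LOH flag,
* a cohort manifest pairing each patient's primary and metastatic samples.

All genomic coordinates are 1-based, closed intervals, matching the usual
single-locus notation for point mutations (e.g. ``chr4:55972974``).  Indel
alleles use ``-`` for the missing side; no left-normalisation is attempted, so
inputs must be consistently normalised upstream.  Parsing is strict: every
data line is either parsed or rejected with a line-numbered error — rows are
never silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger("clonalpair")

#: The seven functional effect classes retained by the upstream variant
#: filter: non-synonymous, synonymous, stop gain/loss, frameshift and
#: non-frameshift indels, and splice-site mutations.
EFFECT_CLASSES = frozenset(
    {
        "nonsynonymous",
        "synonymous",
        "stopgain",
        "stoploss",
        "frameshift_indel",
        "nonframeshift_indel",
        "splicing",
    }
)

#: Effect classes treated as non-silent for gene-level statistics.
NON_SILENT_EFFECTS = frozenset(EFFECT_CLASSES - {"synonymous"})

_ALLELE_CHARS = frozenset("ACGT")


class FormatError(ValueError):
    """A table violates its dialect (missing column, duplicate id, ...)."""


class RecordError(ValueError):
    """A single row is invalid; the message names the line."""


def _check_allele(value: str) -> str:
    if value == "-":
        return value
    if value and set(value) <= _ALLELE_CHARS:
        return value
    raise ValueError(f"allele {value!r} is not a DNA string or '-'")


@dataclass(frozen=True, order=True)
class MutationRecord:
    """One somatic variant call in one sample."""

    sample_id: str
    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    gene: str
    effect: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        _check_allele(self.ref_allele)
        _check_allele(self.alt_allele)
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref_allele equals alt_allele")
        if self.effect not in EFFECT_CLASSES:
            raise ValueError(
                f"unknown effect {self.effect!r}; allowed: "
                + ", ".join(sorted(EFFECT_CLASSES))
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity key (chromosome, position, ref, alt) for cross-sample matching."""
        return (self.chromosome, self.position, self.ref_allele, self.alt_allele)

    @property
    def is_substitution(self) -> bool:
        """True for single-nucleotide substitutions (indels excluded)."""
        return (
            len(self.ref_allele) == 1
            and len(self.alt_allele) == 1
            and self.ref_allele in _ALLELE_CHARS
            and self.alt_allele in _ALLELE_CHARS
        )


@dataclass(frozen=True)
class SegmentRecord:
    """One genomic segment with total copy number and LOH status for one sample."""

    sample_id: str
    chromosome: str
    start: int
    end: int
    copy_number: int
    loh: bool

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.copy_number < 0:
            raise ValueError(f"copy_number must be >= 0, got {self.copy_number}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class PatientPair:
    patient_id: str
    primary_sample_id: str
    metastasis_sample_id: str
    normal_sample_id: str | None = None


@dataclass
class CohortManifest:
    """Pairing of primary and metastasis samples per patient.

    Sample ids must be unique across all roles and patients.
    """

    patients: list[PatientPair] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for pair in self.patients:
            ids = [pair.primary_sample_id, pair.metastasis_sample_id]
            if pair.normal_sample_id:
                ids.append(pair.normal_sample_id)
            for sid in ids:
                if sid in seen:
                    raise FormatError(f"duplicate sample id {sid!r} in manifest")
                seen.add(sid)

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    @property
    def primary_ids(self) -> list[str]:
        return [p.primary_sample_id for p in self.patients]

    @property
    def metastasis_ids(self) -> list[str]:
        return [p.metastasis_sample_id for p in self.patients]

    @property
    def tumor_ids(self) -> list[str]:
        out: list[str] = []
        for p in self.patients:
            out.extend([p.primary_sample_id, p.metastasis_sample_id])
        return out


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

MUTATION_COLUMNS = ("sample", "chrom", "pos", "ref", "alt", "gene", "effect")
SEGMENT_COLUMNS = ("sample", "chrom", "start", "end", "copy_number", "loh")
MANIFEST_COLUMNS = ("patient", "primary", "metastasis", "normal")

_LOH_STRINGS = {"0": False, "1": True, "false": False, "true": True}


def _read_header(
    path: Path, required: Sequence[str], column_map: dict[str, str] | None
) -> tuple[list[str], dict[str, int]]:
    with open(path) as fh:
        header_line = fh.readline()
    if not header_line:
        raise FormatError(f"{path}: empty file (no header)")
    names = header_line.rstrip("\n").split("\t")
    if column_map:
        names = [column_map.get(n, n) for n in names]
    index = {name: i for i, name in enumerate(names)}
    for col in required:
        if col not in index:
            raise FormatError(f"{path}: missing required column {col!r}")
    return names, index


def _data_lines(path: Path) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line:
                continue
            yield lineno, line.split("\t")


def read_mutation_table(
    path: str | Path, column_map: dict[str, str] | None = None
) -> list[MutationRecord]:
    """Read a MAF-like TSV into a list of :class:`MutationRecord`.

    ``column_map`` renames input header names onto the canonical seven
    (``sample, chrom, pos, ref, alt, gene, effect``).  Row order is preserved;
    any invalid row aborts with a :class:`RecordError` naming its line.
    """
    path = Path(path)
    _, idx = _read_header(path, MUTATION_COLUMNS, column_map)
    records: list[MutationRecord] = []
    for lineno, fields in _data_lines(path):
        try:
            records.append(
                MutationRecord(
                    sample_id=fields[idx["sample"]],
                    chromosome=fields[idx["chrom"]],
                    position=int(fields[idx["pos"]]),
                    ref_allele=fields[idx["ref"]],
                    alt_allele=fields[idx["alt"]],
                    gene=fields[idx["gene"]],
                    effect=fields[idx["effect"]],
                )
            )
        except (ValueError, IndexError) as exc:
            raise RecordError(f"{path}:{lineno}: {exc}") from exc
    if not records:
        logger.warning("%s: mutation table contains no data rows", path)
    return records


def read_segment_table(
    path: str | Path, column_map: dict[str, str] | None = None
) -> list[SegmentRecord]:
    """Read a SEG-like TSV into a list of :class:`SegmentRecord`.

    The ``loh`` column accepts 0/1/true/false (case-insensitive).
    """
    path = Path(path)
    _, idx = _read_header(path, SEGMENT_COLUMNS, column_map)
    records: list[SegmentRecord] = []
    for lineno, fields in _data_lines(path):
        try:
            loh_raw = fields[idx["loh"]].strip().lower()
            if loh_raw not in _LOH_STRINGS:
                raise ValueError(f"loh value {loh_raw!r} not in 0/1/true/false")
            records.append(
                SegmentRecord(
                    sample_id=fields[idx["sample"]],
                    chromosome=fields[idx["chrom"]],
                    start=int(fields[idx["start"]]),
                    end=int(fields[idx["end"]]),
                    copy_number=int(fields[idx["copy_number"]]),
                    loh=_LOH_STRINGS[loh_raw],
                )
            )
        except (ValueError, IndexError) as exc:
            raise RecordError(f"{path}:{lineno}: {exc}") from exc
    if not records:
        logger.warning("%s: segment table contains no data rows", path)
    return records


def read_manifest(
    path: str | Path, column_map: dict[str, str] | None = None
) -> CohortManifest:
    """Read a cohort manifest TSV (patient, primary, metastasis[, normal])."""
    path = Path(path)
    names, idx = _read_header(path, MANIFEST_COLUMNS[:3], column_map)
    has_normal = "normal" in names
    pairs: list[PatientPair] = []
    for lineno, fields in _data_lines(path):
        try:
            normal = fields[idx["normal"]] if has_normal else ""
            pairs.append(
                PatientPair(
                    patient_id=fields[idx["patient"]],
                    primary_sample_id=fields[idx["primary"]],
                    metastasis_sample_id=fields[idx["metastasis"]],
                    normal_sample_id=normal or None,
                )
            )
        except IndexError as exc:
            raise RecordError(f"{path}:{lineno}: truncated row") from exc
    return CohortManifest(patients=pairs)


# ---------------------------------------------------------------------------
# Writers (inverse of the readers; write->read is the identity)
# ---------------------------------------------------------------------------


def write_mutation_table(records: Iterable[MutationRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(MUTATION_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.sample_id}\t{r.chromosome}\t{r.position}\t{r.ref_allele}\t"
                f"{r.alt_allele}\t{r.gene}\t{r.effect}\n"
            )


def write_segment_table(records: Iterable[SegmentRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SEGMENT_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.sample_id}\t{r.chromosome}\t{r.start}\t{r.end}\t"
                f"{r.copy_number}\t{int(r.loh)}\n"
            )


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(MANIFEST_COLUMNS) + "\n")
        for p in manifest:
            fh.write(
                f"{p.patient_id}\t{p.primary_sample_id}\t{p.metastasis_sample_id}\t"
                f"{p.normal_sample_id or ''}\n"
            )


def group_by_sample(records: Iterable) -> dict[str, list]:
    """Group mutation or segment records by ``sample_id`` preserving order."""
    out: dict[str, list] = {}
    for r in records:
        out.setdefault(r.sample_id, []).append(r)
    return out
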