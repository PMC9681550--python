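"""Read assignment, counting, RPM normalization, and the abundance filter.

Catalog fragments are short fixed sequences, so read assignment is exact
sequence identity after U->T/uppercase normalization: a read matching exactly
one catalog id is ``unique``, one matching two or more distinct ids is
``ambiguous`` and discarded from counting (the conservative choice), and
anything else is ``unmapped``.  A single-mismatch tolerance and a 3' CCA-trim
retry exist behind flags, both off by default.

RPM uses the uniquely-assigned reads as its denominator — the only
denominator computable from the pipeline's own outputs — so RPM columns sum
to 1e6 for any sample with at least one unique read.  The abundance filter
drops fragments whose log2(mean-across-samples RPM) falls below the
threshold (default 1, i.e. mean RPM < 2), the screen that removes random
degradation fragments.  The mean is taken before the log so all-zero
fragments are well-defined.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import FragmentRecord, normalize_sequence

__all__ = [
    "ReadAssignment",
    "ExpressionMatrix",
    "read_fastq",
    "assign_reads",
    "count_fragments",
    "rpm_normalize",
    "abundance_filter",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    status: str  # "unique" | "ambiguous" | "unmapped"
    fragment_id: str | None = None


@dataclass
class ExpressionMatrix:
    """Fragments x samples matrix with provenance of unit and filter."""

    data: pd.DataFrame  # index: fragment_ids, columns: sample_ids
    unit: str  # "count" | "RPM"
    filter_applied: bool = False
    filter_threshold_log2: float | None = None
    removed_fragments: list[str] = field(default_factory=list)

    @property
    def fragment_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


def read_fastq(path) -> tuple[list[tuple[str, str]], int]:
    """Tolerant FASTQ reader returning ([(read_id, sequence), ...], n_skipped).

    Malformed 4-line records (missing '@'/'+' markers or a length-mismatched
    quality line) are skipped and counted rather than aborting the stream.
    Gzipped input is accepted.
    """
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    records: list[tuple[str, str]] = []
    skipped = 0
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            header = header.rstrip("\n")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline().rstrip("\n")
            qual = fh.readline().rstrip("\n")
            if (
                not header.startswith("@")
                or not plus.startswith("+")
                or not seq
                or len(qual) != len(seq)
            ):
                skipped += 1
                continue
            records.append((header[1:].split()[0], seq))
    return records, skipped


def _sequence_index(catalog: list[FragmentRecord]) -> dict[str, list[str]]:
    index: dict[str, list[str]] = {}
    for rec in catalog:
        index.setdefault(rec.sequence, []).append(rec.fragment_id)
    return index


def _hamming1_match(seq: str, index: dict[str, list[str]]) -> list[str]:
    hits: list[str] = []
    for cat_seq, ids in index.items():
        if len(cat_seq) == len(seq) and sum(a != b for a, b in zip(seq, cat_seq)) <= 1:
            hits.extend(ids)
    return hits


def assign_reads(
    reads,
    catalog: list[FragmentRecord],
    *,
    cca_trim: bool = False,
    allow_one_mismatch: bool = False,
) -> tuple[list[ReadAssignment], int]:
    """Assign reads to catalog fragments by exact sequence identity.

    ``reads`` is a FASTQ path or an iterable of (read_id, sequence) pairs.
    Returns (assignments, skipped_record_count).
    """
    if not catalog:
        raise ValueError("catalog is empty")
    index = _sequence_index(catalog)
    trf3_trimmed: dict[str, list[str]] = {}
    if cca_trim:
        # retry table: tRF-3 fragments with up to 3 terminal 3' bases removed
        for rec in catalog:
            if rec.type == "tRF-3":
                for k in (1, 2, 3):
                    trf3_trimmed.setdefault(rec.sequence[:-k], []).append(rec.fragment_id)

    skipped = 0
    if isinstance(reads, (str, bytes)) or hasattr(reads, "__fspath__"):
        pairs, skipped = read_fastq(reads)
    else:
        pairs = list(reads)

    assignments: list[ReadAssignment] = []
    for rid, raw_seq in pairs:
        seq = normalize_sequence(raw_seq)
        hits = index.get(seq)
        if hits is None and cca_trim:
            for k in (1, 2, 3):
                trimmed = seq[:-k]
                if trimmed in trf3_trimmed and len(trimmed) >= 14:
                    hits = trf3_trimmed[trimmed]
                    break
        if hits is None and allow_one_mismatch:
            hits = _hamming1_match(seq, index) or None
        if hits is None:
            assignments.append(ReadAssignment(rid, "unmapped"))
        elif len(set(hits)) == 1:
            assignments.append(ReadAssignment(rid, "unique", hits[0]))
        else:
            assignments.append(ReadAssignment(rid, "ambiguous"))
    if skipped:
        logger.warning("skipped %d malformed FASTQ records", skipped)
    return assignments, skipped


def count_fragments(
    assignments_per_sample: dict[str, list[ReadAssignment]],
    catalog: list[FragmentRecord],
) -> ExpressionMatrix:
    """Count unique-status reads per fragment per sample.

    Conservation holds per sample: unique + ambiguous + unmapped = total.
    """
    fragment_ids = [rec.fragment_id for rec in catalog]
    data = pd.DataFrame(
        0, index=pd.Index(fragment_ids, name="fragment_id"),
        columns=list(assignments_per_sample), dtype=np.int64,
    )
    from collections import Counter

    for sample, assignments in assignments_per_sample.items():
        counts = Counter(a.fragment_id for a in assignments if a.status == "unique")
        if not counts:
            warnings.warn(f"sample {sample}: no uniquely assigned reads")
            continue
        col = pd.Series(counts).reindex(fragment_ids, fill_value=0)
        data[sample] = col.to_numpy(dtype=np.int64)
    return ExpressionMatrix(data=data, unit="count")


def rpm_normalize(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Reads-per-million over uniquely assigned reads, per sample."""
    if counts.unit != "count":
        raise ValueError("rpm_normalize expects a count matrix")
    totals = counts.data.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"samples with zero unique reads: {list(totals.index[zero])}")
    safe = totals.replace(0, 1)
    rpm = counts.data.div(safe, axis=1) * 1e6
    return ExpressionMatrix(data=rpm.astype(float), unit="RPM")


def abundance_filter(
    rpm: ExpressionMatrix, threshold_log2: float = 1.0
) -> ExpressionMatrix:
    """Retain fragments with log2(mean RPM) >= threshold (mean RPM >= 2 at default)."""
    if rpm.unit != "RPM":
        raise ValueError("abundance_filter expects an RPM matrix")
    mean_rpm = rpm.data.mean(axis=1)
    keep = mean_rpm >= 2.0 ** threshold_log2
    removed = list(rpm.data.index[~keep])
    if removed:
        logger.info("abundance filter removed %d fragments", len(removed))
    return ExpressionMatrix(
        data=rpm.data.loc[keep].copy(),
        unit="RPM",
        filter_applied=True,
        filter_threshold_log2=threshold_log2,
        removed_fragments=removed,
    )
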