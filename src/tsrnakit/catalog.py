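"""tsRNA fragment catalog: mapping, classification, and summaries.

A fragment is re-mapped by exact substring search against every mature and
precursor tRNA model, then classified into the five tRF classes:

* tRF-5  — anchored at the mature 5' end (stops before the 3' terminus)
* tRF-3  — ends exactly at the mature 3' terminus (includes the CCA tail)
* i-tRF  — internal to the mature body, touching neither end
* tRF-1  — entirely within the precursor's 3' trailer
* 5'U-tRF — starts inside the precursor's 5' leader

A full-length mature match is not a fragment and stays ``unclassified``.
When a fragment maps to several parents with conflicting classes, the
priority tRF-3 > tRF-5 > i-tRF > tRF-1 > 5'U-tRF picks the reported type
(every parent mapping is retained).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .reference import LOOP_LABELS, MatureTRNA, PrecursorTRNA, TRNAGene

__all__ = [
    "ParentMapping",
    "FragmentRecord",
    "TRNAModels",
    "build_reference_models",
    "map_fragment",
    "classify_fragment",
    "annotate_cleavage_loop",
    "classify_catalog",
    "summarize_catalog",
    "load_fragment_table",
    "write_catalog",
]

logger = logging.getLogger(__name__)

TRF_TYPES = ("tRF-5", "tRF-3", "i-tRF", "tRF-1", "5'U-tRF")
#: tie-break priority for multi-parent conflicts (lower = wins)
TYPE_PRIORITY = {"tRF-3": 0, "tRF-5": 1, "i-tRF": 2, "tRF-1": 3, "5'U-tRF": 4, "unclassified": 5}

MIN_FRAGMENT_LEN = 14
MAX_FRAGMENT_LEN = 50


class UnmappableFragment(ValueError):
    """Raised when classification is requested for a fragment with no parent."""


def normalize_sequence(seq: str) -> str:
    return seq.strip().upper().replace("U", "T")


@dataclass(frozen=True)
class ParentMapping:
    gene_id: str
    context: str  # "mature" | "precursor"
    start: int  # 1-based closed
    end: int
    exact: bool = True


@dataclass
class FragmentRecord:
    fragment_id: str
    sequence: str
    parents: list[ParentMapping] = field(default_factory=list)
    type: str = "unclassified"
    cleavage_loop: str = "none"
    chromosomes: set[str] = field(default_factory=set)
    declared_type: str | None = None

    def __post_init__(self) -> None:
        self.sequence = normalize_sequence(self.sequence)


@dataclass
class TRNAModels:
    """Mature and precursor models for every gene, plus gene metadata."""

    genes: dict[str, TRNAGene]
    matures: dict[str, MatureTRNA]
    precursors: dict[str, PrecursorTRNA]

    def chromosome_of(self, gene_id: str) -> str:
        return self.genes[gene_id].chromosome


def build_reference_models(
    genes,
    genome,
    leader_len: int = 20,
    trailer_len: int = 30,
    landmark_table=None,
) -> TRNAModels:
    from .reference import build_mature_trna, build_precursor, read_genome

    if not isinstance(genome, dict):
        genome = read_genome(genome)
    matures = {g.gene_id: build_mature_trna(g, landmark_table) for g in genes}
    precursors = {
        g.gene_id: build_precursor(g, genome, leader_len, trailer_len) for g in genes
    }
    return TRNAModels(
        genes={g.gene_id: g for g in genes}, matures=matures, precursors=precursors
    )


def _occurrences(needle: str, haystack: str) -> list[int]:
    """All (possibly overlapping) 0-based start offsets of needle in haystack."""
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def map_fragment(sequence: str, models: TRNAModels) -> list[ParentMapping]:
    """Report every exact occurrence in every mature and precursor context.

    A precursor occurrence entirely inside the mature body is suppressed: the
    identical region is already reported (or deliberately absent) in mature
    coordinates, and double-reporting it would double-count the fragment.
    Only precursor intervals touching the leader or trailer survive.
    """
    seq = normalize_sequence(sequence)
    if len(seq) < MIN_FRAGMENT_LEN:
        raise ValueError(f"fragment shorter than {MIN_FRAGMENT_LEN} nt")
    mappings: list[ParentMapping] = []
    for gene_id, mature in models.matures.items():
        for off in _occurrences(seq, mature.sequence):
            mappings.append(
                ParentMapping(gene_id, "mature", off + 1, off + len(seq))
            )
    for gene_id, prec in models.precursors.items():
        body_start = prec.leader_len + 1  # 1-based first body position
        body_end = prec.leader_len + prec.body_len
        for off in _occurrences(seq, prec.sequence):
            s, e = off + 1, off + len(seq)
            if s >= body_start and e <= body_end:
                continue  # shadowed by the mature context
            mappings.append(ParentMapping(gene_id, "precursor", s, e))
    return mappings


def _classify_one(m: ParentMapping, models: TRNAModels) -> str:
    if m.context == "mature":
        n = len(models.matures[m.gene_id])
        if m.start == 1 and m.end == n:
            return "unclassified"  # full-length mature tRNA, not a fragment
        if m.start == 1:
            return "tRF-5"
        if m.end == n:
            return "tRF-3"
        return "i-tRF"
    prec = models.precursors[m.gene_id]
    trailer_start = prec.leader_len + prec.body_len + 1
    if m.start >= trailer_start:
        return "tRF-1"
    if m.start <= prec.leader_len:
        return "5'U-tRF"
    # spans the mature/trailer junction: conservative, logged
    logger.info("%s: precursor interval [%d,%d] spans the body/trailer junction",
                m.gene_id, m.start, m.end)
    return "unclassified"


def classify_fragment(
    mappings: list[ParentMapping], models: TRNAModels
) -> tuple[str, ParentMapping]:
    """Classify from parent mappings; returns (type, winning mapping).

    Multi-parent conflicts resolve by tRF-3 > tRF-5 > i-tRF > tRF-1 > 5'U-tRF;
    the winning mapping's context also determines the cleavage loop.
    """
    if not mappings:
        raise UnmappableFragment("fragment has no parent mapping")
    best = min(
        ((TYPE_PRIORITY[_classify_one(m, models)], i, m) for i, m in enumerate(mappings)),
    )
    _, _, winner = best
    return _classify_one(winner, models), winner


def annotate_cleavage_loop(
    interval: tuple[int, int], mature: MatureTRNA, frag_type: str
) -> str:
    """Label the cleavage boundary with the cloverleaf loop containing it.

    The informative boundary is the 3' end for tRF-5 and the 5' end for
    tRF-3; for i-tRF both ends are checked, 5' first.
    """
    if frag_type not in ("tRF-5", "tRF-3", "i-tRF"):
        return "none"
    start, end = interval
    if frag_type == "tRF-5":
        boundaries = [end]
    elif frag_type == "tRF-3":
        boundaries = [start]
    else:
        boundaries = [start, end]
    for pos in boundaries:
        for name in ("d_loop", "anticodon_loop", "t_loop"):
            if name in mature.landmarks:
                s, e = mature.landmarks[name]
                if s <= pos <= e:
                    return LOOP_LABELS[name]
    return "none"


def classify_catalog(records: list[FragmentRecord], models: TRNAModels) -> list[FragmentRecord]:
    """Map and classify every record in place; unmappable ones stay unclassified."""
    for rec in records:
        rec.parents = map_fragment(rec.sequence, models)
        if not rec.parents:
            rec.type = "unclassified"
            rec.cleavage_loop = "none"
            continue
        rec.type, winner = classify_fragment(rec.parents, models)
        if winner.context == "mature":
            rec.cleavage_loop = annotate_cleavage_loop(
                (winner.start, winner.end), models.matures[winner.gene_id], rec.type
            )
        else:
            rec.cleavage_loop = "none"
        rec.chromosomes = {models.chromosome_of(m.gene_id) for m in rec.parents}
        if rec.declared_type and rec.declared_type != rec.type:
            logger.warning(
                "%s: declared type %s disagrees with computed type %s",
                rec.fragment_id, rec.declared_type, rec.type,
            )
    return records


def summarize_catalog(catalog: list[FragmentRecord]) -> dict[str, pd.Series]:
    """Proportions by type, cleavage loop, and chromosome.

    Multi-chromosome fragments count once per chromosome (the chromosome
    partition is over fragment-chromosome pairs); type/loop partitions are
    over fragments, so each sums to 1.
    """
    if not catalog:
        warnings.warn("empty catalog: summary is empty")
        return {"by_type": pd.Series(dtype=float),
                "by_loop": pd.Series(dtype=float),
                "by_chromosome": pd.Series(dtype=float)}
    types = pd.Series([r.type for r in catalog])
    loops = pd.Series([r.cleavage_loop for r in catalog])
    chroms = pd.Series([c for r in catalog for c in sorted(r.chromosomes)])
    out = {
        "by_type": types.value_counts(normalize=True).sort_index(),
        "by_loop": loops.value_counts(normalize=True).sort_index(),
    }
    out["by_chromosome"] = (
        chroms.value_counts(normalize=True).sort_index()
        if not chroms.empty
        else pd.Series(dtype=float)
    )
    return out


def load_fragment_table(path) -> list[FragmentRecord]:
    """Read a TSV catalog (fragment_id, sequence[, type]) of known fragments.

    Sequences are uppercased with U->T; rows with non-nucleotide characters
    are rejected with a message; duplicate sequences under distinct ids are
    kept and flagged.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"fragment_id", "sequence"} <= set(df.columns):
        raise ValueError("fragment table needs columns fragment_id, sequence")
    records: list[FragmentRecord] = []
    seen: dict[str, str] = {}
    for _, row in df.iterrows():
        seq = normalize_sequence(str(row["sequence"]))
        if set(seq) - set("ACGTN"):
            logger.error("%s: rejected, non-nucleotide characters in %r",
                         row["fragment_id"], row["sequence"])
            continue
        if not (MIN_FRAGMENT_LEN <= len(seq) <= MAX_FRAGMENT_LEN):
            logger.error("%s: rejected, length %d outside [%d,%d]",
                         row["fragment_id"], len(seq), MIN_FRAGMENT_LEN, MAX_FRAGMENT_LEN)
            continue
        if seq in seen:
            logger.warning("%s: duplicate sequence of %s (kept)",
                           row["fragment_id"], seen[seq])
        else:
            seen[seq] = str(row["fragment_id"])
        records.append(
            FragmentRecord(
                fragment_id=str(row["fragment_id"]),
                sequence=seq,
                declared_type=str(row["type"]) if "type" in df.columns and pd.notna(row.get("type")) else None,
            )
        )
    return records


def write_catalog(catalog: list[FragmentRecord], path) -> None:
    rows = []
    for r in catalog:
        rows.append({
            "fragment_id": r.fragment_id,
            "sequence": r.sequence,
            "type": r.type,
            "cleavage_loop": r.cleavage_loop,
            "parents": ";".join(
                f"{m.gene_id}:{m.context}:{m.start}-{m.end}" for m in r.parents
            ),
            "chromosomes": ",".join(sorted(r.chromosomes)),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
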