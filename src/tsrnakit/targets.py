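"""tsRNA -> 3'UTR target-site prediction.

tsRNAs can load into Argonaute and repress mRNAs through 3'UTR sites much
like microRNAs, so candidate sites are nucleated by the seed: fragment
positions 2-8 (5' end) must pair Watson-Crick with a UTR 7-mer.  Each seed
site is then extended to a gapless duplex over the fragment's full length
and scored with transparent integer pair weights:

    G:C = +3    A:T = +2    G:T wobble = +1    mismatch = -1

Wobble pairs are tolerated outside the seed only; any non-Watson-Crick seed
pair drops the hit.  The pairing diagram uses '|' (Watson-Crick), ':'
(wobble) and '.' (mismatch) per paired position.  UTRs are handled in DNA
alphabet (U->T) on the mRNA sense strand.  This is a deliberately simple,
fully testable stand-in for thermodynamic duplex predictors; the interface
leaves room for a free-energy backend.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "DuplexHit",
    "find_seed_sites",
    "score_duplex",
    "scan_utr",
    "rank_targets",
    "edges_to_network_json",
]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

PAIR_WEIGHTS = {
    frozenset(("G", "C")): 3,
    frozenset(("A", "T")): 2,
    frozenset(("G", "T")): 1,  # wobble
}

SEED_START, SEED_END = 2, 8  # fragment positions, 1-based, inclusive


def _revcomp(seq: str) -> str:
    return "".join(_COMP.get(b, "N") for b in reversed(seq))


def _norm(seq: str) -> str:
    return seq.strip().upper().replace("U", "T")


@dataclass(frozen=True)
class DuplexHit:
    fragment_id: str
    target_id: str
    site_start: int  # 1-based closed interval on the UTR
    site_end: int
    score: int
    pairing: str
    seed_matched: bool


def find_seed_sites(fragment_seq: str, utr: str) -> list[int]:
    """1-based UTR start positions whose 7-mer reverse-complements the seed."""
    frag = _norm(fragment_seq)
    utr = _norm(utr)
    if len(utr) < 7:
        return []
    if len(frag) < SEED_END:
        raise ValueError("fragment shorter than the seed span")
    target = _revcomp(frag[SEED_START - 1 : SEED_END])
    out, i = [], utr.find(target)
    while i != -1:
        out.append(i + 1)
        i = utr.find(target, i + 1)
    return out


def _pair_char(a: str, b: str) -> tuple[int, str]:
    key = frozenset((a, b))
    if key == frozenset(("G", "C")) or key == frozenset(("A", "T")):
        return PAIR_WEIGHTS[key], "|"
    if key == frozenset(("G", "T")):
        return 1, ":"
    return -1, "."


def _score_site(frag: str, utr: str, seed_site: int) -> tuple[int, str, tuple[int, int], bool]:
    """Score the gapless duplex anchored at a seed site.

    Fragment position i pairs UTR position seed_site + SEED_END - i (the
    fragment runs 3'->5' along the UTR); positions falling off either UTR
    end stay unpaired and contribute 0.
    """
    m = len(frag)
    score = 0
    chars = []
    seed_ok = True
    lo, hi = None, None
    for i in range(1, m + 1):
        j = seed_site + SEED_END - i
        if j < 1 or j > len(utr):
            continue
        w, c = _pair_char(frag[i - 1], utr[j - 1])
        in_seed = SEED_START <= i <= SEED_END
        if in_seed and c != "|":
            seed_ok = False
        score += w
        chars.append((j, c))
        lo = j if lo is None else min(lo, j)
        hi = j if hi is None else max(hi, j)
    chars.sort()
    return score, "".join(c for _, c in chars), (lo, hi), seed_ok


def score_duplex(fragment_seq: str, utr_window: str) -> DuplexHit | None:
    """Score a fragment against an extracted UTR window.

    The fragment is laid 3'->5' against the window 5'->3' with its 5' end at
    the window's 3' end (the layout ``scan_utr`` extracts).  Returns None
    when the hit is dropped for a non-Watson-Crick seed pair.
    """
    frag = _norm(fragment_seq)
    window = _norm(utr_window)
    if len(window) < SEED_END:
        raise ValueError("window shorter than the seed span")
    # place the seed site so fragment position 1 pairs the window 3' end
    seed_site = len(window) - SEED_END + 1
    score, pairing, span, seed_ok = _score_site(frag, window, seed_site)
    if not seed_ok:
        return None
    return DuplexHit("", "", span[0], span[1], score, pairing, True)


def scan_utr(
    fragment_seq: str, utr: str, fragment_id: str = "", target_id: str = ""
) -> list[DuplexHit]:
    """All seed-nucleated duplex hits of a fragment in one UTR, by position."""
    frag = _norm(fragment_seq)
    utr = _norm(utr)
    hits = []
    for site in find_seed_sites(frag, utr):
        score, pairing, (lo, hi), seed_ok = _score_site(frag, utr, site)
        if not seed_ok:
            continue
        hits.append(DuplexHit(fragment_id, target_id, lo, hi, score, pairing, True))
    return hits


def rank_targets(
    fragments: dict[str, str], utrs: dict[str, str], top_n: int = 50
) -> pd.DataFrame:
    """Best-site score per (fragment, UTR); top_n edges per fragment.

    Ties in score break lexicographically by target id, making the edge
    table deterministic.  Columns: fragment_id, target_id, score,
    site_start, site_end, pairing.
    """
    rows = []
    for fid, fseq in fragments.items():
        best: list[DuplexHit] = []
        for tid in sorted(utrs):
            hits = scan_utr(fseq, utrs[tid], fid, tid)
            if hits:
                best.append(max(hits, key=lambda h: (h.score, -h.site_start)))
        best.sort(key=lambda h: (-h.score, h.target_id))
        for h in best[:top_n]:
            rows.append({
                "fragment_id": h.fragment_id, "target_id": h.target_id,
                "score": h.score, "site_start": h.site_start,
                "site_end": h.site_end, "pairing": h.pairing,
            })
    return pd.DataFrame(
        rows, columns=["fragment_id", "target_id", "score",
                       "site_start", "site_end", "pairing"],
    )


def edges_to_network_json(edges: pd.DataFrame) -> dict:
    """Node/edge export for network tools (Cytoscape-style JSON)."""
    nodes = [{"id": f, "kind": "tsRNA"} for f in edges["fragment_id"].unique()]
    nodes += [{"id": t, "kind": "target"} for t in edges["target_id"].unique()]
    links = [
        {"source": r.fragment_id, "target": r.target_id, "score": int(r.score)}
        for r in edges.itertuples()
    ]
    return {"nodes": nodes, "edges": links}
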