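"""Fixed-string promoter motif scanning.

Exact-match scanning of short DNA words (e.g. the E-box CAGCTG enriched
in H4R3me2s-bound promoter regions) on both strands, with palindrome
deduplication: a motif equal to its own reverse complement matches
identically on both strands and is reported once, on '+'.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "PromoterSeq",
    "MotifHit",
    "scan_fixed_motif",
    "count_motif_per_gene",
]

_DNA = set("ACGT")
_DNA_N = set("ACGTN")


@dataclass(frozen=True)
class PromoterSeq:
    """A promoter sequence over {A,C,G,T,N}, uppercase-normalized."""

    seq_id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        bad = set(self.sequence) - _DNA_N
        if bad:
            raise ValueError(f"{self.seq_id}: invalid characters {sorted(bad)}")


@dataclass(frozen=True)
class MotifHit:
    """One exact motif occurrence: 0-based offset on the given strand."""

    seq_id: str
    offset: int
    strand: str


def _check_motif(motif: str) -> str:
    motif = motif.upper()
    if not motif or set(motif) - _DNA:
        raise ValueError("motif must be a non-empty string over ACGT")
    return motif


def scan_fixed_motif(seq: PromoterSeq | str, motif: str) -> list[MotifHit]:
    """All exact occurrences of ``motif`` and its reverse complement.

    Overlapping matches are all reported (step-1 sliding window).
    Positions containing N never match. For a palindromic motif each
    matching position is reported once, with strand '+'. Offsets are
    0-based starts on the forward sequence for both strands.
    """
    if isinstance(seq, str):
        seq = PromoterSeq("seq", seq)
    motif = _check_motif(motif)
    rc = str(Seq(motif).reverse_complement())
    s = seq.sequence
    k = len(motif)

    hits = []
    for i in range(len(s) - k + 1):
        window = s[i : i + k]
        if window == motif:
            hits.append(MotifHit(seq.seq_id, i, "+"))
        elif window == rc:  # elif: palindrome (rc == motif) counted once
            hits.append(MotifHit(seq.seq_id, i, "-"))
    return hits


def count_motif_per_gene(
    records: list[tuple[str, str]] | list[PromoterSeq], motif: str
) -> pd.DataFrame:
    """Per-sequence motif-hit summary table.

    ``records`` are (seq_id, sequence) pairs (as read from FASTA) or
    :class:`PromoterSeq` objects. Returns one row per record, in input
    order, with columns ``seq_id``, ``n_hits``, ``offsets``
    (comma-separated 0-based starts). Duplicate sequence IDs raise.
    """
    proms = [
        r if isinstance(r, PromoterSeq) else PromoterSeq(r[0], r[1]) for r in records
    ]
    ids = [p.seq_id for p in proms]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence IDs in input")
    rows = []
    for p in proms:
        hits = scan_fixed_motif(p, motif)
        rows.append(
            dict(
                seq_id=p.seq_id,
                n_hits=len(hits),
                offsets=",".join(str(h.offset) for h in hits),
            )
        )
    return pd.DataFrame(rows, columns=["seq_id", "n_hits", "offsets"])
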