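"""Quick-match stage: exact seed scanning by k-mer lookup.

A candidate target site is anchored by a *seed*: a run of at least ``b``
consecutive Watson-Crick base pairs (A:U or G:C; no G:U wobble here)
between the miRNA and the target read antiparallel.  Equivalently, a run
where the reverse complement of the miRNA matches the target exactly.
The scan indexes every length-``b`` window of the target and extends each
lookup hit to a maximal run, so it is exhaustive: every maximal run of
length >= b is reported exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ParameterError
from .sequence_io import MiRNARecord, NucSequence, reverse_complement

MIN_SEED = 4


@dataclass(frozen=True, order=True)
class SeedMatch:
    """A maximal run of consecutive WC pairs between miRNA and target.

    ``target_start``/``target_end`` are 0-based half-open on the scanned
    target strand; ``mirna_start``/``mirna_end`` index the miRNA 5'->3'.
    Antiparallel pairing means the miRNA 3' side faces the target 5' side:
    miRNA position ``mirna_start + k`` pairs target ``target_end - 1 - k``.
    """

    target_id: str
    target_start: int
    target_end: int
    mirna_start: int
    mirna_end: int

    @property
    def length(self) -> int:
        return self.target_end - self.target_start

    def __post_init__(self) -> None:
        if self.target_end - self.target_start != self.mirna_end - self.mirna_start:
            raise ValueError("seed run must span equal lengths on both molecules")
        if self.length < 1:
            raise ValueError("empty seed run")


def build_match_index(target: NucSequence, b: int) -> dict[str, list[int]]:
    """Map every length-``b`` substring of the target to its start positions.

    Windows containing N are excluded: N never pairs, so no seed can cross
    one.  Position lists are sorted (they are produced left to right).
    """
    if b < MIN_SEED:
        raise ParameterError(f"seed length b={b} is below the minimum of {MIN_SEED}")
    seq = target.residues
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - b + 1):
        kmer = seq[i : i + b]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    return index


def find_seed_matches(
    mirna: MiRNARecord,
    target: NucSequence,
    b: int,
    index: dict[str, list[int]] | None = None,
) -> list[SeedMatch]:
    """All maximal runs of >= b consecutive WC pairs, sorted and deduplicated.

    The reverse complement of the miRNA is slid over the index; each exact
    k-mer hit is extended in both directions to maximality.  Hits that
    extend to the same (diagonal, extent) are reported once.  A prebuilt
    ``index`` for (target, b) may be passed to amortize scanning many
    miRNAs against one target.
    """
    if b < MIN_SEED:
        raise ParameterError(f"seed length b={b} is below the minimum of {MIN_SEED}")
    query = reverse_complement(mirna.seq.residues)  # match in query == WC pair
    n = len(query)
    if n < b or len(target) < b:
        return []
    if index is None:
        index = build_match_index(target, b)
    tseq = target.residues
    tlen = len(tseq)
    seen: set[tuple[int, int]] = set()
    out: list[SeedMatch] = []
    for q in range(n - b + 1):
        kmer = query[q : q + b]
        if "N" in kmer:
            continue
        for t in index.get(kmer, ()):
            # extend the hit to a maximal equal run on diagonal t - q
            qs, ts = q, t
            while qs > 0 and ts > 0 and query[qs - 1] == tseq[ts - 1] and query[qs - 1] != "N":
                qs -= 1
                ts -= 1
            qe, te = q + b, t + b
            while qe < n and te < tlen and query[qe] == tseq[te] and query[qe] != "N":
                qe += 1
                te += 1
            key = (t - q, ts)
            if key in seen:
                continue
            seen.add(key)
            # query coordinates back to miRNA 5'->3' coordinates
            out.append(
                SeedMatch(
                    target_id=target.id,
                    target_start=ts,
                    target_end=te,
                    mirna_start=n - qe,
                    mirna_end=n - qs,
                )
            )
    out.sort(key=lambda m: (m.target_start, m.mirna_start, m.target_end))
    return out
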