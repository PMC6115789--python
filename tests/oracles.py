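"""Independent brute-force oracles used to validate the production engines.

These deliberately share nothing with the scanning/DP code paths they
check: the seed oracle is a naive per-diagonal walk, and the two energy
oracles enumerate *every* admissible structure and score it with the
re-scoring functions (the model's single energetic authority).
"""

from __future__ import annotations

import math

from mirtarp.energy import EnergyModel, pair_type, score_duplex, score_structure
from mirtarp.seed_match import SeedMatch
from mirtarp.sequence_io import MiRNARecord, NucSequence, reverse_complement

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}


def naive_seed_scan(mirna: MiRNARecord, target: NucSequence, b: int) -> list[SeedMatch]:
    """O(n*m) diagonal scan for maximal runs of >= b consecutive WC pairs.

    Walks every diagonal of the (reverse-complemented miRNA) x target
    grid and collects maximal equality runs.
    """
    query = reverse_complement(mirna.seq.residues)
    tseq = target.residues
    n, m = len(query), len(tseq)
    out = []
    for d in range(-(n - 1), m):  # diagonal: t - q == d
        q = max(0, -d)
        t = q + d
        run = 0
        while q <= n and t <= m:
            inside = q < n and t < m
            if inside and query[q] == tseq[t] and query[q] != "N":
                run += 1
            else:
                if run >= b:
                    qe, te = q, t
                    qs, ts = q - run, t - run
                    out.append(
                        SeedMatch(
                            target_id=target.id, target_start=ts, target_end=te,
                            mirna_start=n - qe, mirna_end=n - qs,
                        )
                    )
                run = 0
            q += 1
            t += 1
    out.sort(key=lambda s: (s.target_start, s.mirna_start, s.target_end))
    return out


def enumerate_duplex_mfe(mirna_seq: str, site_seq: str, model: EnergyModel) -> float:
    """Minimum over every admissible intermolecular pair chain, by exhaustion."""
    n, m = len(mirna_seq), len(site_seq)
    allowed = [
        (i, j)
        for i in range(n)
        for j in range(m)
        if pair_type(mirna_seq[i], site_seq[j]) >= 0
    ]
    best = math.inf

    def extend(chain: list[tuple[int, int]]) -> None:
        nonlocal best
        e = score_duplex(chain, mirna_seq, site_seq, model)
        if e < best:
            best = e
        i0, j0 = chain[-1]
        for (i, j) in allowed:
            if i > i0 and j < j0 and (i - i0 - 1) + (j0 - j - 1) <= model.max_loop:
                chain.append((i, j))
                extend(chain)
                chain.pop()

    for p in allowed:
        extend([p])
    return best


def enumerate_structures(seq: str, min_hairpin: int = 3):
    """Every non-crossing intramolecular structure with the hairpin minimum."""
    n = len(seq)

    memo: dict[tuple[int, int], list[tuple]] = {}

    def structs(i: int, j: int) -> list[tuple]:
        # all structures on the inclusive interval [i, j]
        if j - i < min_hairpin + 1:
            return [()]
        key = (i, j)
        if key in memo:
            return memo[key]
        out = list(structs(i, j - 1))  # j unpaired
        for k in range(i, j - min_hairpin):
            if pair_type(seq[k], seq[j]) < 0:
                continue
            for left in structs(i, k - 1) if k > i else [()]:
                for inner in structs(k + 1, j - 1):
                    out.append(left + inner + ((k, j),))
        memo[key] = out
        return out

    return structs(0, n - 1)


def enumerate_fold_mfe(seq: str, model: EnergyModel) -> float:
    """Minimum folding energy by exhaustive structure enumeration."""
    best = 0.0
    for s in enumerate_structures(seq, model.min_hairpin):
        if not s:
            continue
        e = score_structure(s, seq, model)
        if e < best:
            best = e
    return best
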