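"""Duplex assessment: minimum-free-energy miRNA-target hybridization.

Given a localized target window (produced by the seed scan), the engine
finds the lowest-energy *intermolecular* structure between the miRNA and
the window under the nearest-neighbor model: antiparallel, non-crossing
pairing with no intramolecular pairs and no multibranch loops — stacks,
bulges and internal loops only (the standard hybridization restriction).
This is the computation classically delegated to a duplex tool such as
RNAhybrid, reimplemented as an exact dynamic program with traceback.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._kernels import duplex_fill
from .energy import (
    EnergyModel, INF_CENTS, PAIR_TABLE, encode, load_energy_model,
    score_duplex_cents,
)
from .errors import ParameterError
from .sequence_io import MiRNARecord, NucSequence

MAX_WINDOW = 200


@dataclass(frozen=True)
class HybridDuplex:
    """An intermolecular miRNA-site structure with its free energy.

    ``pairs`` holds (miRNA position, target position) tuples, strictly
    increasing in the miRNA coordinate and strictly decreasing in the
    target coordinate (the strands are antiparallel); target positions are
    on the forward strand of the scanned sequence.  ``site_start`` /
    ``site_end`` delimit the duplex footprint on the target (half-open).
    The three alignment strings render the duplex for human eyes:
    miRNA 5'->3' on top, target 3'->5' underneath, ``|`` for Watson-Crick
    pairs and ``:`` for G:U wobbles.
    """

    mirna_id: str
    target_id: str
    site_start: int
    site_end: int
    pairs: tuple[tuple[int, int], ...]
    mfe: float
    mirna_aln: str = ""
    pair_aln: str = ""
    target_aln: str = ""

    @property
    def is_empty(self) -> bool:
        return not self.pairs


def passes_energy_cutoff(duplex: HybridDuplex, e: float) -> bool:
    """True iff the duplex is at least as stable as the cutoff (mfe <= e)."""
    return duplex.mfe <= e


def _render_alignment(pairs, mirna_seq: str, site_seq: str) -> tuple[str, str, str]:
    top: list[str] = []
    mid: list[str] = []
    bot: list[str] = []
    for k, (i, j) in enumerate(pairs):
        if k > 0:
            i0, j0 = pairs[k - 1]
            gap_m = mirna_seq[i0 + 1 : i]          # unpaired miRNA bases, 5'->3'
            gap_t = site_seq[j + 1 : j0][::-1]      # unpaired target bases, 3'->5'
            width = max(len(gap_m), len(gap_t))
            top.append(gap_m.ljust(width, "-"))
            bot.append(gap_t.ljust(width, "-"))
            mid.append(" " * width)
        top.append(mirna_seq[i])
        bot.append(site_seq[j])
        mid.append(":" if (mirna_seq[i], site_seq[j]) in (("G", "U"), ("U", "G")) else "|")
    return "".join(top), "".join(mid), "".join(bot)


def hybridize(
    mirna: MiRNARecord,
    target: NucSequence,
    window: tuple[int, int],
    model: EnergyModel | None = None,
) -> HybridDuplex:
    """Minimum-free-energy hybrid of a miRNA with one target window.

    ``window`` is a 0-based half-open interval on the target (at most
    200 nt — the seed scan already localizes candidate sites).  Returns
    the optimal :class:`HybridDuplex`; if no base pair is possible the
    empty duplex with ``mfe = +inf`` is returned, which fails every
    energy cutoff.
    """
    if model is None:
        model = load_energy_model()
    ws, we = window
    if not (0 <= ws < we <= len(target)):
        raise ParameterError(f"window {window} outside target {target.id!r}")
    if we - ws > MAX_WINDOW:
        raise ParameterError(f"window of {we - ws} nt exceeds the {MAX_WINDOW} nt limit")

    mirna_seq = mirna.seq.residues
    site_seq = target.residues[ws:we]
    x = encode(mirna_seq)
    w = encode(site_seq)
    V, Bi, Bj, best, ei, ej = duplex_fill(
        x, w, PAIR_TABLE, model.stack.astype(np.int64), model.bulge.astype(np.int64),
        model.internal.astype(np.int64), model.au_end.astype(np.int64),
        model.duplex_init, model.ninio_per_nt, model.ninio_max, model.max_loop,
    )
    if best >= INF_CENTS:
        return HybridDuplex(
            mirna_id=mirna.id, target_id=target.id, site_start=ws, site_end=ws,
            pairs=(), mfe=math.inf,
        )
    # traceback along stored predecessors, 3' miRNA end inwards
    rev: list[tuple[int, int]] = []
    i, j = ei, ej
    while i >= 0:
        rev.append((i, j))
        i, j = int(Bi[i, j]), int(Bj[i, j])
    pairs = tuple(rev[::-1])
    assert score_duplex_cents(pairs, mirna_seq, site_seq, model) == best
    aln = _render_alignment(pairs, mirna_seq, site_seq)
    tpos = [j for (_, j) in pairs]
    return HybridDuplex(
        mirna_id=mirna.id,
        target_id=target.id,
        site_start=ws + min(tpos),
        site_end=ws + max(tpos) + 1,
        pairs=tuple((i, ws + j) for (i, j) in pairs),
        mfe=best / 100.0,
        mirna_aln=aln[0],
        pair_aln=aln[1],
        target_aln=aln[2],
    )
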