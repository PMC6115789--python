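"""Local-structure accessibility: minimum folding energy around a site.

A miRNA can only engage a target region that is not locked up in stable
intramolecular structure.  As supplementary evidence for each predicted
site, the window around it (site +/- flank) is folded with a Zuker-style
minimum-free-energy dynamic program over hairpins, stacks, bulges,
internal loops and linearly-scored multibranch loops.  The folding energy
and the unpaired fraction of the site in the MFE structure are *reported*,
never filtered on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import fold_fill
from .energy import (
    EnergyModel, INF_CENTS, PAIR_TABLE, encode, load_energy_model,
    score_structure_cents,
)
from .errors import ParameterError
from .sequence_io import NucSequence

MAX_FOLD_WINDOW = 300


@dataclass(frozen=True)
class FoldResult:
    """MFE structure of a target window; positions are absolute target coords."""

    target_id: str
    window_start: int
    window_end: int
    fold_mfe: float
    pair_map: tuple[tuple[int, int], ...]


def fold_local(
    target: NucSequence,
    site: tuple[int, int],
    flank: int,
    model: EnergyModel | None = None,
) -> FoldResult:
    """Fold the window site +/- flank (clipped to the sequence ends).

    The empty structure scores 0, so ``fold_mfe <= 0`` always; hairpin
    loops keep at least ``model.min_hairpin`` unpaired bases.  Among
    co-optimal structures the deterministic traceback prefers, in order:
    two-loop continuations (stacks first, then larger loops), hairpin
    closure, then multibranch with the smallest split point — so the
    reported pair map and unpaired fraction are reproducible.
    """
    if model is None:
        model = load_energy_model()
    if flank < 0:
        raise ParameterError("flank must be >= 0")
    ss, se = site
    if not (0 <= ss < se <= len(target)):
        raise ParameterError(f"site {site} outside target {target.id!r}")
    ws = max(0, ss - flank)
    we = min(len(target), se + flank)
    n = we - ws
    if n > MAX_FOLD_WINDOW:
        raise ParameterError(f"fold window of {n} nt exceeds the {MAX_FOLD_WINDOW} nt limit")

    s = encode(target.residues[ws:we])
    hairpin_ext = model.hairpin_table(max(n, model.max_loop))
    V, WM, W = fold_fill(
        s, PAIR_TABLE, model.stack.astype(np.int64), model.bulge.astype(np.int64),
        model.internal.astype(np.int64), hairpin_ext, model.au_end.astype(np.int64),
        model.ninio_per_nt, model.ninio_max, model.max_loop, model.min_hairpin,
        model.ml_offset, model.ml_branch, model.ml_unpaired,
    )
    mfe_cents = int(W[n])
    pairs = _traceback(s, V, WM, W, hairpin_ext, model)
    assert score_structure_cents(pairs, target.residues[ws:we], model) == mfe_cents
    return FoldResult(
        target_id=target.id,
        window_start=ws,
        window_end=we,
        fold_mfe=mfe_cents / 100.0,
        pair_map=tuple((ws + i, ws + j) for (i, j) in sorted(pairs)),
    )


def site_accessibility_report(fold: FoldResult, site: tuple[int, int]) -> tuple[float, float]:
    """(fraction of site positions unpaired in the MFE structure, fold MFE)."""
    ss, se = site
    if not (fold.window_start <= ss and se <= fold.window_end):
        raise ParameterError("fold window does not contain the site")
    paired = set()
    for (i, j) in fold.pair_map:
        paired.add(i)
        paired.add(j)
    n_site = se - ss
    unpaired = sum(1 for k in range(ss, se) if k not in paired)
    return unpaired / n_site, fold.fold_mfe


def _ptype(s, i, j):
    return int(PAIR_TABLE[s[i], s[j]])


def _traceback(s, V, WM, W, hairpin_ext, model: EnergyModel) -> list[tuple[int, int]]:
    n = len(s)
    pairs: list[tuple[int, int]] = []

    def trace_V(i: int, j: int) -> None:
        pairs.append((i, j))
        p = _ptype(s, i, j)
        target = int(V[i, j])
        span = j - i
        lmax1 = min(model.max_loop, span - 2)
        for l1 in range(lmax1 + 1):
            k = i + 1 + l1
            lmax2 = min(model.max_loop - l1, j - k - 1)
            for l2 in range(lmax2 + 1):
                l = j - 1 - l2
                if V[k, l] >= INF_CENTS:
                    continue
                p2 = _ptype(s, k, l)
                if int(V[k, l]) + model.two_loop_cents(p, p2, l1, l2) == target:
                    trace_V(k, l)
                    return
        if hairpin_ext[span - 1] + int(model.au_end[p]) == target:
            return
        for k in range(i + 2, j - 1):
            if WM[i + 1, k - 1] >= INF_CENTS or WM[k, j - 1] >= INF_CENTS:
                continue
            if model.ml_offset + int(model.au_end[p]) + int(WM[i + 1, k - 1]) + int(WM[k, j - 1]) == target:
                trace_WM(i + 1, k - 1)
                trace_WM(k, j - 1)
                return
        raise AssertionError(f"fold traceback failed at V[{i},{j}]")

    def trace_WM(i: int, j: int) -> None:
        target = int(WM[i, j])
        p = _ptype(s, i, j)
        if p >= 0 and V[i, j] < INF_CENTS:
            if int(V[i, j]) + model.ml_branch + int(model.au_end[p]) == target:
                trace_V(i, j)
                return
        if WM[i + 1, j] < INF_CENTS and int(WM[i + 1, j]) + model.ml_unpaired == target:
            trace_WM(i + 1, j)
            return
        if WM[i, j - 1] < INF_CENTS and int(WM[i, j - 1]) + model.ml_unpaired == target:
            trace_WM(i, j - 1)
            return
        for k in range(i + 1, j + 1):
            if WM[i, k - 1] >= INF_CENTS or WM[k, j] >= INF_CENTS:
                continue
            if int(WM[i, k - 1]) + int(WM[k, j]) == target:
                trace_WM(i, k - 1)
                trace_WM(k, j)
                return
        raise AssertionError(f"fold traceback failed at WM[{i},{j}]")

    pos = n
    while pos > 0:
        if int(W[pos]) == int(W[pos - 1]):
            pos -= 1
            continue
        j = pos - 1
        done = False
        for k in range(j + 1):
            if V[k, j] >= INF_CENTS:
                continue
            p = _ptype(s, k, j)
            if int(W[k]) + int(V[k, j]) + int(model.au_end[p]) == int(W[pos]):
                trace_V(k, j)
                pos = k
                done = True
                break
        if not done:  # pragma: no cover - guarded by DP construction
            raise AssertionError(f"fold traceback failed in exterior loop at {pos}")
    return pairs
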