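"""Nearest-neighbor thermodynamic model shared by the duplex and folding engines.

Free energies are Gibbs increments at 37 C in kcal/mol, loaded from a
versioned plain-text parameter file shipped with the package (see
``mirtarp/data/``).  Internally every energy is held as an integer number
of *centi*-kcal/mol (0.01 kcal/mol units), so dynamic programming,
traceback and the independent re-scoring functions use exact integer
arithmetic and agree bit-for-bit.

Model class
-----------
Allowed pairs are the Watson-Crick pairs plus G:U wobble.  A structure is
scored as a sum over loops:

* helix stacks (sequence-dependent 6x6 table),
* bulge loops (size-dependent initiation; a 1-nt bulge keeps the stack
  across it),
* internal loops (size-dependent initiation plus a capped asymmetry term),
* hairpin loops (folding only; size-dependent, log-extrapolated past the
  table),
* multibranch loops (folding only; linear offset/branch/unpaired model),

plus an intermolecular initiation term for duplexes and a penalty for
every helix end closed by an AU, UA, GU or UG pair.  Terminal mismatches,
dangling ends and coaxial stacking are deliberately not modeled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .errors import InvalidStructureError, ParameterError

INF_CENTS = 1 << 28  # sentinel "impossible" energy for integer DP

BASES = "ACGUN"
BASE_CODE = {b: i for i, b in enumerate(BASES)}

#: pair-type order used by every energy table
PAIR_TYPES = ("CG", "GC", "GU", "UG", "AU", "UA")
_PAIR_INDEX = {p: k for k, p in enumerate(PAIR_TYPES)}

# 5x5 base-code -> pair type (-1 = not pairable; N pairs nothing)
PAIR_TABLE = np.full((5, 5), -1, dtype=np.int8)
for _p, _k in _PAIR_INDEX.items():
    PAIR_TABLE[BASE_CODE[_p[0]], BASE_CODE[_p[1]]] = _k

DEFAULT_PARAMS = "turner2004-min"
_PARAM_FILES = {"turner2004-min": "turner2004_min_v1.tsv"}


def encode(seq: str) -> np.ndarray:
    """Encode an RNA string as base codes (A=0 C=1 G=2 U=3 N=4)."""
    return np.fromiter((BASE_CODE[c] for c in seq), dtype=np.int8, count=len(seq))


def pair_type(a: str, b: str) -> int:
    """Pair-type index of bases (a, b), or -1 if they cannot pair."""
    return int(PAIR_TABLE[BASE_CODE[a], BASE_CODE[b]])


@dataclass(frozen=True)
class EnergyModel:
    """A loaded nearest-neighbor parameter set (integer centi-kcal/mol).

    ``stack[p1, p2]`` scores the motif 5'-a c-3' / 3'-b d-5' where p1 is
    the pair a:b and p2 the pair c:d.  The loop tables are indexed by the
    number of unpaired nucleotides.
    """

    name: str
    stack: np.ndarray          # (6, 6) int32
    hairpin: np.ndarray        # (max_loop + 1,) int32; sizes < min_hairpin are INF
    bulge: np.ndarray          # (max_loop + 1,) int32
    internal: np.ndarray       # (max_loop + 1,) int32
    au_end: np.ndarray         # (6,) int32 penalty per closing pair type
    duplex_init: int
    ninio_per_nt: int
    ninio_max: int
    ml_offset: int
    ml_branch: int
    ml_unpaired: int
    lxc: float                 # centi-kcal log-extrapolation coefficient
    max_loop: int
    min_hairpin: int

    def hairpin_cents(self, size: int) -> int:
        if size < self.min_hairpin:
            return INF_CENTS
        if size <= self.max_loop:
            return int(self.hairpin[size])
        return int(self.hairpin[self.max_loop] + round(self.lxc * math.log(size / self.max_loop)))

    def hairpin_table(self, max_size: int) -> np.ndarray:
        """Hairpin initiation for sizes 0..max_size, extrapolated past the table."""
        return np.asarray([self.hairpin_cents(s) for s in range(max_size + 1)], dtype=np.int64)

    def two_loop_cents(self, p_outer: int, p_inner: int, l1: int, l2: int) -> int:
        """Energy of the loop joining two pairs separated by l1 and l2 unpaired nt.

        ``p_outer`` is the pair that comes first along the top (5'->3')
        strand; orientation matters only through the stack table.
        """
        if l1 < 0 or l2 < 0 or l1 + l2 > self.max_loop:
            raise InvalidStructureError(f"loop of size {l1}x{l2} outside the model class")
        if l1 == 0 and l2 == 0:
            return int(self.stack[p_outer, p_inner])
        if l1 == 0 or l2 == 0:
            size = l1 + l2
            e = int(self.bulge[size])
            if size == 1:
                e += int(self.stack[p_outer, p_inner])  # helix stacks across a 1-nt bulge
            else:
                e += int(self.au_end[p_outer]) + int(self.au_end[p_inner])
            return e
        e = int(self.internal[l1 + l2])
        e += min(self.ninio_max, abs(l1 - l2) * self.ninio_per_nt)
        e += int(self.au_end[p_outer]) + int(self.au_end[p_inner])
        return e


def _cents(x: str) -> int:
    return round(float(x) * 100)


def load_energy_model(name_or_path: str = DEFAULT_PARAMS) -> EnergyModel:
    """Load a parameter file by shipped id (e.g. ``turner2004-min``) or path."""
    if name_or_path in _PARAM_FILES:
        ref = resources.files("mirtarp.data") / _PARAM_FILES[name_or_path]
        text = ref.read_text()
        name = name_or_path
    else:
        p = Path(name_or_path)
        if not p.exists():
            raise ParameterError(
                f"unknown energy parameter set {name_or_path!r}; "
                f"shipped sets: {sorted(_PARAM_FILES)}"
            )
        text = p.read_text()
        name = p.stem

    stack = np.full((6, 6), INF_CENTS, dtype=np.int32)
    loops: dict[str, dict[int, int]] = {"hairpin": {}, "bulge": {}, "internal": {}}
    scalars: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        kind, key, *rest = line.split("\t")
        if kind == "stack":
            top, bottom = key, rest[0]
            p1 = _PAIR_INDEX[top[0] + bottom[0]]
            p2 = _PAIR_INDEX[top[1] + bottom[1]]
            stack[p1, p2] = _cents(rest[1])
        elif kind in loops:
            loops[kind][int(key)] = _cents(rest[0])
        else:
            scalars[f"{kind}.{key}"] = float(rest[0])

    max_loop = int(scalars.get("limit.max_loop", 30))
    min_hairpin = int(scalars.get("limit.min_hairpin", 3))

    def table(kind: str, first: int) -> np.ndarray:
        t = np.full(max_loop + 1, INF_CENTS, dtype=np.int32)
        for size, v in loops[kind].items():
            t[size] = v
        missing = [s for s in range(first, max_loop + 1) if t[s] >= INF_CENTS]
        if missing:
            raise ParameterError(f"{name}: missing {kind} sizes {missing}")
        return t

    if np.any(stack >= INF_CENTS):
        raise ParameterError(f"{name}: incomplete 6x6 stack table")

    au = _cents(str(scalars["penalty.terminal_au"]))
    au_end = np.asarray([0 if PAIR_TYPES[k] in ("CG", "GC") else au for k in range(6)],
                        dtype=np.int32)
    return EnergyModel(
        name=name,
        stack=stack,
        hairpin=table("hairpin", min_hairpin),
        bulge=table("bulge", 1),
        internal=table("internal", 2),
        au_end=au_end,
        duplex_init=_cents(str(scalars["init.duplex"])),
        ninio_per_nt=_cents(str(scalars["ninio.per_nt"])),
        ninio_max=_cents(str(scalars["ninio.max"])),
        ml_offset=_cents(str(scalars["multibranch.offset"])),
        ml_branch=_cents(str(scalars["multibranch.per_branch"])),
        ml_unpaired=_cents(str(scalars["multibranch.per_unpaired"])),
        lxc=float(scalars["extrapolation.lxc"]) * 100.0,
        max_loop=max_loop,
        min_hairpin=min_hairpin,
    )


# ---------------------------------------------------------------------------
# Re-scoring functions: the single energetic authority.  The DP engines are
# required (and tested) to reproduce these sums exactly.
# ---------------------------------------------------------------------------

def _duplex_pair_types(pairs, mirna_seq: str, site_seq: str) -> list[int]:
    n, m = len(mirna_seq), len(site_seq)
    types = []
    prev = None
    for (i, j) in pairs:
        if not (0 <= i < n and 0 <= j < m):
            raise InvalidStructureError(f"pair ({i},{j}) out of range")
        p = pair_type(mirna_seq[i], site_seq[j])
        if p < 0:
            raise InvalidStructureError(
                f"{mirna_seq[i]}:{site_seq[j]} at ({i},{j}) is not an allowed pair"
            )
        if prev is not None and not (i > prev[0] and j < prev[1]):
            raise InvalidStructureError("pairs must be antiparallel and non-crossing")
        prev = (i, j)
        types.append(p)
    return types


def score_duplex_cents(pairs, mirna_seq: str, site_seq: str, model: EnergyModel) -> int:
    pairs = list(pairs)
    if not pairs:
        return INF_CENTS
    types = _duplex_pair_types(pairs, mirna_seq, site_seq)
    total = model.duplex_init + int(model.au_end[types[0]]) + int(model.au_end[types[-1]])
    for k in range(1, len(pairs)):
        (i1, j1), (i2, j2) = pairs[k - 1], pairs[k]
        total += model.two_loop_cents(types[k - 1], types[k], i2 - i1 - 1, j1 - j2 - 1)
    return total


def score_duplex(pairs, mirna_seq: str, site_seq: str, model: EnergyModel) -> float:
    """Free energy (kcal/mol) of an explicit intermolecular structure.

    ``pairs`` is a list of (miRNA position, site position), strictly
    increasing in the first and strictly decreasing in the second
    coordinate.  The empty structure scores +inf by convention so that it
    can never pass an energy cutoff.
    """
    c = score_duplex_cents(pairs, mirna_seq, site_seq, model)
    return math.inf if c >= INF_CENTS else c / 100.0


def _children_map(pairs: list[tuple[int, int]], n: int):
    """Nesting tree of a non-crossing pair list; raises if crossing/overlapping."""
    used = set()
    for (i, j) in pairs:
        if not (0 <= i < j < n):
            raise InvalidStructureError(f"pair ({i},{j}) out of range")
        if i in used or j in used:
            raise InvalidStructureError("a position participates in two pairs")
        used.update((i, j))
    ordered = sorted(pairs)
    root: list[tuple[int, int]] = []
    children: dict[tuple[int, int], list[tuple[int, int]]] = {p: [] for p in ordered}
    stack: list[tuple[int, int]] = []
    for p in ordered:
        while stack and p[0] > stack[-1][1]:
            stack.pop()
        if stack:
            if p[1] > stack[-1][1]:
                raise InvalidStructureError(f"crossing pairs {stack[-1]} and {p}")
            children[stack[-1]].append(p)
        else:
            root.append(p)
        stack.append(p)
    return root, children


def score_structure_cents(pairs, seq: str, model: EnergyModel) -> int:
    pairs = [tuple(p) for p in pairs]
    if not pairs:
        return 0
    root, children = _children_map(pairs, len(seq))
    ptype = {}
    for (i, j) in pairs:
        p = pair_type(seq[i], seq[j])
        if p < 0:
            raise InvalidStructureError(f"{seq[i]}:{seq[j]} at ({i},{j}) is not an allowed pair")
        ptype[(i, j)] = p

    total = sum(int(model.au_end[ptype[p]]) for p in root)  # exterior loop
    for (i, j), kids in children.items():
        p = ptype[(i, j)]
        if not kids:
            total += model.hairpin_cents(j - i - 1) + int(model.au_end[p])
        elif len(kids) == 1:
            (k, l) = kids[0]
            total += model.two_loop_cents(p, ptype[(k, l)], k - i - 1, j - l - 1)
        else:
            unpaired = (j - i - 1) - sum(l2 - k2 + 1 for (k2, l2) in kids)
            total += (
                model.ml_offset
                + model.ml_branch * len(kids)
                + model.ml_unpaired * unpaired
                + int(model.au_end[p])
                + sum(int(model.au_end[ptype[c]]) for c in kids)
            )
    return total


def score_structure(pairs, seq: str, model: EnergyModel) -> float:
    """Free energy (kcal/mol) of an explicit intramolecular structure.

    The empty structure scores 0; hairpin loops must enclose at least
    ``model.min_hairpin`` unpaired nucleotides.
    """
    for (i, j) in pairs:
        kids_inside = any(i < a and b < j for (a, b) in pairs if (a, b) != (i, j))
        if not kids_inside and j - i - 1 < model.min_hairpin:
            raise InvalidStructureError(f"hairpin loop of pair ({i},{j}) below minimum size")
    return score_structure_cents(pairs, seq, model) / 100.0
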