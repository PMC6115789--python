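"""Synthetic fixture generation: miRNA/target sets with planted sites.

Every stage of the pipeline is testable without downloads: the generator
emits random mature-miRNA-like records (20-24 nt) and long random target
sequences into which reverse-complement binding sites are planted at
known, non-overlapping coordinates, together with a machine-readable
truth table.  Backgrounds are i.i.d. at a requested GC fraction; a
dinucleotide-preserving shuffle is provided separately as the negative
control of choice for sequence-composition effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ParameterError
from .sequence_io import MiRNARecord, NucSequence, reverse_complement, write_fasta

PLANT_TYPES = ("perfect", "mismatched", "bulged")
_ALPHABET = np.array(list("ACGU"))


@dataclass(frozen=True)
class PlantedSite:
    mirna_id: str
    target_id: str
    strand: str
    site_start: int
    site_end: int
    plant_type: str


@dataclass(frozen=True)
class FixtureTruth:
    planted: tuple[PlantedSite, ...]
    rng_seed: int
    params: dict = field(default_factory=dict, hash=False, compare=False)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_ALPHABET, size=length, p=p))


def _random_mirna(rng: np.random.Generator, gc: float, min_gc: float | None,
                  lo: int = 20, hi: int = 24) -> str:
    """A random mature-miRNA-like sequence, resampled until GC >= min_gc."""
    for _ in range(1000):
        length = int(rng.integers(lo, hi + 1))
        s = _random_seq(rng, length, gc)
        if min_gc is None or (s.count("G") + s.count("C")) / len(s) >= min_gc:
            return s
    raise ParameterError("could not sample a miRNA at the requested GC constraint")


def generate_fixture(
    n_mirnas: int,
    n_targets: int,
    target_len: int,
    n_planted: int,
    gc: float = 0.5,
    plant_types: tuple[str, ...] = ("perfect",),
    rng_seed: int = 0,
    min_mirna_gc: float | None = 0.4,
    out_dir=None,
) -> tuple[list[MiRNARecord], list[NucSequence], FixtureTruth]:
    """Generate a synthetic miRNA set, target set and planted-site truth.

    Planted sites are the reverse complement of a miRNA written into a
    target at a random position; sites on the same target never overlap.
    ``mismatched`` plants carry 1-3 point substitutions, ``bulged`` plants
    a 1-2 nt insertion on the target side.  The same ``rng_seed``
    reproduces byte-identical sequences and truth.  If ``out_dir`` is
    given, ``mirnas.fasta``, ``targets.fasta`` and ``truth.tsv`` are
    written there.
    """
    if not 0 < gc < 1:
        raise ParameterError("gc must be strictly between 0 and 1")
    if n_mirnas < 1 or n_targets < 1 or target_len < 1:
        raise ParameterError("counts and lengths must be positive")
    for pt in plant_types:
        if pt not in PLANT_TYPES:
            raise ParameterError(f"unknown plant type {pt!r}")
    rng = np.random.default_rng(rng_seed)

    mirnas = [
        MiRNARecord(
            id=f"mir-{k + 1:03d}",
            origin="host",
            seq=NucSequence(id=f"mir-{k + 1:03d}",
                            residues=_random_mirna(rng, gc, min_mirna_gc)),
        )
        for k in range(n_mirnas)
    ]
    backgrounds = [list(_random_seq(rng, target_len, gc)) for _ in range(n_targets)]
    occupied: list[list[tuple[int, int]]] = [[] for _ in range(n_targets)]
    planted: list[PlantedSite] = []

    for k in range(n_planted):
        mirna = mirnas[int(rng.integers(0, n_mirnas))]
        t = int(rng.integers(0, n_targets))
        plant_type = plant_types[int(rng.integers(0, len(plant_types)))]
        site = list(reverse_complement(mirna.seq.residues))
        if plant_type == "mismatched":
            n_sub = int(rng.integers(1, 4))
            for pos in rng.choice(len(site), size=min(n_sub, len(site)), replace=False):
                site[pos] = str(rng.choice([b for b in "ACGU" if b != site[pos]]))
        elif plant_type == "bulged":
            n_ins = int(rng.integers(1, 3))
            for _ in range(n_ins):
                pos = int(rng.integers(1, len(site)))
                site.insert(pos, str(rng.choice(_ALPHABET)))
        if len(site) > target_len:
            raise ParameterError("target_len too short for a planted site")
        placed = False
        for _ in range(200):
            start = int(rng.integers(0, target_len - len(site) + 1))
            end = start + len(site)
            if all(end <= s or start >= e for (s, e) in occupied[t]):
                occupied[t].append((start, end))
                backgrounds[t][start:end] = site
                planted.append(
                    PlantedSite(
                        mirna_id=mirna.id, target_id=f"target-{t + 1:03d}", strand="+",
                        site_start=start, site_end=end, plant_type=plant_type,
                    )
                )
                placed = True
                break
        if not placed:
            raise ParameterError(
                f"could not place planted site {k + 1}/{n_planted} without overlap"
            )

    targets = [
        NucSequence(id=f"target-{t + 1:03d}", residues="".join(backgrounds[t]))
        for t in range(n_targets)
    ]
    truth = FixtureTruth(
        planted=tuple(sorted(planted, key=lambda p: (p.target_id, p.site_start, p.mirna_id))),
        rng_seed=rng_seed,
        params=dict(
            n_mirnas=n_mirnas, n_targets=n_targets, target_len=target_len,
            n_planted=n_planted, gc=gc, plant_types=tuple(plant_types),
            min_mirna_gc=min_mirna_gc,
        ),
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta([m.seq for m in mirnas], out_dir / "mirnas.fasta")
        write_fasta(targets, out_dir / "targets.fasta")
        write_truth_tsv(truth, out_dir / "truth.tsv")
    return mirnas, targets, truth


TRUTH_COLUMNS = ("mirna_id", "target_id", "strand", "site_start", "site_end", "plant_type")


def write_truth_tsv(truth: FixtureTruth, path) -> None:
    with Path(path).open("w") as fh:
        fh.write(f"# rng_seed={truth.rng_seed}\n")
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for p in truth.planted:
            fh.write(
                f"{p.mirna_id}\t{p.target_id}\t{p.strand}\t{p.site_start}\t"
                f"{p.site_end}\t{p.plant_type}\n"
            )


def read_truth_tsv(path) -> FixtureTruth:
    planted = []
    rng_seed = 0
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                if "rng_seed=" in line:
                    rng_seed = int(line.split("rng_seed=")[1])
                continue
            if line.startswith("mirna_id") or not line:
                continue
            m, t, strand, s, e, pt = line.split("\t")
            planted.append(PlantedSite(m, t, strand, int(s), int(e), pt))
    return FixtureTruth(planted=tuple(planted), rng_seed=rng_seed)


def shuffle_preserving_dinucleotides(seq: NucSequence, rng_seed: int = 0) -> NucSequence:
    """Permutation of a sequence preserving its dinucleotide multiset.

    Altschul-Erikson Eulerian-walk shuffle: treat each dinucleotide as an
    edge of a multigraph over the four bases, sample a uniform arborescence
    toward the terminal base to fix each vertex's last exit, shuffle the
    remaining out-edges, and read off the walk.  Mononucleotide counts are
    preserved automatically.
    """
    s = seq.residues
    if len(s) < 2:
        return seq
    rng = np.random.default_rng(rng_seed)
    vertices = sorted(set(s))
    edges: dict[str, list[str]] = {v: [] for v in vertices}
    for a, b in zip(s, s[1:]):
        edges[a].append(b)
    last = s[-1]

    for _ in range(5000):
        # pick a candidate last-exit edge for every vertex except the terminal
        last_exit: dict[str, str] = {}
        ok = True
        for v in vertices:
            if v == last or not edges[v]:
                continue
            last_exit[v] = edges[v][int(rng.integers(0, len(edges[v])))]
        # the chosen exits must lead every vertex (that has edges) to `last`
        for v in last_exit:
            seen = set()
            u = v
            while u != last and u in last_exit and u not in seen:
                seen.add(u)
                u = last_exit[u]
            if u != last:
                ok = False
                break
        if not ok:
            continue
        walk_edges: dict[str, list[str]] = {}
        for v in vertices:
            rest = list(edges[v])
            if v in last_exit:
                rest.remove(last_exit[v])
            rng.shuffle(rest)
            if v in last_exit:
                rest.append(last_exit[v])
            walk_edges[v] = rest
        out = [s[0]]
        u = s[0]
        ptr = {v: 0 for v in vertices}
        for _ in range(len(s) - 1):
            nxt = walk_edges[u][ptr[u]]
            ptr[u] += 1
            out.append(nxt)
            u = nxt
        return NucSequence(id=seq.id, residues="".join(out), description=seq.description)
    raise RuntimeError("dinucleotide shuffle failed to find an Eulerian arrangement")
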