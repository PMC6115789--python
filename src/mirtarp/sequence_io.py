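"""FASTA input/output, alphabet normalization and coordinate primitives.

All sequences are held as uppercase RNA (``A C G U N``), 5'->3'.  DNA input
is accepted and transcribed on read (``T`` -> ``U``).  Coordinates are
0-based half-open on the forward strand everywhere inside the package; the
GFF3 writer converts to 1-based inclusive at the boundary.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, TYPE_CHECKING

from Bio import SeqIO

from .errors import FastaFormatError

if TYPE_CHECKING:  # pragma: no cover
    from .pipeline import TargetSite

logger = logging.getLogger(__name__)

_VALID = set("ACGUN")
_ACCEPTED_RAW = set("ACGUNT")
_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


def normalize_residues(raw: str) -> str:
    """Uppercase a raw nucleotide string and transcribe T to U.

    Raises ``ValueError`` if any character falls outside the accepted
    alphabet (``ACGTUN``, either case) — callers decide whether that means
    dropping a record or aborting.
    """
    s = raw.upper().replace("T", "U")
    bad = set(s) - _VALID
    if bad:
        raise ValueError(f"invalid nucleotide characters: {sorted(bad)}")
    if not s:
        raise ValueError("empty sequence")
    return s


@dataclass(frozen=True)
class NucSequence:
    """A named nucleotide sequence in the normalized RNA alphabet."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.residues) - _VALID
        if bad:
            raise ValueError(f"{self.id}: non-normalized characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    @classmethod
    def from_raw(cls, id: str, raw: str, description: str = "") -> "NucSequence":
        return cls(id=id, residues=normalize_residues(raw), description=description)

    def gc_fraction(self) -> float:
        n = len(self.residues)
        return (self.residues.count("G") + self.residues.count("C")) / n


@dataclass(frozen=True)
class MiRNARecord:
    """A mature miRNA with an explicit origin (host or virus).

    The origin tag records which prediction direction a record belongs to
    (host miRNA against viral targets, or viral miRNA against host
    transcripts); it is bookkeeping only and never alters the algorithm.
    """

    id: str
    origin: str  # "host" | "virus"
    seq: NucSequence

    def __post_init__(self) -> None:
        if self.origin not in ("host", "virus"):
            raise ValueError(f"{self.id}: origin must be 'host' or 'virus'")
        n = len(self.seq)
        if n < 10:
            raise ValueError(f"{self.id}: {n} nt is too short for a mature miRNA")
        if not 15 <= n <= 30:
            logger.warning("%s: unusual mature-miRNA length %d nt", self.id, n)

    def __len__(self) -> int:
        return len(self.seq)


def reverse_complement(seq):
    """RNA reverse complement (A<->U, G<->C, N<->N).

    Accepts either a plain string or a :class:`NucSequence`; returns the
    same type.  The operation is an involution.
    """
    if isinstance(seq, NucSequence):
        return NucSequence(
            id=seq.id, residues=reverse_complement(seq.residues), description=seq.description
        )
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path) -> list[NucSequence]:
    """Read a multi-FASTA file into normalized :class:`NucSequence` records.

    Records whose sequence contains characters outside the accepted
    alphabet are dropped with a logged warning rather than silently masked.
    Duplicate ids get a deterministic ``_2``, ``_3`` ... suffix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records: list[NucSequence] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq)
        bad = set(raw.upper()) - _ACCEPTED_RAW
        if bad or not raw:
            logger.warning(
                "%s: dropping record %r (invalid characters %s)",
                path.name, rec.id, sorted(bad) if bad else "empty",
            )
            continue
        rid = rec.id
        if rid in seen:
            seen[rid] += 1
            new_id = f"{rid}_{seen[rid]}"
            logger.warning("%s: duplicate id %r renamed to %r", path.name, rid, new_id)
            rid = new_id
        else:
            seen[rid] = 1
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(NucSequence.from_raw(rid, raw, desc))
    if not records:
        raise FastaFormatError(f"no parseable FASTA records in {path}")
    return records


def read_mirna_fasta(path, origin: str) -> list[MiRNARecord]:
    """Read mature miRNAs, tagging every record with the given origin."""
    return [MiRNARecord(id=s.id, origin=origin, seq=s) for s in read_fasta(path)]


def write_fasta(records: Iterable[NucSequence], path, width: int = 70) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


SITES_TSV_COLUMNS = (
    "mirna_id", "mirna_origin", "target_id", "strand", "site_start", "site_end",
    "seed_length", "duplex_mfe_kcal_mol", "local_fold_mfe_kcal_mol",
    "mirna_aln", "pair_aln", "target_aln",
)


def _fmt_energy(x) -> str:
    if x is None or (isinstance(x, float) and math.isinf(x)):
        return "NA"
    return f"{x:.2f}"


def write_sites_tsv(sites: Sequence["TargetSite"], path) -> None:
    """Serialize predicted sites, one row each, sorted and 2-decimal energies.

    Rows are ordered by (target_id, site_start, mirna_id) so repeated runs
    on identical inputs are byte-identical.
    """
    path = Path(path)
    ordered = sorted(sites, key=lambda s: (s.target_id, s.site_start, s.mirna_id, s.strand))
    with path.open("w") as fh:
        fh.write("\t".join(SITES_TSV_COLUMNS) + "\n")
        for s in ordered:
            fh.write(
                "\t".join(
                    (
                        s.mirna_id, s.mirna_origin, s.target_id, s.strand,
                        str(s.site_start), str(s.site_end), str(s.seed_length),
                        _fmt_energy(s.duplex_mfe), _fmt_energy(s.local_fold_mfe),
                        s.mirna_aln, s.pair_aln, s.target_aln,
                    )
                )
                + "\n"
            )


def read_sites_tsv(path) -> list[dict]:
    """Parse a sites TSV back into dictionaries (round-trip helper)."""
    path = Path(path)
    rows: list[dict] = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != SITES_TSV_COLUMNS:
            raise FastaFormatError(f"unexpected sites TSV header in {path}")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            row = dict(zip(header, parts))
            row["site_start"] = int(row["site_start"])
            row["site_end"] = int(row["site_end"])
            row["seed_length"] = int(row["seed_length"])
            row["duplex_mfe_kcal_mol"] = float(row["duplex_mfe_kcal_mol"])
            lf = row["local_fold_mfe_kcal_mol"]
            row["local_fold_mfe_kcal_mol"] = None if lf == "NA" else float(lf)
            rows.append(row)
    return rows


def write_gff3(sites: Sequence["TargetSite"], path, source: str = "mirtarp") -> None:
    """GFF3 export: 1-based inclusive coordinates, score = duplex MFE."""
    path = Path(path)
    ordered = sorted(sites, key=lambda s: (s.target_id, s.site_start, s.mirna_id, s.strand))
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for k, s in enumerate(ordered, start=1):
            attrs = [
                f"ID=site{k}",
                f"mirna_id={s.mirna_id}",
                f"mirna_origin={s.mirna_origin}",
                f"duplex_mfe={_fmt_energy(s.duplex_mfe)}",
                f"local_fold_mfe={_fmt_energy(s.local_fold_mfe)}",
            ]
            fh.write(
                "\t".join(
                    (
                        s.target_id, source, "miRNA_target_site",
                        str(s.site_start + 1), str(s.site_end), _fmt_energy(s.duplex_mfe),
                        s.strand, ".", ";".join(attrs),
                    )
                )
                + "\n"
            )
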