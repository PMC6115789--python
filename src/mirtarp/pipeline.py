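"""End-to-end prediction: seed scan -> window -> duplex MFE -> filter -> report.

The same machinery serves both prediction directions (host miRNAs against
viral genomes, viral miRNAs against human transcripts); only the origin
tag carried on each miRNA record differs.  For every miRNA x target
(x strand, optionally), seed matches are extended by a flank into candidate
windows, overlapping windows are merged, each window is hybridized once,
sites at least as stable as the ``-e`` cutoff are kept, and local folding
accessibility is annotated unless disabled.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path

from .accessibility import MAX_FOLD_WINDOW, fold_local, site_accessibility_report
from .duplex import MAX_WINDOW, hybridize, passes_energy_cutoff
from .energy import EnergyModel, load_energy_model
from .errors import MirtarpError, ParameterError
from .seed_match import MIN_SEED, build_match_index, find_seed_matches
from .sequence_io import (
    MiRNARecord, NucSequence, read_fasta, read_mirna_fasta, reverse_complement,
    write_gff3, write_sites_tsv,
)

logger = logging.getLogger(__name__)

DEFAULT_B = 7            # consecutive base matches ('-b')
DEFAULT_E = -25.0        # duplex MFE cutoff in kcal/mol ('-e')
DEFAULT_SITE_FLANK = 15
DEFAULT_FOLD_FLANK = 70


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of a prediction run.

    ``b`` and ``e`` are the tool's two headline knobs: the seed length in
    consecutive Watson-Crick matches (default 7) and the duplex
    minimum-free-energy cutoff in kcal/mol (default -25; sites with
    mfe <= e pass).
    """

    b: int = DEFAULT_B
    e: float = DEFAULT_E
    site_flank: int = DEFAULT_SITE_FLANK
    fold_flank: int = DEFAULT_FOLD_FLANK
    both_strands: bool = False
    accessibility: bool = True
    energy_params: str = "turner2004-min"
    rng_seed: int = 0  # consumed only by the fixture generator

    def __post_init__(self) -> None:
        if self.b < MIN_SEED:
            raise ParameterError(f"b={self.b} is below the minimum seed length {MIN_SEED}")
        if self.e > 0:
            raise ParameterError(f"e={self.e} must be <= 0 kcal/mol")
        if self.site_flank < 0 or self.fold_flank < 0:
            raise ParameterError("flanks must be >= 0")


@dataclass(frozen=True)
class TargetSite:
    """One reported miRNA target site (passed the energy filter)."""

    mirna_id: str
    mirna_origin: str
    target_id: str
    strand: str                    # '+' or '-'
    site_start: int                # duplex footprint, forward-strand coords
    site_end: int
    seed_length: int
    duplex_mfe: float
    local_fold_mfe: float | None   # None when accessibility is disabled
    site_unpaired_fraction: float | None = None
    mirna_aln: str = ""
    pair_aln: str = ""
    target_aln: str = ""


@dataclass
class PipelineStats:
    """Per-stage counts for the run log (seeds >= windows >= sites)."""

    n_mirnas: int = 0
    n_targets: int = 0
    n_seeds: int = 0
    n_windows: int = 0
    n_duplexes_passing: int = 0
    n_sites: int = 0
    runtime_s: float = 0.0


@dataclass
class PredictionResult:
    sites: list[TargetSite]
    stats: PipelineStats
    config: PipelineConfig


def _merge_windows(intervals: list[tuple[int, int]], cap: int) -> list[tuple[int, int]]:
    """Merge overlapping intervals; start a fresh window instead of growing
    a merged one past ``cap`` nt (the duplex engine's window limit)."""
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [intervals[0]]
    for s, e in intervals[1:]:
        ls, le = merged[-1]
        if s < le and max(le, e) - ls <= cap:
            merged[-1] = (ls, max(le, e))
        else:
            merged.append((s, e))
    return merged


def run_prediction(
    mirnas: list[MiRNARecord],
    targets: list[NucSequence],
    config: PipelineConfig | None = None,
    model: EnergyModel | None = None,
) -> PredictionResult:
    """Full pipeline run, returning sites plus per-stage counters."""
    t0 = time.monotonic()
    if config is None:
        config = PipelineConfig()
    if not mirnas:
        raise MirtarpError("empty miRNA set")
    if not targets:
        raise MirtarpError("empty target set")
    if model is None:
        model = load_energy_model(config.energy_params)

    stats = PipelineStats(n_mirnas=len(mirnas), n_targets=len(targets))
    sites: list[TargetSite] = []
    strands = ("+", "-") if config.both_strands else ("+",)

    for target in targets:
        for strand in strands:
            scanned = target if strand == "+" else reverse_complement(target)
            if len(scanned) < config.b:
                continue
            index = build_match_index(scanned, config.b)
            for mirna in mirnas:
                seeds = find_seed_matches(mirna, scanned, config.b, index=index)
                stats.n_seeds += len(seeds)
                if not seeds:
                    continue
                windows = _merge_windows(
                    [
                        (
                            max(0, s.target_start - config.site_flank),
                            min(len(scanned), s.target_end + config.site_flank),
                        )
                        for s in seeds
                    ],
                    cap=MAX_WINDOW,
                )
                stats.n_windows += len(windows)
                for ws, we in windows:
                    dup = hybridize(mirna, scanned, (ws, we), model)
                    if not passes_energy_cutoff(dup, config.e):
                        continue
                    stats.n_duplexes_passing += 1
                    seed_length = max(
                        s.length for s in seeds
                        if s.target_start < we and s.target_end > ws
                    )
                    fold_mfe = None
                    unpaired = None
                    if config.accessibility:
                        site_len = dup.site_end - dup.site_start
                        flank = min(config.fold_flank, (MAX_FOLD_WINDOW - site_len) // 2)
                        fold = fold_local(scanned, (dup.site_start, dup.site_end), flank, model)
                        unpaired, fold_mfe = site_accessibility_report(
                            fold, (dup.site_start, dup.site_end)
                        )
                    if strand == "+":
                        fs, fe = dup.site_start, dup.site_end
                    else:
                        fs, fe = len(scanned) - dup.site_end, len(scanned) - dup.site_start
                    sites.append(
                        TargetSite(
                            mirna_id=mirna.id,
                            mirna_origin=mirna.origin,
                            target_id=target.id,
                            strand=strand,
                            site_start=fs,
                            site_end=fe,
                            seed_length=seed_length,
                            duplex_mfe=dup.mfe,
                            local_fold_mfe=fold_mfe,
                            site_unpaired_fraction=unpaired,
                            mirna_aln=dup.mirna_aln,
                            pair_aln=dup.pair_aln,
                            target_aln=dup.target_aln,
                        )
                    )
    sites.sort(key=lambda s: (s.target_id, s.site_start, s.mirna_id, s.strand))
    stats.n_sites = len(sites)
    stats.runtime_s = time.monotonic() - t0
    return PredictionResult(sites=sites, stats=stats, config=config)


def predict_targets(
    mirnas: list[MiRNARecord],
    targets: list[NucSequence],
    config: PipelineConfig | None = None,
    model: EnergyModel | None = None,
) -> list[TargetSite]:
    """Predict target sites for a miRNA set against a target set."""
    return run_prediction(mirnas, targets, config, model).sites


def run_batch(
    mirna_file,
    target_file,
    config: PipelineConfig | None = None,
    out_prefix: str = "mirtarp_out",
    mirna_origin: str = "host",
    gff3: bool = False,
) -> PredictionResult:
    """File-to-file batch mode: FASTA in, TSV (+ optional GFF3) and log out.

    A run with zero passing sites is a *successful* run (header-only TSV):
    screening a new virus must distinguish "no targets" from "failure".
    """
    if config is None:
        config = PipelineConfig()
    try:
        mirnas = read_mirna_fasta(mirna_file, origin=mirna_origin)
    except (OSError, MirtarpError) as exc:
        raise MirtarpError(f"failed to read miRNA FASTA {mirna_file}: {exc}") from exc
    try:
        targets = read_fasta(target_file)
    except (OSError, MirtarpError) as exc:
        raise MirtarpError(f"failed to read target FASTA {target_file}: {exc}") from exc

    result = run_prediction(mirnas, targets, config)
    tsv_path = Path(f"{out_prefix}.sites.tsv")
    write_sites_tsv(result.sites, tsv_path)
    if gff3:
        write_gff3(result.sites, Path(f"{out_prefix}.sites.gff3"))

    s = result.stats
    log_lines = [
        f"mirtarp run: b={config.b} e={config.e} site_flank={config.site_flank} "
        f"fold_flank={config.fold_flank} both_strands={config.both_strands} "
        f"accessibility={config.accessibility} energy_params={config.energy_params}",
        f"inputs: {s.n_mirnas} miRNAs ({mirna_origin}), {s.n_targets} targets",
        f"seeds found: {s.n_seeds}",
        f"windows assessed: {s.n_windows}",
        f"duplexes passing cutoff: {s.n_duplexes_passing}",
        f"{s.n_sites} sites reported",
        f"runtime: {s.runtime_s:.2f} s",
    ]
    Path(f"{out_prefix}.log").write_text("\n".join(log_lines) + "\n")
    for line in log_lines:
        logger.info(line)
    return result
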