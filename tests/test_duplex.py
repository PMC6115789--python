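"""Duplex MFE engine: oracle equivalence, consistency and cutoff semantics."""

from __future__ import annotations

import math

import pytest

from mirtarp.duplex import HybridDuplex, hybridize, passes_energy_cutoff
from mirtarp.energy import score_duplex
from mirtarp.errors import ParameterError
from mirtarp.sequence_io import reverse_complement

from conftest import make_mirna, make_target, random_rna
from oracles import enumerate_duplex_mfe

MIR20 = "ACGUACGUACGUACGUACGU"


def _pad(seq: str, to: int = 15) -> str:
    """Pad a short sequence to the miRNA length floor with unpairable N."""
    return seq + "N" * max(0, to - len(seq))


def test_no_possible_pair_returns_empty_infinite_duplex(model):
    mir = make_mirna("A" * 20)
    tgt = make_target("A" * 40)
    d = hybridize(mir, tgt, (0, 40), model)
    assert d.is_empty and d.mfe == math.inf
    assert not passes_energy_cutoff(d, -1e9)


def test_dp_equals_brute_force_on_random_small_instances(rng, model):
    # N-padding satisfies the miRNA length floor without changing the optimum:
    # N can never pair, so the admissible structures are identical
    battery = [
        ("GCGC", "GCGC"), ("AUAU", "AUAU"), ("GGGG", "CCCC"),
        ("GUGU", "GUGU"), ("ACGU", "ACGU"), ("AAGGUC", "GACCUU"),
    ]
    for _ in range(40):
        battery.append(
            (random_rna(rng, int(rng.integers(4, 10))), random_rna(rng, int(rng.integers(4, 10))))
        )
    for xs, ws in battery:
        padded = _pad(xs)
        d = hybridize(make_mirna(padded), make_target(ws), (0, len(ws)), model)
        assert d.mfe == pytest.approx(enumerate_duplex_mfe(padded, ws, model), abs=1e-6)


def test_traceback_rescoring_consistency(rng, model):
    for _ in range(25):
        mir = make_mirna(random_rna(rng, 22))
        tgt = make_target(random_rna(rng, 60))
        d = hybridize(mir, tgt, (5, 55), model)
        if d.is_empty:
            continue
        rel = [(i, j - 5) for (i, j) in d.pairs]
        assert score_duplex(rel, mir.seq.residues, tgt.residues[5:55], model) == pytest.approx(
            d.mfe, abs=1e-6
        )
        assert 5 <= d.site_start < d.site_end <= 55


def test_appending_a_stacking_pair_adds_the_stack_term(model):
    # growing a GC helix by one pair: delta = stack increment (GC ends carry
    # no terminal penalty, so no end bookkeeping changes)
    mirna = "GCGCGCGC"
    site = "GCGCGCGC"
    for k in range(2, 8):
        pairs_k = [(i, 7 - i) for i in range(k)]
        e_prev = score_duplex(pairs_k[:-1], mirna, site, model)
        e_now = score_duplex(pairs_k, mirna, site, model)
        top = mirna[k - 2] + mirna[k - 1]
        bottom = site[7 - (k - 2)] + site[7 - (k - 1)]
        from test_energy import parse_param_file

        assert e_now - e_prev == pytest.approx(parse_param_file()["stack"][(top, bottom)])


def test_cutoff_is_inclusive(model):
    d = HybridDuplex("m", "t", 0, 10, ((0, 9),), mfe=-25.0)
    assert passes_energy_cutoff(d, -25)
    assert not passes_energy_cutoff(HybridDuplex("m", "t", 0, 10, ((0, 9),), mfe=-24.9), -25)
    assert not passes_energy_cutoff(HybridDuplex("m", "t", 0, 0, (), mfe=math.inf), -25)


def test_relaxing_cutoff_never_shrinks_passing_set(rng, model):
    duplexes = []
    for _ in range(30):
        mir = make_mirna(random_rna(rng, 22))
        tgt = make_target(random_rna(rng, 50))
        duplexes.append(hybridize(mir, tgt, (0, 50), model))
    strict = {id(d) for d in duplexes if passes_energy_cutoff(d, -20)}
    relaxed = {id(d) for d in duplexes if passes_energy_cutoff(d, -10)}
    assert strict <= relaxed


def test_strand_label_symmetry(rng, model):
    # the model has no strand asymmetry: swapping which molecule is called
    # "miRNA" leaves the optimum energy unchanged
    for _ in range(15):
        a = random_rna(rng, int(rng.integers(15, 20)))
        b = random_rna(rng, int(rng.integers(15, 20)))
        e1 = hybridize(make_mirna(a), make_target(b), (0, len(b)), model).mfe
        e2 = hybridize(make_mirna(b), make_target(a), (0, len(a)), model).mfe
        assert e1 == pytest.approx(e2, abs=1e-6)


def test_window_limits_enforced(model):
    mir = make_mirna(MIR20)
    tgt = make_target("ACGU" * 100)
    with pytest.raises(ParameterError):
        hybridize(mir, tgt, (0, 300), model)
    with pytest.raises(ParameterError):
        hybridize(mir, tgt, (10, 5), model)


def test_alignment_strings_render_pairs_and_wobbles(model):
    mir = make_mirna("UAGCUUAUCAGACUGAUGUUGA")
    tgt = make_target(reverse_complement(mir.seq.residues))
    d = hybridize(mir, tgt, (0, len(tgt)), model)
    assert len(d.mirna_aln) == len(d.pair_aln) == len(d.target_aln)
    assert set(d.pair_aln) <= {"|", ":", " "}
    for top, mid, bot in zip(d.mirna_aln, d.pair_aln, d.target_aln):
        if mid == "|":
            assert (top, bot) in {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
        elif mid == ":":
            assert (top, bot) in {("G", "U"), ("U", "G")}
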