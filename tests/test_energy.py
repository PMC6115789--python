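"""Energy model loading and the explicit-structure scoring functions."""

from __future__ import annotations

import math
from importlib import resources

import numpy as np
import pytest

from mirtarp.energy import (
    PAIR_TYPES, load_energy_model, pair_type, score_duplex, score_structure,
)
from mirtarp.errors import InvalidStructureError, ParameterError


def parse_param_file() -> dict:
    """Independent, minimal parser of the shipped table for hand-summed oracles."""
    text = (resources.files("mirtarp.data") / "turner2004_min_v1.tsv").read_text()
    out = {"stack": {}, "hairpin": {}, "bulge": {}, "internal": {}}
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        kind, key, *rest = line.split("\t")
        if kind == "stack":
            out["stack"][(key, rest[0])] = float(rest[1])
        elif kind in ("hairpin", "bulge", "internal"):
            out[kind][int(key)] = float(rest[0])
        else:
            out[f"{kind}.{key}"] = float(rest[0])
    return out


def test_stack_table_complete_and_strand_symmetric(model):
    assert model.stack.shape == (6, 6)
    assert np.all(model.stack < 1 << 20)
    # reading the motif from the other strand gives the same increment
    params = parse_param_file()
    for (top, bottom), v in params["stack"].items():
        flipped = (bottom[::-1], top[::-1])
        assert params["stack"][flipped] == v


def test_loop_tables_monotone_beyond_six(model):
    for table in (model.bulge, model.internal):
        tail = table[6:]
        assert np.all(np.diff(tail) >= 0)


def test_terminal_penalty_only_on_weak_closings(model):
    for k, p in enumerate(PAIR_TYPES):
        if p in ("CG", "GC"):
            assert model.au_end[k] == 0
        else:
            assert model.au_end[k] > 0


def test_unknown_parameter_set_rejected():
    with pytest.raises(ParameterError):
        load_energy_model("no-such-params")


def test_empty_duplex_scores_infinite(model):
    assert score_duplex([], "ACGU", "ACGU", model) == math.inf


def test_single_pair_is_init_plus_two_end_penalties(model):
    params = parse_param_file()
    e = score_duplex([(0, 3)], "AAAA", "UUUU", model)
    assert e == pytest.approx(params["init.duplex"] + 2 * params["penalty.terminal_au"])
    e = score_duplex([(0, 3)], "GAAA", "UUUC", model)
    assert e == pytest.approx(params["init.duplex"])  # G:C closing carries no penalty


def test_eight_bp_helix_matches_hand_sum(model):
    # 5'-GGCAUGCC-3' paired to its reverse complement: 7 stacks, GC closings
    mirna = "GGCAUGCC"
    site = "GGCAUGCC"  # reverse complement of mirna read 3'->5' along j descending
    pairs = [(i, 7 - i) for i in range(8)]
    params = parse_param_file()
    expected = params["init.duplex"]
    for k in range(7):
        top = mirna[k] + mirna[k + 1]
        bottom = site[7 - k] + site[7 - k - 1]
        expected += params["stack"][(top, bottom)]
    assert score_duplex(pairs, mirna, site, model) == pytest.approx(expected)
    assert expected < -10  # a GC-rich helix is strongly stable


def test_duplex_geometry_violations_raise(model):
    with pytest.raises(InvalidStructureError):
        score_duplex([(0, 0), (1, 1)], "GG", "CC", model)  # j not decreasing
    with pytest.raises(InvalidStructureError):
        score_duplex([(0, 1)], "AA", "AA", model)  # A:A is not a pair
    with pytest.raises(InvalidStructureError):
        score_duplex([(0, 9)], "A", "UUUU", model)  # out of range


def test_score_structure_empty_and_hairpin(model):
    assert score_structure([], "ACGUACGU", model) == 0.0
    params = parse_param_file()
    # one closing GC pair around a 4-nt loop
    seq = "GAAAAC"
    e = score_structure([(0, 5)], seq, model)
    assert e == pytest.approx(params["hairpin"][4])


def test_score_structure_rejects_bad_geometry(model):
    with pytest.raises(InvalidStructureError):
        score_structure([(0, 8), (4, 12)], "GGGGAAAACCCCC", model)  # crossing
    with pytest.raises(InvalidStructureError):
        score_structure([(0, 3)], "GAAC", model)  # hairpin loop below minimum


def test_gu_wobble_is_a_valid_duplex_pair(model):
    assert pair_type("G", "U") >= 0
    e = score_duplex([(0, 1), (1, 0)], "GG", "UU", model)
    assert math.isfinite(e)
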