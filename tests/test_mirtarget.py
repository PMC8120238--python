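"""Seed-site scanning and duplex minimum free energy."""

import itertools
import re

import numpy as np
import pytest

from smirnet import mirtarget
from smirnet.mirtarget import EnergyParameters, default_parameters
from smirnet.seq import revcomp_rna

# ---------------------------------------------------------------------------
# seed scanning
# ---------------------------------------------------------------------------


def test_8mer_site_detected():
    # miRNA nt 1-8 = UGAGGUAG; canonical site = revcomp(nt 2-8) + A
    mirna = "UGAGGUAGUAGGUUGUAUAGUU"
    target = "GGGG" + "CUACCUCA" + "GGGG"
    sites = mirtarget.scan_seed_sites({"m": mirna}, {"t": target})
    assert len(sites) == 1
    s = sites[0]
    assert s.site_type == "8mer" and s.start == 4
    assert s.site_sequence == "CUACCUCA"


def test_7mer_m8_site_when_t1_not_adenine():
    mirna = "UGAGGUAGUAGGUUGUAUAGUU"
    target = "GGGG" + "CUACCUC" + "G" + "GGG"  # m8 match, non-A at t1
    sites = mirtarget.scan_seed_sites({"m": mirna}, {"t": target})
    assert [s.site_type for s in sites] == ["7mer-m8"]
    assert sites[0].site_sequence == "CUACCUC"


def test_7mer_a1_site_without_m8_match():
    mirna = "UGAGGUAGUAGGUUGUAUAGUU"
    # seed6 match = UACCUC; preceded by G (not C, the m8 complement), then A
    target = "GGGG" + "G" + "UACCUC" + "A" + "GGG"
    sites = mirtarget.scan_seed_sites({"m": mirna}, {"t": target})
    assert [s.site_type for s in sites] == ["7mer-A1"]
    assert sites[0].site_sequence == "UACCUCA"


def test_poly_a_target_has_no_sites():
    mirna = "UGAGGUAGUAGGUUGUAUAGUU"
    assert mirtarget.scan_seed_sites({"m": mirna}, {"t": "A" * 50}) == []


def test_short_mirna_rejected():
    with pytest.raises(ValueError, match="shorty"):
        mirtarget.scan_seed_sites({"shorty": "ACGUACG"}, {"t": "ACGU" * 10})


def _site_oracle(mirna, target):
    """Regular-expression reimplementation of the site taxonomy."""
    seed6 = revcomp_rna(mirna[1:7])
    m8 = revcomp_rna(mirna[7])
    out = []
    for m in re.finditer("(?=" + re.escape(seed6) + ")", target):
        pos = m.start()
        has_m8 = pos >= 1 and target[pos - 1] == m8
        has_a1 = pos + 6 < len(target) and target[pos + 6] == "A"
        if has_m8 and has_a1:
            out.append(("8mer", pos - 1))
        elif has_m8:
            out.append(("7mer-m8", pos - 1))
        elif has_a1:
            out.append(("7mer-A1", pos))
        else:
            out.append(("6mer", pos))
    return out


def test_scanner_matches_regex_oracle_on_random_pairs():
    rng = np.random.default_rng(0)
    bases = np.array(list("ACGU"))
    for _ in range(300):
        mirna = "".join(rng.choice(bases, 22))
        target = "".join(rng.choice(bases, rng.integers(30, 120)))
        got = [
            (s.site_type, s.start)
            for s in mirtarget.scan_seed_sites({"m": mirna}, {"t": target})
        ]
        assert got == _site_oracle(mirna, target)


# ---------------------------------------------------------------------------
# duplex MFE
# ---------------------------------------------------------------------------


def test_perfect_gc_helix_energy_sums_the_stack_table():
    params = default_parameters()
    expected = params.duplex_init + 7 * params.stack_energy[("GC", "GC")]
    d = mirtarget.duplex_mfe("GGGGGGGG", "CCCCCCCC", params)
    assert d.mfe == pytest.approx(expected)
    assert len(d.pairs) == 8
    assert d.structure[0] == "(" * 8


def test_no_possible_pair_reports_zero_and_empty_structure():
    d = mirtarget.duplex_mfe("AAAAAAAA", "AAAAAAAA")
    assert d.mfe == 0.0
    assert d.pairs == []
    assert set(d.structure[0]) == {"."}


def test_mfe_monotone_in_perfect_complement_length():
    rng = np.random.default_rng(1)
    bases = np.array(list("ACGU"))
    seq = "".join(rng.choice(bases, 22))
    last = 0.0
    for L in range(6, 23):
        sub = seq[:L]
        d = mirtarget.duplex_mfe(sub, revcomp_rna(sub))
        assert d.mfe <= last + 1e-9
        last = d.mfe


def test_mfe_invariant_to_unpairable_target_flanks():
    mirna = "GGGGCCCC"
    core = revcomp_rna(mirna)
    base = mirtarget.duplex_mfe(mirna, core).mfe
    flanked = mirtarget.duplex_mfe(mirna, "N" * 10 + core + "N" * 10).mfe
    assert flanked == pytest.approx(base)


def test_n_bases_are_unpairable():
    assert mirtarget.duplex_mfe("GGGG", "NNNN").mfe == 0.0


def test_non_rna_characters_rejected():
    with pytest.raises(ValueError):
        mirtarget.duplex_mfe("ACGX", "ACGU")


# -- exhaustive enumeration oracle ------------------------------------------

_PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}


def _enumerate_mfe(mirna, target, params):
    """Brute-force minimum over every legal duplex structure.

    A structure is a set of pairs (i, k) on the miRNA and the reversed
    target, strictly increasing in both coordinates; consecutive pairs are
    scored as a stack (adjacent) or a bulge/internal loop, plus the
    initiation term.
    """
    trev = target[::-1]
    pairable = [
        (i, k)
        for i in range(len(mirna))
        for k in range(len(trev))
        if (mirna[i], trev[k]) in _PAIRS
    ]
    best = 0.0

    def extend(chain_energy, i, k):
        nonlocal best
        best = min(best, chain_energy)
        for i2, k2 in pairable:
            if i2 <= i or k2 <= k:
                continue
            a, b = i2 - i - 1, k2 - k - 1
            if a == 0 and b == 0:
                cost = params.stack(mirna[i] + trev[k], mirna[i2] + trev[k2])
            elif a > params.max_loop or b > params.max_loop:
                continue
            else:
                cost = params.loop_cost(a, b)
            extend(chain_energy + cost, i2, k2)

    for i, k in pairable:
        extend(params.duplex_init, i, k)
    return best


def test_dp_equals_exhaustive_enumeration_for_short_sequences():
    rng = np.random.default_rng(2)
    bases = np.array(list("ACGU"))
    params = default_parameters()
    for _ in range(40):
        n1 = int(rng.integers(3, 8))
        n2 = int(rng.integers(3, 8))
        mirna = "".join(rng.choice(bases, n1))
        target = "".join(rng.choice(bases, n2))
        dp = mirtarget.duplex_mfe(mirna, target, params).mfe
        brute = _enumerate_mfe(mirna, target, params)
        assert dp == pytest.approx(min(brute, 0.0), abs=1e-9)


def test_structure_trace_is_consistent():
    d = mirtarget.duplex_mfe("GGGGGGGG", "CCCCCCCCC")
    # pairs strictly increasing on the miRNA, strictly decreasing on the
    # target (antiparallel), and every pair is WC or G:U
    mir_pos = [i for i, _ in d.pairs]
    tgt_pos = [j for _, j in d.pairs]
    assert mir_pos == sorted(mir_pos)
    assert tgt_pos == sorted(tgt_pos, reverse=True)
    assert d.target_window == (min(tgt_pos), max(tgt_pos) + 1)


# ---------------------------------------------------------------------------
# target calling and parameter I/O
# ---------------------------------------------------------------------------


def test_call_targets_requires_site_and_energy():
    sites = mirtarget.scan_seed_sites(
        {"m": "UGAGGUAGUAGGUUGUAUAGUU"}, {"with_site": "GGCUACCUCAGG"}
    )
    mk = lambda t, mfe: mirtarget.DuplexResult("m", t, mfe, [], (".", "."), (0, 0))
    confirmed = mirtarget.call_targets(
        sites, [mk("with_site", -25.0), mk("no_site", -40.0)]
    )
    assert confirmed == [("m", "with_site")]
    assert mirtarget.call_targets(sites, [mk("with_site", -10.0)]) == []


def test_energy_parameters_tsv_round_trip(tmp_path):
    params = default_parameters()
    path = tmp_path / "params.tsv"
    params.to_tsv(path)
    back = EnergyParameters.from_tsv(path)
    assert back.stack_energy == params.stack_energy
    assert back.duplex_init == params.duplex_init
    assert back.max_loop == params.max_loop
    assert mirtarget.duplex_mfe("GGGGGGGG", "CCCCCCCC", back).mfe == pytest.approx(
        mirtarget.duplex_mfe("GGGGGGGG", "CCCCCCCC", params).mfe
    )
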