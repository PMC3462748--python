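"""Signal prediction, cleavage rules, excision and PTMs."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from barnapep.annotate import (
    AnnotationError, apply_amidation, apply_pyroglu, excise_peptides,
    find_cleavage_sites, find_orf, predict_signal_peptide, predict_sulfation,
    screen_precursor, annotate_protein,
)
from barnapep.config import PipelineConfig
from barnapep.io import Transcript
from barnapep.mining import mine_transcriptome
from barnapep.simulate import (
    Payload, PrecursorSpec, back_translate, generate_precursor, make_signal,
)
from barnapep.io import ReferencePeptide

AA20 = "ACDEFGHIKLMNPQRSTVWY"


# --- signal peptide -------------------------------------------------------

def test_constructed_signal_cleaved_after_16():
    sig = predict_signal_peptide("MKTLLVLAVLALASSA" + "QFDDYSTENNA")
    assert sig.present and sig.cleavage_after == 16


def test_acidic_protein_has_no_signal():
    assert not predict_signal_peptide("MDDDDEEEEDDDDEEEEDDDDEEEE").present


def test_short_protein_has_no_signal():
    assert not predict_signal_peptide("MKTLLVLAVLA").present


def test_planted_signals_recovered_within_two_residues():
    detected = within2 = 0
    n = 200
    for i in range(n):
        rng = np.random.default_rng(3000 + i)
        L = int(rng.integers(14, 21))
        sig = make_signal(rng, L)
        body = "".join(rng.choice(list("ASNETDHL"), size=40))
        pred = predict_signal_peptide(sig + body)
        if pred.present:
            detected += 1
            if abs(pred.cleavage_after - L) <= 2:
                within2 += 1
    assert detected >= 0.95 * n
    assert within2 >= 0.95 * n


# --- cleavage rules -------------------------------------------------------

def _accepted(protein, signal_end=0, cfg=None):
    return [(s.position, s.site_type)
            for s in find_cleavage_sites(protein, signal_end, cfg)
            if s.accepted]


def test_dibasic_kr_and_rr_always_accepted():
    assert _accepted("AAAAKRSSSS") == [(6, "KR")]
    assert _accepted("AAAARRSSSS") == [(6, "RR")]


def test_rk_and_kk_only_when_toggled():
    assert _accepted("AAAARKSSSS") == []
    assert _accepted("AAAAKKSSSS") == []
    cfg = PipelineConfig(accept_rk=True, accept_kk=True)
    assert _accepted("AAAARKSSSS", cfg=cfg) == [(6, "RK")]
    assert _accepted("AAAAKKSSSS", cfg=cfg) == [(6, "KK")]


def test_site_followed_by_proline_is_rejected():
    assert _accepted("AAAAKRPSSS") == []


def test_mono_arg_needs_upstream_basic_at_4_6_or_8():
    # K at -4 of the R supports cleavage
    assert _accepted("KAAARNAAAA") == [(5, "mono_R")]
    # K at -6
    assert _accepted("KAAAAARNAA") == [(7, "mono_R")]
    # isolated R: no support anywhere
    assert _accepted("AAAARNAAAA") == []
    # support residue inside an accepted dibasic site does not count
    assert _accepted("AAKRAAARAA") == [(4, "KR")]


def test_exhaustive_mono_arg_rule_table():
    # brute-force check of the -4/-6/-8 rule over all support offsets
    for off in range(1, 10):
        protein = "A" * (10 - off) + "K" + "A" * (off - 1) + "R" + "NAAA"
        got = _accepted(protein)
        expect_pos = 11
        if off == 1:
            # adjacent K and R form a dibasic KR site instead
            assert got == [(expect_pos, "KR")], off
        elif off in (4, 6, 8):
            assert got == [(expect_pos, "mono_R")], off
        else:
            assert got == [], off


def test_multibasic_run_is_one_site_at_last_residue():
    assert _accepted("AAAAKKRSSS") == [(7, "multibasic")]
    assert _accepted("AAARRKRSSS") == [(7, "multibasic")]


def test_sites_before_signal_end_are_ignored():
    assert _accepted("AAKRAAAAAA", signal_end=5) == []


# --- screening ------------------------------------------------------------

SIGNAL = "MKLLILFLIILFSFA"


def _screened(length):
    body_len = length - len(SIGNAL) - 2
    protein = SIGNAL + "KR" + "N" * body_len
    assert len(protein) == length
    sig = predict_signal_peptide(protein)
    sites = find_cleavage_sites(protein, sig.cleavage_after)
    return screen_precursor(protein, sig, sites)


def test_299_residue_precursor_passes_screen():
    assert _screened(299).passed


def test_300_residue_precursor_fails_length_criterion():
    s = _screened(300)
    assert not s.under_length and not s.passed


def test_no_processing_site_fails_screen():
    protein = SIGNAL + "N" * 50
    sig = predict_signal_peptide(protein)
    s = screen_precursor(protein, sig,
                         find_cleavage_sites(protein, sig.cleavage_after))
    assert sig.present and not s.has_processing_site and not s.passed


def test_screen_is_monotone_in_signal_and_sites():
    full = _screened(250)
    assert full.passed
    # removing the signal can only flip passed to False
    naked = "N" * 250
    no_sig = screen_precursor(naked, predict_signal_peptide(naked), [])
    assert not no_sig.passed


# --- excision -------------------------------------------------------------

def test_excision_between_signal_and_sites():
    protein = "M" * 16 + "AAAA" + "KR" + "DDDD"
    sites = find_cleavage_sites(protein, 16)
    segs = excise_peptides(protein, 16, sites)
    assert [(s, e, q) for s, e, q in segs] == \
        [(17, 20, "AAAA"), (23, 26, "DDDD")]


def test_zero_sites_yield_single_segment():
    protein = "M" * 16 + "ADEFNQSTH"
    assert excise_peptides(protein, 16, []) == [(17, 25, "ADEFNQSTH")]


@pytest.mark.parametrize("seed", range(25))
def test_conservation_random_proteins(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(30, 120))
    protein = "".join(rng.choice(list(AA20), size=n))
    signal_end = int(rng.integers(10, min(26, n)))
    sites = find_cleavage_sites(protein, signal_end)
    segs = excise_peptides(protein, signal_end, sites)
    pieces = [(1, protein[:signal_end])]
    pieces += [(s.start, protein[s.start - 1:s.position])
               for s in sites if s.accepted]
    pieces += [(a, q) for a, _, q in segs]
    rebuilt = "".join(q for _, q in sorted(pieces))
    assert rebuilt == protein


# --- PTMs -----------------------------------------------------------------

@pytest.mark.parametrize("segment,expect", [
    ("NSELINSLLGLPKIMNEAG", ("NSELINSLLGLPKIMNEA", True)),
    ("SYWKQCSFNAVSCFG", ("SYWKQCSFNAVSCF", True)),
    ("ADEF", ("ADEF", False)),
])
def test_gly_donor_amidation(segment, expect):
    assert apply_amidation(segment) == expect


@given(st.text(alphabet=AA20, min_size=1, max_size=30))
def test_amidation_idempotent_and_removes_at_most_one(seq):
    once, _ = apply_amidation(seq)
    twice, again = apply_amidation(once)
    assert twice == once and not again or once.endswith("G")
    assert len(seq) - len(once) <= 1


def test_pyroglu_flags():
    assert apply_pyroglu("QVRF")
    assert not apply_pyroglu("AVRF")
    cfg_on = PipelineConfig(pyroglu_glu=True)
    assert apply_pyroglu("EVRF", cfg_on)
    assert not apply_pyroglu("EVRF")


def test_sulfation_hand_counted_window():
    # Y at position 9; D/E within +/-5 residues: D4, D7, D8 -> flagged
    assert predict_sulfation("GGDDQFDDYGHMRF") == (9,)
    assert predict_sulfation("AAAYAAA") == ()
    assert predict_sulfation("ACDEFG") == ()


# --- ORF extraction -------------------------------------------------------

def _hit_for(query, transcripts):
    hits = mine_transcriptome([query], transcripts)[query.id]
    assert hits
    return hits[0]


def test_orf_starts_at_met_inside_stop_bounded_segment(rng):
    protein = "M" + "KLLILFLIILFSF" + "ANSELINSLLGLPKIMNEAG"
    cds = back_translate(protein, rng)
    seq = "AAA" + "TAA" + cds + "TAA" + "AAA"
    tx = Transcript(id="t", sequence=seq)
    q = ReferencePeptide(id="q", sequence=protein[5:30])
    cand = find_orf(_hit_for(q, [tx]), tx)
    assert cand.protein == protein
    assert cand.starts_at_met


def test_orf_without_met_is_flagged(rng):
    protein = "NSELINSLLGLPDDENNEASSDEANNQ"  # no Met anywhere
    cds = back_translate(protein, rng)
    tx = Transcript(id="t", sequence="TAA" + cds + "TAA")
    q = ReferencePeptide(id="q", sequence=protein)
    cand = find_orf(_hit_for(q, [tx]), tx)
    assert cand.protein == protein
    assert not cand.starts_at_met


@pytest.mark.parametrize("seed", range(10))
def test_planted_orfs_recovered_exactly(seed):
    spec = PrecursorSpec(
        family="PDH",
        payloads=(Payload("NSELINSLLGLPKIMNEA", True),),
        spacer_len=8,
    )
    rng = np.random.default_rng(seed)
    protein, truth = generate_precursor(spec, rng)
    cds = back_translate(protein, rng)
    utr = "".join(rng.choice(list("ACGT"), size=int(rng.integers(20, 60))))
    tx = Transcript(id="t", sequence=utr + "TAA" + cds + "TAA" + utr)
    q = ReferencePeptide(id="q", sequence=protein[:40])
    cand = find_orf(_hit_for(q, [tx]), tx)
    assert cand.protein == protein


# --- end-to-end planted recovery -----------------------------------------

@pytest.mark.parametrize("seed", range(10))
def test_planted_peptide_triples_recovered(seed):
    spec = PrecursorSpec(
        family="SULF",
        payloads=(Payload("QFDDYGHMRF", True), Payload("AADEYGFMKF", True),
                  Payload("SLDDYGFFKF", True)),
        spacer_len=6,
    )
    protein, truth = generate_precursor(spec, seed)
    ap = annotate_protein(protein, "s")
    got = [(p.sequence, p.amidated, p.pyroglu) for p in ap.peptides]
    want = [(p.sequence, p.amidated, p.pyroglu) for p in truth.peptides]
    assert got == want
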