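"""SE selection, compatibility screens, RE barcodes, silent mutagenesis."""

import random

import pytest

from gts.barcodes import (
    REDefinition,
    barcodable_fraction,
    choose_enzyme,
    find_sites,
    get_enzyme,
    load_enzyme_table,
    longest_complementary_match,
    make_re_barcode,
    screen_barcode_set,
    select_se,
    suggest_silent_mutation,
    translate_cds,
    type_iis_panel,
)
from gts.config import DEFAULT_CONFIG
from gts.errors import (
    DesignError,
    NoSynonymousFixError,
    SeDesignError,
    UnknownEnzymeError,
)
from gts.fixtures import FixtureSpec, generate_parts, random_barcode
from gts.parts import Barcode, Fragment, has_self_complementary_run, revcomp


# ------------------------------------------------------------- enzyme table

def test_bundled_panel_contains_tested_enzymes():
    table = load_enzyme_table()
    for name in ("MboII", "HphI", "BmrI", "BciVI"):
        enz = table[name]
        assert enz.panel_1nt
        assert enz.overhang_length == 1 and enz.overhang_polarity == "3p"
    assert len(type_iis_panel()) == 5  # a fifth (provisional) member
    with pytest.raises(UnknownEnzymeError):
        get_enzyme("NopeI")


def test_find_sites_both_strands():
    enz = get_enzyme("MboII")
    seq = "AA" + "GAAGA" + "CCCC" + revcomp("GAAGA") + "TT"
    assert find_sites(seq, enz) == [(2, "+"), (11, "-")]
    # palindromic recognition reports one hit per position
    noti = get_enzyme("NotI")
    assert find_sites("AAGCGGCCGCAA", noti) == [(2, "+")]


# ------------------------------------------------------------ SE selection

def test_select_se_minimality_and_validity(cfg):
    rng = random.Random(5)
    for _ in range(50):
        region = "".join(rng.choice("GCGCAT") for _ in range(26))
        try:
            se = select_se(region, cfg)
        except SeDesignError:
            continue
        # minimal: no shorter in-range prefix also qualifies
        from gts.parts import melting_temp

        for n in range(cfg.se_min_len, len(se)):
            prefix = region[:n]
            assert (
                melting_temp(prefix, cfg.tm_se) < cfg.tm_se.threshold_c
                or has_self_complementary_run(prefix, cfg.palindrome_min)
            )
        assert "SE-length" not in Barcode(id="t", L="AAA", SE=se, R="AA").validate().violations


def test_select_se_gc_rich_shortest_at_rich_fails():
    assert len(select_se("GGC" * 9)) == 15  # GC-rich: minimum length suffices
    with pytest.raises(SeDesignError) as exc:
        select_se("AT" * 13)
    assert exc.value.diagnosis  # per-length diagnosis attached


def test_select_se_rejects_palindromic_regions():
    # every 15-20-nt prefix contains the central 10-nt palindrome GCGCGCGCGC
    region = "AAAA" + "GCGCGCGCGC" + "ATATATATATAT"
    with pytest.raises(SeDesignError):
        select_se(region)


def test_self_ligation_screen_matches_brute_force():
    def brute(seq, k=8):
        return any(
            seq[i : i + n] == revcomp(seq[i : i + n])
            for n in range(k, len(seq) + 1)
            for i in range(len(seq) - n + 1)
        )

    rng = random.Random(9)
    for _ in range(500):
        seq = "".join(rng.choice("ACGT") for _ in range(15))
        assert has_self_complementary_run(seq, 8) == brute(seq)


# ------------------------------------------------------------ compatibility

def test_longest_complementary_match_brute_force():
    def brute(a, b):
        best = 0
        for n in range(1, min(len(a), len(b)) + 1):
            for i in range(len(a) - n + 1):
                if revcomp(a[i : i + n]) in b:
                    best = max(best, n)
        return best

    rng = random.Random(13)
    for _ in range(100):
        a = "".join(rng.choice("ACGT") for _ in range(rng.randint(8, 20)))
        b = "".join(rng.choice("ACGT") for _ in range(rng.randint(8, 20)))
        assert longest_complementary_match(a, b) == brute(a, b)


def test_screen_rejects_duplicate_and_revcomp_ses():
    se = "GCGTGCAGCCGTGCAGC"
    b1 = Barcode(id="a", L="AAA", SE=se, R="")
    b2 = Barcode(id="b", L="CCC", SE=se, R="")
    rep = screen_barcode_set([b1, b2])
    assert not rep.compatible
    assert rep.offending[0][2] == "duplicate-SE"
    b3 = Barcode(id="c", L="AAA", SE=revcomp(se), R="")
    assert not screen_barcode_set([b1, b3]).compatible


def test_screen_random_set_compatible_and_scores_match_oracle(cfg):
    rng = random.Random(21)
    barcodes = [random_barcode(rng, f"s{i}", cfg) for i in range(7)]
    rep = screen_barcode_set(barcodes)
    assert rep.compatible
    # scores equal a brute-force all-pairs duplex scan over overhang variants
    for (i, j), score in rep.scores.items():
        bi = next(b for b in barcodes if b.id == i)
        bj = next(b for b in barcodes if b.id == j)
        expected = max(
            longest_complementary_match(x, y)
            for x in (bi.SE, revcomp(bi.SE))
            for y in (bj.SE, revcomp(bj.SE))
        )
        assert score == expected


# ------------------------------------------------------------ enzyme choice

def test_choose_enzyme_skip_and_tiebreak():
    clean = Fragment(id="c", seq="G" + "GCCT" * 20 + "T")
    assert choose_enzyme(clean).name == type_iis_panel()[0].name
    blocked = Fragment(id="b", seq="G" + "GCCT" * 10 + "GAAGA" + "GCCT" * 10 + "T")
    enz = choose_enzyme(blocked)
    assert enz is not None and enz.name != "MboII"


def test_barcodable_fraction_matches_double_strand_scan():
    reg = generate_parts(FixtureSpec(seed=77, n_fragments=100, n_barcodes=2,
                                     fragment_len=(200, 900)))
    panel = type_iis_panel()
    frac = barcodable_fraction(reg, panel)

    def brute_ok(seq):
        return any(
            e.recognition not in seq and revcomp(e.recognition) not in seq
            for e in panel
        )

    expected = sum(brute_ok(f.seq) for f in reg.fragments.values()) / 100
    assert frac == expected
    assert 0.5 < frac <= 1.0  # most fragments barcodable, as in real registries


# -------------------------------------------------------------- RE barcodes

def test_make_re_barcode_bsai_overhang_in_spacer(rng):
    from gts.simulate import Duplex, digest

    bsai = get_enzyme("BsaI")
    bc = make_re_barcode([bsai], "A" + "CTAG", rng, bc_id="gg")
    assert bc.validate().ok
    circle = Duplex.circle("G" * 60 + bc.full_seq + "T" * 50)
    pieces = digest(circle, [bsai])
    assert len(pieces) == 1  # one site: linearized
    assert pieces[0].left_end().seq == "CTAG"  # the designed 4-nt overhang
    assert pieces[0].left_end().kind == "top5"


def test_make_re_barcode_long_site_and_fit_error(rng):
    iceu = get_enzyme("I-CeuI")
    bc = make_re_barcode([iceu], "", rng, bc_id="homing")
    assert iceu.recognition in bc.full_seq
    assert bc.validate().ok
    with pytest.raises(DesignError):
        make_re_barcode([iceu, iceu, iceu], "", rng, bc_id="toolong")


# -------------------------------------------------------- silent mutagenesis

def test_silent_mutation_bsai_example():
    # GGTCTC split as codons GGT|CTC: Gly GGT->GGA destroys the site
    seq = "G" + "ATG" + "GGTCTC" + "AAACCC" * 8 + "TAA" + "T"
    frag = Fragment(id="cds", seq=seq, kind="gene", cds_frame=1)
    bsai = get_enzyme("BsaI")
    (start, _strand), = find_sites(seq, bsai)
    edited, report = suggest_silent_mutation(frag, (start, start + 6), bsai)
    assert report["edits"] == [{"codon_index": 1, "old": "GGT", "new": "GGA"}]
    assert not find_sites(edited.seq, bsai)
    assert translate_cds(edited.seq, 1) == translate_cds(seq, 1)
    assert edited.validate().ok


def test_silent_mutation_impossible_for_met_trp_codons():
    # recognition covering only Met/Trp codons admits no synonymous change
    enz = REDefinition(name="FakeI", recognition="ATGTGG", cut_top=10, cut_bottom=9)
    seq = "G" + "ATG" + "ATGTGG" + "AAACCC" * 8 + "TAA" + "T"
    frag = Fragment(id="cds", seq=seq, kind="gene", cds_frame=1)
    (start, _strand), = find_sites(seq, enz)
    with pytest.raises(NoSynonymousFixError):
        suggest_silent_mutation(frag, (start, start + 6), enz, panel=[enz])


def test_silent_mutation_property_random_cds():
    """Random CDS fragments with implanted sites: translation always preserved
    and the whole panel re-scans clean of new sites."""
    panel = type_iis_panel()
    reg = generate_parts(
        FixtureSpec(seed=31, n_fragments=1, n_barcodes=1, n_cds_fragments=12,
                    cds_implant_site="BsaI", fragment_len=(120, 400))
    )
    bsai = get_enzyme("BsaI")
    fixed = 0
    for frag in reg.fragments.values():
        if frag.cds_frame is None:
            continue
        sites = find_sites(frag.seq, bsai)
        if not sites:
            continue
        start, _ = sites[0]
        old_sites = {e.name: set(find_sites(frag.seq, e)) for e in panel + [bsai]}
        try:
            edited, _ = suggest_silent_mutation(frag, (start, start + 6), bsai, panel)
        except NoSynonymousFixError:
            continue
        assert translate_cds(edited.seq, frag.cds_frame) == translate_cds(
            frag.seq, frag.cds_frame
        )
        for e in panel + [bsai]:
            assert set(find_sites(edited.seq, e)) <= old_sites[e.name]
        assert edited.validate().ok
        fixed += 1
    assert fixed >= 8  # the property was actually exercised
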