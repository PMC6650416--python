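"""Design of Foligos, Noligos, Boligos and Aoligos, routing, order sheets."""

import math
import random

import pytest

from gts.barcodes import get_enzyme, type_iis_panel
from gts.errors import DesignError, NoRouteError, PrimerDesignError
from gts.fixtures import FixtureSpec, random_barcode, random_fragment
from gts.oligos import (
    Oligo,
    RouteOptions,
    boligo_arms,
    choose_fragment_route,
    design_aoligos,
    design_boligos,
    design_foligos_ps,
    design_foligos_re,
    design_noligos,
    emit_order_sheet,
    parse_order_sheet,
)
from gts.parts import Barcode, Fragment, revcomp
from gts.simulate import fold_boligo


def _fragment(seq, fid="f", **kw):
    return Fragment(id=fid, seq=seq, **kw)


# ------------------------------------------------------------------ Foligos

def test_foligo_ps_positions_and_prefixes():
    frag = _fragment("GCTA" + "GCAT" * 20 + "AGT")
    fol_f, fol_r = design_foligos_ps(frag)
    assert frag.seq.startswith(fol_f.seq)
    assert fol_f.seq.startswith("GCTA")
    assert fol_f.ps_bonds == frozenset({1})
    assert fol_f.vendor_string().startswith("G*CTA")
    # reverse primer is a prefix of the reverse complement: fragment ends AGT
    assert revcomp(frag.seq).startswith(fol_r.seq)
    assert fol_r.seq.startswith("ACT")
    assert fol_r.ps_bonds == frozenset({1})


def test_foligo_binding_length_tracks_gc_content():
    gc_rich = _fragment("G" + "GC" * 40 + "AT")
    balanced = _fragment("G" + "GCAT" * 20 + "T")
    f_gc, _ = design_foligos_ps(gc_rich)
    f_bal, _ = design_foligos_ps(balanced)
    assert len(f_gc.seq) <= len(f_bal.seq)


def test_foligo_failure_on_extreme_at_fragment():
    at_frag = _fragment("G" + "AT" * 40 + "T")
    with pytest.raises(PrimerDesignError):
        design_foligos_ps(at_frag)


def test_foligo_re_layout_and_as_randomness(rng):
    frag = _fragment("G" + "GCAT" * 30 + "T")
    enz = get_enzyme("MboII")
    d1 = design_foligos_re(frag, enz, random.Random(1))
    d2 = design_foligos_re(frag, enz, random.Random(2))
    # primer = AS + RS + SS + binding; spacer length is enzyme-specific
    assert d1.plan_f.RS == "GAAGA"
    assert len(d1.plan_f.SS) == enz.cut_top - len(enz.recognition) - 1
    assert d1.foligo_f.seq == d1.plan_f.primer_seq
    assert frag.seq.startswith(d1.plan_f.binding)
    # AS is non-functional random padding: differs across seeds
    assert d1.plan_f.AS != d2.plan_f.AS


def test_foligo_re_rejects_internal_site(rng):
    frag = _fragment("G" + "GCAT" * 10 + "GAAGA" + "GCAT" * 10 + "T")
    from gts.errors import InternalSiteError

    with pytest.raises(InternalSiteError):
        design_foligos_re(frag, get_enzyme("MboII"), rng)


# ------------------------------------------------------------------ Noligos

def test_noligo_construction_and_bounds():
    frag = _fragment("G" + "GCAT" * 9 + "ACT")  # 40 nt
    nol_g, nol_a = design_noligos(frag)
    assert nol_g.seq == frag.seq[1:]
    assert nol_a.seq == revcomp(frag.seq)[1:]
    assert len(nol_g.seq) == len(nol_a.seq) == len(frag.seq) - 1
    with pytest.raises(DesignError):
        design_noligos(_fragment("G" + "GCAT" * 14 + "GAT"))  # 60 nt: out of range


# ------------------------------------------------------------------ Boligos

@pytest.fixture(scope="module")
def barcode():
    return Barcode(id="B", L="ACT", SE="GCGTGCAGCCGTGCAGC", R="TTGA")


def test_boligo_count_and_layout(barcode):
    bols = design_boligos(barcode)
    assert sorted(bols) == ["LA", "LG", "RA", "RG"]
    loop = "TTTTTT"
    left, right = barcode.left_half, barcode.right_half
    assert bols["LG"].seq == left + loop + revcomp(left) + "G"
    assert bols["LA"].seq == left + loop + revcomp(left) + "A"
    assert bols["RG"].seq == revcomp(right) + loop + right + "G"
    assert bols["RA"].seq == revcomp(right) + loop + right + "A"
    assert all(o.phos5 for o in bols.values())


def test_boligo_length_formula():
    # L empty, 17-nt SE, 4-nt R: RG length = 2*21 + 7 = 49
    bc = Barcode(id="B2", L="", SE="GCGTGCAGCCGTGCAGC", R="TTGA")
    bols = design_boligos(bc)
    assert len(bols["RG"].seq) == 2 * len(bc.right_half) + 7 == 49


def test_boligo_corpus_respects_cap_and_folds(cfg):
    rng = random.Random(11)
    for i in range(200):
        bc = random_barcode(rng, f"c{i}", cfg)
        for role, oligo in design_boligos(bc, cfg=cfg).items():
            assert len(oligo.seq) <= 90
            hp = fold_boligo(oligo)  # stems perfectly self-complementary
            expected_arm = (
                bc.left_half if role.startswith("L") else revcomp(bc.right_half)
            )
            assert hp.pre_arm == expected_arm
            assert hp.base == role[1]


def test_boligo_loop_terminal_pairing_rejected(barcode):
    with pytest.raises(DesignError):
        design_boligos(barcode, loop="AGGGGT")  # A pairs T: stem would extend
    design_boligos(barcode, loop="AGGGGA")  # same ends, no pair: accepted


def test_boligo_role_requires_phosphate(barcode):
    with pytest.raises(DesignError):
        Oligo(id="x", seq=barcode.left_half, role="BoligoLG", phos5=False)


# ------------------------------------------------------------------ Aoligos

def test_aoligo_is_postloop_arm_plus_base(barcode):
    bols = design_boligos(barcode)
    aols = design_aoligos(barcode)
    se_len = len(barcode.SE)
    for role in ("LG", "LA", "RG", "RA"):
        # exact post-loop suffix of its Boligo
        assert bols[role].seq.endswith(aols[role].seq)
        assert aols[role].ps_bonds == frozenset({se_len, math.ceil(se_len / 2)})
    assert aols["RG"].seq == barcode.right_half + "G"
    assert aols["LA"].seq == revcomp(barcode.left_half) + "A"


# ------------------------------------------------------------------ routing

def test_route_choice_by_length():
    short = _fragment("G" + "GCAT" * 10 + "ACT")  # 45 nt
    assert choose_fragment_route(short).route == "noligo"
    long = _fragment("G" + "GCAT" * 199 + "ACT")  # ~800 nt
    assert choose_fragment_route(long).route == "ps-pcr"


def test_route_boundary_is_59():
    for n in (59, 60):
        frag = _fragment("G" + "GC" * ((n - 2) // 2) + "A" * ((n - 2) % 2) + "T")
        assert len(frag.seq) == n
        route = choose_fragment_route(frag).route
        assert route == ("noligo" if n <= 59 else "ps-pcr")


def test_route_no_ps_with_all_sites_blocked():
    core = "".join(e.recognition for e in type_iis_panel())
    frag = _fragment("G" + "GCAT" * 10 + core + "GCAT" * 10 + "T")
    with pytest.raises(NoRouteError) as exc:
        choose_fragment_route(frag, RouteOptions(allow_ps=False))
    assert exc.value.blocking_sites  # names the blocking sites per enzyme
    # with the chemical route allowed, the same fragment routes to ps-pcr
    assert choose_fragment_route(frag).route == "ps-pcr"


def test_route_prefer_re_picks_first_clean_enzyme():
    frag = _fragment("G" + "GCAT" * 30 + "T")
    choice = choose_fragment_route(frag, RouteOptions(prefer_re=True))
    assert choice.route == "re-pcr"
    assert choice.enzyme.name == type_iis_panel()[0].name  # tie-break: panel order


def test_route_skips_blocked_enzyme():
    # internal MboII site only: first clean enzyme is the next panel member
    frag = _fragment("G" + "GCCT" * 15 + "GAAGA" + "GCCT" * 15 + "T")
    choice = choose_fragment_route(frag, RouteOptions(prefer_re=True))
    assert choice.route == "re-pcr"
    assert choice.enzyme.name != "MboII"


# -------------------------------------------------------------- order sheet

def test_order_sheet_round_trip(barcode):
    oligos = list(design_boligos(barcode).values()) + list(
        design_aoligos(barcode).values()
    )
    sheet = emit_order_sheet(oligos)
    assert list(sheet["id"]) == sorted(sheet["id"])  # deterministic ordering
    boligo_rows = sheet[sheet["role"].str.startswith("Boligo")]
    assert all(boligo_rows["sequence"].str.startswith("/5Phos/"))
    aoligo_rows = sheet[sheet["role"].str.startswith("Aoligo")]
    assert all(aoligo_rows["sequence"].str.contains(r"\*"))
    back = parse_order_sheet(sheet)
    assert sorted(back, key=lambda o: o.id) == sorted(oligos, key=lambda o: o.id)
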