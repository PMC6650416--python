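"""Strand-level chemistry: preparation, folding, barcoding, digestion,
assembly, colony PCR, GenBank export."""

import random
from dataclasses import replace

import pytest

from gts.barcodes import get_enzyme
from gts.errors import (
    AmbiguousAssemblyError,
    NoCircularProductError,
    NotAHairpinError,
    OverhangMismatchError,
    PrimerNotFoundError,
    SimulationError,
)
from gts.fixtures import FixtureSpec, generate_parts
from gts.oligos import (
    Oligo,
    design_aoligos,
    design_boligos,
    design_foligos_ps,
    design_foligos_re,
    design_noligos,
)
from gts.parts import Barcode, Fragment, revcomp
from gts.planner import AssemblyDesign, declarative_product
from gts.simulate import (
    AssemblyProduct,
    Duplex,
    End,
    assemble,
    barcode_fragment,
    cliva_activate,
    digest,
    fold_boligo,
    from_genbank,
    predict_colony_pcr,
    prepare_fragment,
    to_genbank,
)
from gts.workflow import simulate_design


@pytest.fixture(scope="module")
def barcode():
    return Barcode(id="B", L="ACT", SE="GCGTGCAGCCGTGCAGC", R="TTGA")


@pytest.fixture(scope="module")
def barcode2():
    return Barcode(id="B2", L="", SE="GGTGGACGTGAGGTGC", R="CAAT")


@pytest.fixture(scope="module")
def fragment():
    return Fragment(id="f", seq="GACG" + "GCAT" * 20 + "AAT")


# ------------------------------------------------------------- preparation

def test_prepared_fragment_shape(fragment):
    fol = design_foligos_ps(fragment)
    pf = prepare_fragment(fragment, "ps-pcr", fol)
    d = pf.duplex
    n = len(fragment.seq)
    assert d.top_seq == fragment.seq[1:]  # top strand lost the leading G
    assert d.bottom_seq == revcomp(fragment.seq)[1:]
    assert d.left_end() == End("bot3", "G")  # C overhang opposite the native G
    assert d.right_end() == End("top3", "T")


def test_route_equivalence_ps_re_noligo(rng, fragment):
    pf_ps = prepare_fragment(fragment, "ps-pcr", design_foligos_ps(fragment))
    for name in ("MboII", "HphI", "BmrI", "BciVI", "MnlI"):
        enz = get_enzyme(name)
        from gts.barcodes import find_sites

        if find_sites(fragment.seq, enz):
            continue
        design = design_foligos_re(fragment, enz, rng)
        pf_re = prepare_fragment(fragment, "re-pcr", design)
        assert pf_re.duplex == pf_ps.duplex  # byte-identical

    short = Fragment(id="s", seq="G" + "GCAT" * 9 + "ACT")
    pf_n = prepare_fragment(short, "noligo", design_noligos(short))
    n = len(short.seq)
    assert pf_n.duplex == Duplex(extent=short.seq, top=(1, n), bottom=(0, n - 1))


def test_prepare_rejects_mismatched_oligos(fragment):
    other = Fragment(id="o", seq="G" + "TACG" * 20 + "CCT")
    fol = design_foligos_ps(other)
    with pytest.raises(SimulationError):
        prepare_fragment(fragment, "ps-pcr", fol)


# ------------------------------------------------------------------ folding

def test_fold_boligo_descriptor(barcode):
    bols = design_boligos(barcode)
    hp = fold_boligo(bols["RG"])
    assert hp.stem_len == len(barcode.right_half)
    assert hp.base == "G"
    assert hp.loop == "TTTTTT"


def test_fold_rejects_blunt_conventional_oligo(barcode):
    # a conventional (non-hairpin) barcode-half oligo submitted as a Boligo
    blunt = Oligo(
        id="conv", seq=barcode.left_half + "G", role="BoligoLG", phos5=True
    )
    with pytest.raises(NotAHairpinError):
        fold_boligo(blunt)


def test_fold_rejects_one_nt_arm_mismatch(barcode):
    good = design_boligos(barcode)["LG"].seq
    mutated = good[:1] + ("A" if good[1] != "A" else "C") + good[2:]
    bad = Oligo(id="mut", seq=mutated, role="BoligoLG", phos5=True)
    with pytest.raises(NotAHairpinError):
        fold_boligo(bad)


# ---------------------------------------------------------------- barcoding

def _barcoded(fragment, up_bc, dn_bc, up_role="RG", dn_role="LA"):
    pf = prepare_fragment(fragment, "ps-pcr", design_foligos_ps(fragment))
    return barcode_fragment(
        pf,
        left_boligo=design_boligos(up_bc)[up_role],
        right_boligo=design_boligos(dn_bc)[dn_role],
        left_aoligo=design_aoligos(up_bc)[up_role],
        right_aoligo=design_aoligos(dn_bc)[dn_role],
    )


def test_barcoded_amplicon_structure(fragment, barcode, barcode2):
    bf = _barcoded(fragment, barcode, barcode2)
    # RG + LA on a forward fragment: (SE+R)up + fragment + (L+SE)dn
    assert bf.amplicon.extent == (
        barcode.right_half + fragment.seq + barcode2.left_half
    )
    # the ligation intermediate is a closed dumbbell: no ligatable free ends
    assert bf.dumbbell.free_ends == 0
    assert bf.dumbbell.left_end().kind == "sealed"


def test_barcoding_overhang_mismatch(fragment, barcode, barcode2):
    with pytest.raises(OverhangMismatchError):
        _barcoded(fragment, barcode, barcode2, up_role="RA")  # A offered to C end
    with pytest.raises(OverhangMismatchError):
        _barcoded(fragment, barcode, barcode2, dn_role="LG")  # G offered to T end


def test_barcoding_aoligo_boligo_mismatch(fragment, barcode, barcode2):
    pf = prepare_fragment(fragment, "ps-pcr", design_foligos_ps(fragment))
    with pytest.raises(SimulationError):
        barcode_fragment(
            pf,
            left_boligo=design_boligos(barcode)["RG"],
            right_boligo=design_boligos(barcode2)["LA"],
            left_aoligo=design_aoligos(barcode)["LG"],  # wrong variant
            right_aoligo=design_aoligos(barcode2)["LA"],
        )


def test_cliva_activation_exposes_full_se(fragment, barcode, barcode2):
    bf = _barcoded(fragment, barcode, barcode2)
    act = cliva_activate(bf)
    left, right = act.left_end(), act.right_end()
    assert left == End("bot3", barcode.SE)  # revcomp(SE_up) on the bottom strand
    assert right == End("top3", barcode2.SE)
    assert len(left.seq) == len(barcode.SE)


def test_shared_barcode_exposes_complementary_overhangs(barcode, barcode2):
    f1 = Fragment(id="f1", seq="G" + "GCAT" * 20 + "AAT")
    f2 = Fragment(id="f2", seq="G" + "CCAT" * 20 + "GGT")
    a1 = cliva_activate(_barcoded(f1, barcode, barcode2))
    a2 = cliva_activate(_barcoded(f2, barcode2, barcode))
    # a1's right (top 3') overhang pairs with a2's left (bottom 3') overhang
    assert a1.right_end().seq == a2.left_end().seq == barcode2.SE


def test_unmodified_aoligos_cannot_activate(fragment, barcode, barcode2):
    bf = _barcoded(fragment, barcode, barcode2)
    bf = replace(bf, top_ps=frozenset(), bottom_ps=frozenset())
    with pytest.raises(SimulationError):
        cliva_activate(bf)


# ---------------------------------------------------------------- digestion

def test_notI_linearization_and_conservation():
    noti = get_enzyme("NotI")
    circle = Duplex.circle("G" * 60 + "GCGGCCGC" + "T" * 40)
    (piece,) = digest(circle, [noti])
    assert piece.left_end() == End("top5", "GGCC")
    assert piece.right_end() == End("bot5", "GGCC")

    two = Duplex.circle("G" * 50 + "GCGGCCGC" + "A" * 40 + "GGATCC" + "C" * 30)
    pieces = digest(two, [noti, get_enzyme("BamHI")])
    assert len(pieces) == 2
    assert sum(len(p.top_seq) for p in pieces) == len(two.extent)  # conservation
    # re-ligation of all pieces regenerates the parent circle
    (product,) = assemble(pieces, "re")
    assert product.same_molecule(two.extent)


def test_aatII_three_prime_overhangs():
    aat = get_enzyme("AatII")
    (piece,) = digest(Duplex.circle("G" * 40 + "GACGTC" + "T" * 40), [aat])
    assert piece.left_end().kind == "bot3" and piece.left_end().seq == "ACGT"


# ----------------------------------------------------------------- assembly

def test_five_part_design_single_product(registry):
    # AR, RO, gRNA, UHS, DHS stand-ins with five barcodes, one circular product
    reg = generate_parts(
        FixtureSpec(seed=99, n_fragments=5, n_barcodes=5, fragment_len=(80, 500))
    )
    parts = []
    for f, b in zip(sorted(reg.fragments), sorted(reg.barcodes)):
        parts += [b, f]
    d = AssemblyDesign.from_strings("fivepart", parts)
    product = simulate_design(d, reg)
    frag_features = [ft for ft in product.features if ft.part_type == "fragment"]
    bc_features = [ft for ft in product.features if ft.part_type == "barcode"]
    assert len(frag_features) == 5 and len(bc_features) == 5
    assert product.same_molecule(declarative_product(d, reg))


def test_assembly_ambiguity_and_no_product():
    noti = get_enzyme("NotI")
    two_same = Duplex.circle(
        "G" * 50 + "GCGGCCGC" + "A" * 40 + "GCGGCCGC" + "C" * 30
    )
    with pytest.raises(AmbiguousAssemblyError):
        assemble(digest(two_same, [noti]), "re")
    incompatible = [Duplex.blunt("GCTA" * 30), Duplex.blunt("TTAA" * 30)]
    with pytest.raises(NoCircularProductError):
        assemble(incompatible, "re")


def test_method_agreement_cliva_gibson_infusion(registry, rng):
    d = AssemblyDesign.from_strings(
        "agree", ["N01", "f001", "<N02", "<f002", "N03", "f003"]
    )
    products = {
        m: simulate_design(d, registry, rng=random.Random(1), method=m)
        for m in ("cliva", "gibson", "infusion")
    }
    assert products["cliva"].same_molecule(products["gibson"])
    assert products["cliva"].same_molecule(products["infusion"])


def test_scarless_junctions(registry):
    """Every junction reads barcode-G-core or core-T-barcode, no extra bases."""
    d = AssemblyDesign.from_strings("scar", ["N01", "f001", "N02", "f002"])
    product = simulate_design(d, registry)
    seq2 = product.seq * 2
    for ft in product.features:
        if ft.part_type != "fragment":
            continue
        frag = registry.fragment(ft.part_id)
        assert seq2[ft.start : ft.end] == frag.seq  # full fragment, G..T intact
        up_bc = [f for f in product.features if f.end == ft.start or (ft.start == 0 and f.end == len(product.seq))]
        assert up_bc and up_bc[0].part_type == "barcode"


# --------------------------------------------------------------- colony PCR

def test_colony_pcr_rotation_invariance_and_errors(registry):
    d = AssemblyDesign.from_strings("pcr", ["N01", "f001", "N02", "f002"])
    product = declarative_product(d, registry)
    p1 = registry.fragment("f001").seq[:20]
    p2 = revcomp(registry.fragment("f002").seq[-20:])
    lengths = predict_colony_pcr(product, (p1, p2))
    rotated = AssemblyProduct(seq=product.seq[1000 % len(product.seq):] + product.seq[: 1000 % len(product.seq)])
    assert predict_colony_pcr(rotated, (p1, p2)) == lengths
    with pytest.raises(PrimerNotFoundError):
        predict_colony_pcr(product, (p1, "ACGT" * 5))


# ------------------------------------------------------------------ GenBank

def test_genbank_round_trip(tmp_path, registry):
    d = AssemblyDesign.from_strings("gb", ["N01", "f001", "N02", "<f002"])
    product = declarative_product(d, registry)
    path = tmp_path / "out.gb"
    to_genbank(product, path)
    back = from_genbank(path)
    assert back.same_molecule(product)
    assert len(back.features) == len(product.features)
    flipped = [ft for ft in back.features if ft.part_id == "f002"]
    assert flipped[0].strand == -1  # flipped fragment on the complement strand
    # features tile the circle with no gaps or overlaps
    spans = sorted((ft.start, ft.end) for ft in back.features)
    assert spans[0][0] == 0 and spans[-1][1] == len(back.seq)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        assert e1 == s2
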