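"""Design of the four oligo families of the GT standard.

* **Foligos** create fragments by PCR.  The chemical route uses primers with a
  phosphorothioate (PS) bond after their first base; iodine cleavage of that
  bond later exposes the 1-nt sticky ends.  The enzymatic route prepends a
  Type IIS cassette (6-nt random additional sequence, recognition sequence,
  spacer) so digestion reproduces exactly the same prepared fragment.
* **Noligos** build short fragments (36-59 nt) by direct annealing of two
  plain oligos whose sequences already encode the 1-nt overhangs.
* **Boligos** encode one barcode half each as a 5'-phosphorylated stem-loop
  (hairpin) oligo of at most 90 nt: the loop seals the distal end so the
  barcoded fragment becomes a closed dumbbell with no free ligatable ends,
  and the single unpaired 3' base (G or A) selects which fragment end the
  half ligates to.  Four per barcode: {L,R} half x {G,A} overhang.
* **Aoligos** are the PS-modified primers matching each Boligo's post-loop
  arm; ligation-PCR with an Aoligo pair amplifies correctly barcoded
  fragments, and cleavage at the Aoligos' PS bonds exposes the long SE
  overhangs.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass

import pandas as pd

from .barcodes import REDefinition, choose_enzyme, find_sites, type_iis_panel
from .config import DEFAULT_CONFIG, DesignConfig
from .errors import (
    DesignError,
    InternalSiteError,
    NoRouteError,
    PrimerDesignError,
)
from .parts import Barcode, Fragment, check_dna, complement, melting_temp, revcomp

__all__ = [
    "Oligo",
    "BOLIGO_ROLES",
    "AOLIGO_ROLES",
    "TypeIISPlan",
    "REFoligoDesign",
    "boligo_arms",
    "design_foligos_ps",
    "design_foligos_re",
    "design_noligos",
    "design_boligos",
    "design_aoligos",
    "RouteOptions",
    "RouteChoice",
    "choose_fragment_route",
    "emit_order_sheet",
    "parse_order_sheet",
]

BOLIGO_ROLES = ("BoligoLG", "BoligoLA", "BoligoRG", "BoligoRA")
AOLIGO_ROLES = ("AoligoLG", "AoligoLA", "AoligoRG", "AoligoRA")
_ALL_ROLES = (
    "FoligoF",
    "FoligoR",
    "FoligoRE-F",
    "FoligoRE-R",
    "NoligoG",
    "NoligoA",
) + BOLIGO_ROLES + AOLIGO_ROLES


@dataclass(frozen=True)
class Oligo:
    """A single-stranded DNA oligo with synthesis modifications.

    ``ps_bonds`` holds 1-based backbone bond indices (bond ``i`` joins
    nucleotides ``i`` and ``i+1``); ``phos5`` marks a 5'-phosphate.
    """

    id: str
    seq: str
    role: str
    ps_bonds: frozenset[int] = frozenset()
    phos5: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", check_dna(self.seq))
        object.__setattr__(self, "ps_bonds", frozenset(self.ps_bonds))
        if self.role not in _ALL_ROLES:
            raise DesignError(f"unknown oligo role: {self.role!r}")
        bad = [b for b in self.ps_bonds if not 1 <= b <= len(self.seq) - 1]
        if bad:
            raise DesignError(f"PS bond indices out of range: {bad}")
        if self.role in BOLIGO_ROLES:
            if not self.phos5:
                raise DesignError("Boligos must carry a 5'-phosphate")
            if len(self.seq) > DEFAULT_CONFIG.boligo_max_len:
                raise DesignError(
                    f"Boligo longer than {DEFAULT_CONFIG.boligo_max_len} nt"
                )

    def __len__(self) -> int:
        return len(self.seq)

    def vendor_string(self) -> str:
        """Synthesis-order string: ``*`` marks a PS bond, ``/5Phos/`` a 5'-P."""
        chars = []
        for i, base in enumerate(self.seq, start=1):
            chars.append(base)
            if i in self.ps_bonds:
                chars.append("*")
        return ("/5Phos/" if self.phos5 else "") + "".join(chars)

    @classmethod
    def from_vendor_string(cls, oligo_id: str, text: str, role: str) -> "Oligo":
        phos5 = text.startswith("/5Phos/")
        body = text.removeprefix("/5Phos/")
        seq_chars: list[str] = []
        bonds: set[int] = set()
        for ch in body:
            if ch == "*":
                bonds.add(len(seq_chars))
            else:
                seq_chars.append(ch)
        return cls(id=oligo_id, seq="".join(seq_chars), role=role,
                   ps_bonds=frozenset(bonds), phos5=phos5)


# ------------------------------------------------------------------ Foligos

def _binding_region(template: str, cfg: DesignConfig) -> str:
    """Shortest prefix of ``template`` in the primer length range whose Tm
    reaches the primer threshold."""
    thr = cfg.tm_primer.threshold_c
    for n in range(cfg.primer_min_len, cfg.primer_max_len + 1):
        if n > len(template):
            break
        if melting_temp(template[:n], cfg.tm_primer) >= thr:
            return template[:n]
    raise PrimerDesignError(
        f"no binding length in [{cfg.primer_min_len}, {cfg.primer_max_len}] "
        f"reaches Tm >= {thr} degC"
    )


def design_foligos_ps(
    fragment: Fragment, cfg: DesignConfig | None = None
) -> tuple[Oligo, Oligo]:
    """PS-modified primer pair for amplifying a fragment.

    Each primer is a prefix of the fragment (forward) or of its reverse
    complement (reverse) with a single PS bond between the first and second
    nucleotide -- the bond whose iodine cleavage later removes the terminal
    base and leaves the 1-nt 3' overhangs.
    """
    cfg = cfg or DEFAULT_CONFIG
    _require_valid(fragment, cfg)
    if len(fragment.seq) < 60:
        raise DesignError("PCR route needs a fragment of at least 60 nt")
    fwd = _binding_region(fragment.seq, cfg)
    rev = _binding_region(revcomp(fragment.seq), cfg)
    return (
        Oligo(id=f"{fragment.id}-FoligoF", seq=fwd, role="FoligoF", ps_bonds={1}),
        Oligo(id=f"{fragment.id}-FoligoR", seq=rev, role="FoligoR", ps_bonds={1}),
    )


@dataclass(frozen=True)
class TypeIISPlan:
    """Layout of one enzymatic-route Foligo: AS + RS + SS + binding site.

    The 6-nt additional sequence (AS) is non-functional random padding that
    gives the enzyme room to bind; the spacer (SS) length is enzyme-specific,
    chosen so the cut lands exactly one nucleotide inside the fragment and
    leaves the same 1-nt 3' overhang as the chemical route.
    """

    enzyme: str
    AS: str
    RS: str
    SS: str
    binding: str

    def __post_init__(self) -> None:
        if len(self.AS) != 6:
            raise DesignError("additional sequence must be 6 nt")

    @property
    def primer_seq(self) -> str:
        return self.AS + self.RS + self.SS + self.binding


@dataclass(frozen=True)
class REFoligoDesign:
    foligo_f: Oligo
    foligo_r: Oligo
    plan_f: TypeIISPlan
    plan_r: TypeIISPlan
    enzyme: REDefinition


def _random_padding(
    rng: random.Random, n: int, forbid: list[str], context_after: str
) -> str:
    # regenerate until no forbidden recognition sequence starts inside the
    # padding (sites wholly within the downstream context are not its fault)
    max_rec = max((len(r) for r in forbid), default=0)
    for _ in range(1000):
        pad = "".join(rng.choice("ACGT") for _ in range(n))
        probe = pad + context_after[:max_rec]
        hit = any(
            probe.find(r, 0, len(pad) + len(r) - 1) != -1
            or probe.find(revcomp(r), 0, len(pad) + len(r) - 1) != -1
            for r in forbid
        )
        if not hit:
            return pad
    raise DesignError("could not generate clean random padding")


def design_foligos_re(
    fragment: Fragment,
    enzyme: REDefinition,
    rng: random.Random,
    cfg: DesignConfig | None = None,
) -> REFoligoDesign:
    """Non-modified primer pair carrying a Type IIS cassette.

    Requires the fragment to be free of internal recognition sites of the
    enzyme on either strand; digestion of the amplicon then yields exactly
    the prepared fragment the chemical route would give.
    """
    cfg = cfg or DEFAULT_CONFIG
    _require_valid(fragment, cfg)
    if enzyme.overhang_polarity != "3p" or enzyme.overhang_length != 1:
        raise DesignError(f"{enzyme.name} does not generate 1-nt 3' overhangs")
    if find_sites(fragment.seq, enzyme):
        raise InternalSiteError(
            f"fragment {fragment.id} has an internal {enzyme.name} site"
        )
    ss_len = enzyme.cut_top - len(enzyme.recognition) - 1
    if ss_len < 0:
        raise DesignError(f"{enzyme.name} cuts inside its recognition sequence")
    forbid = [e.recognition for e in type_iis_panel()]

    def one_plan(template: str) -> TypeIISPlan:
        binding = _binding_region(template, cfg)
        ss = _random_padding(rng, ss_len, [enzyme.recognition], binding)
        as_ = _random_padding(rng, 6, forbid, enzyme.recognition)
        return TypeIISPlan(
            enzyme=enzyme.name, AS=as_, RS=enzyme.recognition, SS=ss, binding=binding
        )

    # retry until the whole amplicon carries exactly the two intended sites
    for _ in range(100):
        plan_f = one_plan(fragment.seq)
        plan_r = one_plan(revcomp(fragment.seq))
        amplicon = (
            plan_f.AS + plan_f.RS + plan_f.SS
            + fragment.seq
            + revcomp(plan_r.AS + plan_r.RS + plan_r.SS)
        )
        if len(find_sites(amplicon, enzyme)) == 2:
            break
    else:
        raise DesignError("could not place Type IIS cassettes without extra sites")
    return REFoligoDesign(
        foligo_f=Oligo(
            id=f"{fragment.id}-FoligoRE-F", seq=plan_f.primer_seq, role="FoligoRE-F"
        ),
        foligo_r=Oligo(
            id=f"{fragment.id}-FoligoRE-R", seq=plan_r.primer_seq, role="FoligoRE-R"
        ),
        plan_f=plan_f,
        plan_r=plan_r,
        enzyme=enzyme,
    )


# ------------------------------------------------------------------ Noligos

def design_noligos(
    fragment: Fragment, cfg: DesignConfig | None = None
) -> tuple[Oligo, Oligo]:
    """Two plain oligos that anneal directly into a short prepared fragment.

    The G-Noligo is the fragment without its leading G; the A-Noligo is the
    reverse complement without its leading A; annealing leaves the 1-nt 3'
    overhangs (T on top, C on bottom) ready for barcoding.
    """
    cfg = cfg or DEFAULT_CONFIG
    _require_valid(fragment, cfg)
    if not cfg.fragment_min_len <= len(fragment.seq) <= cfg.noligo_max_len:
        raise DesignError(
            f"Noligo route covers {cfg.fragment_min_len}-{cfg.noligo_max_len} nt; "
            f"fragment {fragment.id} is {len(fragment.seq)} nt"
        )
    return (
        Oligo(id=f"{fragment.id}-NoligoG", seq=fragment.seq[1:], role="NoligoG"),
        Oligo(id=f"{fragment.id}-NoligoA", seq=revcomp(fragment.seq)[1:], role="NoligoA"),
    )


# ------------------------------------------------------------------ Boligos

def boligo_arms(barcode: Barcode, role: str) -> tuple[str, str, str]:
    """(pre-loop arm, post-loop arm, overhang base) for a Boligo role.

    Role names are two letters: the half (L = L+SE, R = SE+R) and the
    unpaired 3' base (G or A).  The L-half hairpin carries the sense arm
    before the loop; the R-half hairpin carries the antisense arm first.
    This arm order is what makes every one of the eight flip configurations
    resolvable with the four stock Boligos.
    """
    if role.startswith("Boligo") or role.startswith("Aoligo"):
        role = role[-2:]
    half, base = role[0], role[1]
    if half not in "LR" or base not in "GA":
        raise DesignError(f"unknown Boligo role: {role!r}")
    if half == "L":
        arm = barcode.left_half
        pre, post = arm, revcomp(arm)
    else:
        arm = barcode.right_half
        pre, post = revcomp(arm), arm
    return pre, post, base


def _check_loop(loop: str, cfg: DesignConfig) -> str:
    loop = check_dna(loop)
    if len(loop) != 6:
        raise DesignError("Boligo loop must be exactly 6 nt")
    # a Watson-Crick pair between the two loop-terminal bases would extend
    # the stem by one and leave only a 4-nt loop
    if loop[0] == complement(loop[-1]):
        raise DesignError("loop terminal bases must not extend the stem")
    return loop


def design_boligos(
    barcode: Barcode, loop: str | None = None, cfg: DesignConfig | None = None
) -> dict[str, Oligo]:
    """The four stem-loop barcoding oligos of a barcode (roles LG, LA, RG, RA)."""
    cfg = cfg or DEFAULT_CONFIG
    _require_valid_barcode(barcode, cfg)
    loop = _check_loop(loop or cfg.loop, cfg)
    out: dict[str, Oligo] = {}
    for half in "LR":
        for base in "GA":
            role = half + base
            pre, post, b = boligo_arms(barcode, role)
            seq = pre + loop + post + b
            if len(seq) > cfg.boligo_max_len:
                raise DesignError(
                    f"Boligo {barcode.id}-{role} exceeds {cfg.boligo_max_len} nt"
                )
            out[role] = Oligo(
                id=f"{barcode.id}-Boligo{role}",
                seq=seq,
                role=f"Boligo{role}",
                phos5=True,
            )
    return out


def design_aoligos(barcode: Barcode, cfg: DesignConfig | None = None) -> dict[str, Oligo]:
    """The four assembling oligos of a barcode.

    Each Aoligo is its Boligo's post-loop arm plus the overhang base -- the
    primer whose 3' end points into the fragment.  PS bonds sit at the SE
    boundary (bond |SE|, so complete cleavage exposes the full SE) and at the
    SE center.
    """
    cfg = cfg or DEFAULT_CONFIG
    _require_valid_barcode(barcode, cfg)
    se_len = len(barcode.SE)
    bonds = frozenset({se_len, math.ceil(se_len / 2)})
    out: dict[str, Oligo] = {}
    for half in "LR":
        for base in "GA":
            role = half + base
            _, post, b = boligo_arms(barcode, role)
            out[role] = Oligo(
                id=f"{barcode.id}-Aoligo{role}",
                seq=post + b,
                role=f"Aoligo{role}",
                ps_bonds=bonds,
            )
    return out


# ------------------------------------------------------------------ routing

@dataclass(frozen=True)
class RouteOptions:
    """User preferences for fragment preparation."""

    allow_ps: bool = True
    prefer_re: bool = False
    panel: tuple[REDefinition, ...] | None = None


@dataclass(frozen=True)
class RouteChoice:
    route: str  # "noligo" | "ps-pcr" | "re-pcr"
    enzyme: REDefinition | None = None


def choose_fragment_route(
    fragment: Fragment,
    options: RouteOptions | None = None,
    cfg: DesignConfig | None = None,
) -> RouteChoice:
    """Pick the preparation route for a fragment.

    Fragments up to 59 nt are annealed from Noligos; longer ones are PCR
    amplified with PS-modified Foligos unless the options ask for (or force)
    the Type IIS route, in which case the first clean panel enzyme is used.
    """
    cfg = cfg or DEFAULT_CONFIG
    options = options or RouteOptions()
    _require_valid(fragment, cfg)
    if len(fragment.seq) <= cfg.noligo_max_len:
        return RouteChoice("noligo")
    panel = list(options.panel) if options.panel is not None else type_iis_panel()
    if options.prefer_re or not options.allow_ps:
        enz = choose_enzyme(fragment, panel)
        if enz is not None:
            return RouteChoice("re-pcr", enz)
        if not options.allow_ps:
            blocking = {
                e.name: find_sites(fragment.seq, e)
                for e in panel
                if find_sites(fragment.seq, e)
            }
            raise NoRouteError(
                f"no panel enzyme applicable to {fragment.id} and the chemical "
                f"route is disallowed",
                blocking_sites=blocking,
            )
    return RouteChoice("ps-pcr")


# -------------------------------------------------------------- order sheet

def emit_order_sheet(oligos: list[Oligo]) -> pd.DataFrame:
    """Vendor order sheet: one row per oligo, deterministically ordered by id."""
    rows = [
        {
            "id": o.id,
            "sequence": o.vendor_string(),
            "length": len(o.seq),
            "role": o.role,
        }
        for o in sorted(oligos, key=lambda o: o.id)
    ]
    return pd.DataFrame(rows, columns=["id", "sequence", "length", "role"])


def parse_order_sheet(sheet: pd.DataFrame) -> list[Oligo]:
    return [
        Oligo.from_vendor_string(row["id"], row["sequence"], row["role"])
        for _, row in sheet.iterrows()
    ]


def _require_valid(fragment: Fragment, cfg: DesignConfig) -> None:
    verdict = fragment.validate(cfg)
    if not verdict.ok:
        raise DesignError(
            f"fragment {fragment.id} violates the grammar: {verdict.violations}"
        )


def _require_valid_barcode(barcode: Barcode, cfg: DesignConfig) -> None:
    verdict = barcode.validate(cfg)
    if not verdict.ok:
        raise DesignError(
            f"barcode {barcode.id} violates the grammar: {verdict.violations}"
        )
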