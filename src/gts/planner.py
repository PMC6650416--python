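"""Declarative plasmid designs and their resolution into stock oligos.

A design is a circular, alternating list of oriented parts (barcode,
fragment, barcode, ...).  Because each fragment and each barcode can be
flipped independently, two fragments can be linked through one barcode in
eight ways -- yet every one of them resolves to a pair of the barcode's four
stock Boligos.  The resolution rule, derived from strand bookkeeping and
verified by the round-trip simulator:

* upstream junction of a fragment: half = R if the barcode is forward else L;
  base = G if the fragment is forward else A;
* downstream junction: half = L if the barcode is forward else R;
  base = A if the fragment is forward else G.

The base rule is equivalent to: the overhang base is G exactly when the
fragment's native 5' (G) end faces the junction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from pathlib import Path

import yaml

from .barcodes import REDefinition, find_sites
from .config import DEFAULT_CONFIG, DesignConfig
from .errors import (
    AmbiguousAssemblyError,
    DesignError,
    DesignValidationError,
    RegistryError,
)
from .parts import Orientation, PartRegistry, Verdict, revcomp
from .simulate import AssemblyProduct, Duplex, PartFeature, assemble, digest

__all__ = [
    "PartUse",
    "AssemblyDesign",
    "JunctionInstruction",
    "FragmentJunctions",
    "validate_design",
    "resolve_junctions",
    "oriented_seq",
    "declarative_product",
    "JunctionCodons",
    "enumerate_junction_codons",
    "ReplaceRequest",
    "DeleteRequest",
    "InsertRequest",
    "EditPlan",
    "plan_edit",
    "SubcloningPlan",
    "plan_re_subcloning",
    "design_to_yaml",
    "design_from_yaml",
]

METHODS = ("cliva", "gibson", "infusion", "goldengate", "re")


@dataclass(frozen=True)
class PartUse:
    """An oriented reference to a registry part."""

    part_id: str
    orientation: str = Orientation.FORWARD

    @classmethod
    def parse(cls, text: str) -> "PartUse":
        text = text.strip()
        if text.startswith("<"):
            return cls(text[1:].strip(), Orientation.FLIPPED)
        return cls(text, Orientation.FORWARD)

    def __str__(self) -> str:
        prefix = "<" if self.orientation == Orientation.FLIPPED else ""
        return prefix + self.part_id

    @property
    def forward(self) -> bool:
        return Orientation.is_forward(self.orientation)

    def flipped(self) -> "PartUse":
        return PartUse(self.part_id, Orientation.flip(self.orientation))


@dataclass
class AssemblyDesign:
    """A circular plasmid design: oriented parts alternating barcode/fragment.

    Stored starting at a barcode; the printed form uses the ``<`` prefix for
    flipped parts.
    """

    name: str
    parts: list[PartUse]
    method: str = "cliva"

    @classmethod
    def from_strings(cls, name: str, parts: list[str], method: str = "cliva") -> "AssemblyDesign":
        return cls(name=name, parts=[PartUse.parse(p) for p in parts], method=method)

    def to_strings(self) -> list[str]:
        return [str(p) for p in self.parts]

    def rotated_to_barcode(self, registry: PartRegistry) -> "AssemblyDesign":
        for offset, part in enumerate(self.parts):
            if registry.part_type(part.part_id) == "barcode":
                return replace(self, parts=self.parts[offset:] + self.parts[:offset])
        raise DesignValidationError(f"design {self.name} contains no barcode")

    def fragment_uses(self, registry: PartRegistry) -> list[tuple[int, PartUse]]:
        return [
            (i, p)
            for i, p in enumerate(self.parts)
            if registry.part_type(p.part_id) == "fragment"
        ]


def oriented_seq(registry: PartRegistry, use: PartUse) -> str:
    if registry.part_type(use.part_id) == "fragment":
        seq = registry.fragment(use.part_id).seq
    else:
        seq = registry.barcode(use.part_id).full_seq
    return seq if use.forward else revcomp(seq)


def validate_design(
    design: AssemblyDesign,
    registry: PartRegistry,
    cfg: DesignConfig | None = None,
) -> Verdict:
    """Check a design against the standard's grammar.

    Verifies the circular alternation rule (every fragment after a barcode
    and vice versa), that every referenced part exists and is itself valid,
    and that the sticky-end cores of the barcodes used are pairwise distinct
    (identical or reverse-complement SEs would scramble the junction
    pairing).  More than the demonstrated seven fragments is a warning, not
    an error.
    """
    cfg = cfg or DEFAULT_CONFIG
    violations: list[str] = []
    warnings: list[str] = []
    if not design.parts:
        return Verdict(("empty-design",))
    if design.method not in METHODS:
        violations.append(f"unknown-method:{design.method}")
    types = []
    for i, part in enumerate(design.parts):
        try:
            types.append(registry.part_type(part.part_id))
        except RegistryError:
            violations.append(f"unknown-part:{i}:{part.part_id}")
            types.append(None)
    if None not in types:
        if len(design.parts) % 2 != 0:
            violations.append("alternation:odd-part-count")
        for i, t in enumerate(types):
            nxt = types[(i + 1) % len(types)]
            if t == nxt:
                violations.append(f"alternation:{i}:{design.parts[i].part_id}")
        for i, (t, part) in enumerate(zip(types, design.parts)):
            if t == "fragment":
                v = registry.fragment(part.part_id).validate(cfg)
            else:
                v = registry.barcode(part.part_id).validate(cfg)
            if not v.ok:
                violations.append(f"invalid-part:{i}:{part.part_id}")
        barcode_uses = [p for p, t in zip(design.parts, types) if t == "barcode"]
        for a, b in itertools.combinations(barcode_uses, 2):
            se_a = registry.barcode(a.part_id).SE
            se_b = registry.barcode(b.part_id).SE
            if a.part_id == b.part_id or se_a == se_b or se_a == revcomp(se_b):
                violations.append(f"duplicate-SE:{a.part_id}:{b.part_id}")
        n_frag = sum(1 for t in types if t == "fragment")
        if n_frag < 1:
            violations.append("no-fragments")
        elif n_frag < 2:
            warnings.append("single-fragment-design")
        if n_frag > cfg.warn_fragments_above:
            warnings.append(f"fragment-count-{n_frag}-above-demonstrated-range")
    return Verdict(tuple(violations), tuple(warnings))


@dataclass(frozen=True)
class JunctionInstruction:
    """Which stock oligo implements one fragment/barcode junction."""

    fragment_id: str
    side: str  # "upstream" | "downstream"
    barcode_id: str
    barcode_orientation: str
    boligo_role: str  # "LG" | "LA" | "RG" | "RA"
    overhang_base: str  # "G" | "A"

    @property
    def aoligo_role(self) -> str:
        return self.boligo_role


@dataclass(frozen=True)
class FragmentJunctions:
    fragment: PartUse
    upstream: JunctionInstruction
    downstream: JunctionInstruction

    @property
    def native_left(self) -> JunctionInstruction:
        """Instruction at the fragment's native 5' (G) end; base is always G."""
        return self.upstream if self.upstream.overhang_base == "G" else self.downstream

    @property
    def native_right(self) -> JunctionInstruction:
        return self.downstream if self.upstream.overhang_base == "G" else self.upstream


def _junction_roles(frag_fwd: bool, bc_fwd: bool, side: str) -> tuple[str, str]:
    if side == "upstream":
        half = "R" if bc_fwd else "L"
        base = "G" if frag_fwd else "A"
    else:
        half = "L" if bc_fwd else "R"
        base = "A" if frag_fwd else "G"
    return half + base, base


def resolve_junctions(
    design: AssemblyDesign, registry: PartRegistry
) -> list[FragmentJunctions]:
    """Resolve every fragment's two junctions to stock Boligo/Aoligo roles.

    The emitted oligo is always one of the adjacent barcode's four stock
    Boligos, whatever combination of part flips the design uses.
    """
    n = len(design.parts)
    out: list[FragmentJunctions] = []
    for i, use in design.fragment_uses(registry):
        up = design.parts[(i - 1) % n]
        dn = design.parts[(i + 1) % n]
        instructions = {}
        for side, bc_use in (("upstream", up), ("downstream", dn)):
            role, base = _junction_roles(use.forward, bc_use.forward, side)
            instructions[side] = JunctionInstruction(
                fragment_id=use.part_id,
                side=side,
                barcode_id=bc_use.part_id,
                barcode_orientation=bc_use.orientation,
                boligo_role=role,
                overhang_base=base,
            )
        out.append(
            FragmentJunctions(
                fragment=use,
                upstream=instructions["upstream"],
                downstream=instructions["downstream"],
            )
        )
    return out


def declarative_product(
    design: AssemblyDesign, registry: PartRegistry, method: str | None = None
) -> AssemblyProduct:
    """The product a design declares: oriented parts concatenated in order.

    This is the declaration side of the round-trip invariant; the
    simulator must reproduce exactly this circle.
    """
    seq_parts: list[str] = []
    features: list[PartFeature] = []
    pos = 0
    for use in design.parts:
        s = oriented_seq(registry, use)
        part_type = registry.part_type(use.part_id)
        kind = (
            registry.fragment(use.part_id).kind if part_type == "fragment" else ""
        )
        features.append(
            PartFeature(
                part_id=use.part_id,
                start=pos,
                end=pos + len(s),
                strand=1 if use.forward else -1,
                part_type=part_type,
                kind=kind,
            )
        )
        seq_parts.append(s)
        pos += len(s)
    return AssemblyProduct(
        seq="".join(seq_parts),
        features=features,
        method=method or design.method,
        name=design.name,
    )


# ------------------------------------------------------- junction codons

_CODONS = ["".join(c) for c in itertools.product("TCAG", repeat=3)]
_STOPS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class JunctionCodons:
    """Codons constructible at a fragment boundary by barcode choice."""

    side: str
    codons: tuple[str, ...]
    stop_codons: tuple[str, ...]
    start_codon_available: bool


def enumerate_junction_codons(side: str) -> JunctionCodons:
    """Codons reachable at the conserved fragment termini.

    The conserved T at a fragment's 3' end can start any of the 16 T-leading
    codons (stop and non-stop) depending on the barcode that follows; the
    conserved G at the 5' end can terminate ATG (start) or 15 other G-ending
    codons.  ``side`` is ``"3T"`` (codons starting with T) or ``"5G"``
    (codons ending with G).
    """
    if side in ("3T", "fragment-3p-T-start"):
        codons = tuple(sorted(c for c in _CODONS if c[0] == "T"))
        return JunctionCodons(
            side="3T",
            codons=codons,
            stop_codons=tuple(c for c in codons if c in _STOPS),
            start_codon_available="ATG" in codons,
        )
    if side in ("5G", "fragment-5p-G-end"):
        codons = tuple(sorted(c for c in _CODONS if c[2] == "G"))
        return JunctionCodons(
            side="5G",
            codons=codons,
            stop_codons=tuple(c for c in codons if c in _STOPS),
            start_codon_available="ATG" in codons,
        )
    raise DesignError(f"unknown junction side: {side!r}")


# ------------------------------------------------------------ edit plans

@dataclass(frozen=True)
class ReplaceRequest:
    target_fragment: str
    replacement: PartUse


@dataclass(frozen=True)
class DeleteRequest:
    target_fragment: str
    neighbor: str | None = None  # defaults to the upstream fragment


@dataclass(frozen=True)
class InsertRequest:
    new_fragment: PartUse
    anchor_fragment: str
    new_barcode: str
    side: str = "after"


@dataclass(frozen=True)
class RebarcodeStep:
    """Barcode one part with two stock Boligo/Aoligo pairs."""

    part: PartUse
    upstream: tuple[str, str]  # (barcode_id, role)
    downstream: tuple[str, str]


@dataclass(frozen=True)
class EditPlan:
    """A plasmid edit expressed purely in stock oligos.

    ``backbone_aoligos`` names the two Aoligos that amplify everything kept
    from the parent plasmid; ``rebarcode`` lists the parts to (re)barcode and
    with which stock roles.  No oligo outside the parts' standard sets is
    ever required.
    """

    kind: str
    backbone_aoligos: tuple[tuple[str, str], tuple[str, str]]
    rebarcode: tuple[RebarcodeStep, ...]
    result: AssemblyDesign


def _find_fragment_index(
    design: AssemblyDesign, registry: PartRegistry, fragment_id: str
) -> int:
    hits = [
        i
        for i, p in design.fragment_uses(registry)
        if p.part_id == fragment_id
    ]
    if not hits:
        raise DesignError(f"fragment {fragment_id!r} not in design {design.name}")
    if len(hits) > 1:
        raise DesignError(f"fragment {fragment_id!r} appears more than once")
    return hits[0]


def _junction_map(design: AssemblyDesign, registry: PartRegistry):
    return {
        (fj.fragment.part_id, "upstream"): fj.upstream
        for fj in resolve_junctions(design, registry)
    } | {
        (fj.fragment.part_id, "downstream"): fj.downstream
        for fj in resolve_junctions(design, registry)
    }


def plan_edit(
    design: AssemblyDesign,
    registry: PartRegistry,
    request: ReplaceRequest | DeleteRequest | InsertRequest,
    cfg: DesignConfig | None = None,
) -> EditPlan:
    """Plan a replace/delete/insert edit using only stock oligos.

    * replace: the backbone (everything but the target) is amplified with the
      outward Aoligos of the two flanking barcodes; the new fragment is
      barcoded with those same barcodes.
    * delete: the target and one adjacent fragment are excised together (with
      the barcode between them) and the adjacent fragment is re-barcoded with
      the outer barcodes, preserving alternation.
    * insert: the anchor fragment is re-barcoded with (outer barcode, new
      barcode) and the new fragment with (new barcode, other outer barcode);
      the backbone is opened at the anchor's junctions.
    """
    cfg = cfg or DEFAULT_CONFIG
    n = len(design.parts)
    jmap = _junction_map(design, registry)

    def outward_aoligos(up_bc_idx: int, dn_bc_idx: int):
        """Aoligo roles that amplify the backbone away from the excised span."""
        prev_frag = design.parts[(up_bc_idx - 1) % n]
        next_frag = design.parts[(dn_bc_idx + 1) % n]
        fwd = jmap[(next_frag.part_id, "upstream")]
        rev = jmap[(prev_frag.part_id, "downstream")]
        return (
            (fwd.barcode_id, fwd.aoligo_role),
            (rev.barcode_id, rev.aoligo_role),
        )

    if isinstance(request, ReplaceRequest):
        idx = _find_fragment_index(design, registry, request.target_fragment)
        result_parts = list(design.parts)
        result_parts[idx] = request.replacement
        result = replace(design, parts=result_parts, name=f"{design.name}-edit")
        backbone = outward_aoligos((idx - 1) % n, (idx + 1) % n)
        rmap = _junction_map(result, registry)
        step = RebarcodeStep(
            part=request.replacement,
            upstream=(
                rmap[(request.replacement.part_id, "upstream")].barcode_id,
                rmap[(request.replacement.part_id, "upstream")].boligo_role,
            ),
            downstream=(
                rmap[(request.replacement.part_id, "downstream")].barcode_id,
                rmap[(request.replacement.part_id, "downstream")].boligo_role,
            ),
        )
        plan = EditPlan("replace", backbone, (step,), result)
    elif isinstance(request, DeleteRequest):
        idx = _find_fragment_index(design, registry, request.target_fragment)
        if request.neighbor is None:
            neighbor_idx = (idx - 2) % n
        else:
            neighbor_idx = _find_fragment_index(design, registry, request.neighbor)
        if (neighbor_idx - idx) % n not in (2, n - 2) or neighbor_idx == idx:
            raise DesignError(
                "delete needs an adjacent fragment to re-barcode (none found)"
            )
        upstream_neighbor = (idx - neighbor_idx) % n == 2
        # span to excise: neighbor .. target (or target .. neighbor), barcode
        # between them included; the neighbor itself returns re-barcoded
        if upstream_neighbor:
            remove = {idx, (idx - 1) % n}
            bc_out_up, bc_out_dn = (neighbor_idx - 1) % n, (idx + 1) % n
        else:
            remove = {idx, (idx + 1) % n}
            bc_out_up, bc_out_dn = (idx - 1) % n, (neighbor_idx + 1) % n
        # backbone excludes the whole neighbor..target span
        prev_frag = design.parts[(bc_out_up - 1) % n]
        next_frag = design.parts[(bc_out_dn + 1) % n]
        backbone = (
            (jmap[(next_frag.part_id, "upstream")].barcode_id,
             jmap[(next_frag.part_id, "upstream")].aoligo_role),
            (jmap[(prev_frag.part_id, "downstream")].barcode_id,
             jmap[(prev_frag.part_id, "downstream")].aoligo_role),
        )
        result_parts = [p for i, p in enumerate(design.parts) if i not in remove]
        result = replace(design, parts=result_parts, name=f"{design.name}-edit")
        rmap = _junction_map(result, registry)
        neighbor_use = design.parts[neighbor_idx]
        step = RebarcodeStep(
            part=neighbor_use,
            upstream=(
                rmap[(neighbor_use.part_id, "upstream")].barcode_id,
                rmap[(neighbor_use.part_id, "upstream")].boligo_role,
            ),
            downstream=(
                rmap[(neighbor_use.part_id, "downstream")].barcode_id,
                rmap[(neighbor_use.part_id, "downstream")].boligo_role,
            ),
        )
        plan = EditPlan("delete", backbone, (step,), result)
    elif isinstance(request, InsertRequest):
        idx = _find_fragment_index(design, registry, request.anchor_fragment)
        registry.barcode(request.new_barcode)  # must exist
        anchor = design.parts[idx]
        result_parts = list(design.parts)
        if request.side == "after":
            insertion = [PartUse(request.new_barcode), request.new_fragment]
            result_parts[idx + 1 : idx + 1] = insertion
        elif request.side == "before":
            insertion = [request.new_fragment, PartUse(request.new_barcode)]
            result_parts[idx:idx] = insertion
        else:
            raise DesignError(f"insert side must be before/after, got {request.side!r}")
        result = replace(design, parts=result_parts, name=f"{design.name}-edit")
        backbone = outward_aoligos((idx - 1) % n, (idx + 1) % n)
        rmap = _junction_map(result, registry)
        steps = []
        for use in (anchor, request.new_fragment):
            steps.append(
                RebarcodeStep(
                    part=use,
                    upstream=(
                        rmap[(use.part_id, "upstream")].barcode_id,
                        rmap[(use.part_id, "upstream")].boligo_role,
                    ),
                    downstream=(
                        rmap[(use.part_id, "downstream")].barcode_id,
                        rmap[(use.part_id, "downstream")].boligo_role,
                    ),
                )
            )
        plan = EditPlan("insert", backbone, tuple(steps), result)
    else:
        raise DesignError(f"unknown edit request: {request!r}")

    verdict = validate_design(plan.result, registry, cfg)
    if not verdict.ok:
        raise DesignValidationError(
            f"edited design is invalid: {verdict.violations}"
        )
    return plan


# ----------------------------------------------------- second-tier RE plans

@dataclass(frozen=True)
class SubcloningPlan:
    """A PCR-free second-tier assembly: digestions plus a single ligation.

    Each source plasmid is digested with the given enzymes and the piece
    containing that source's marker sequence is kept -- the in silico
    counterpart of gel purification; the destination (if any) contributes
    its backbone piece the same way.  The selected pieces must then ligate
    through their overhangs into exactly one circular product.  The
    conventional two-enzyme route and the Golden Gate route differ only in
    which enzymes expose the overhangs; reassembled junctions retain their
    recognition sites, which is what makes modules replaceable later.
    """

    method: str  # "re" | "goldengate"
    sources: tuple[AssemblyProduct, ...]
    source_markers: tuple[str, ...]
    destination: AssemblyProduct | None
    enzymes: tuple[REDefinition, ...]
    dest_marker: str | None = None

    def _select(self, prod: AssemblyProduct, marker: str | None) -> Duplex:
        pieces = digest(Duplex.circle(prod.seq), list(self.enzymes))
        if marker is None:
            return max(pieces, key=len)
        hits = [p for p in pieces if marker in p.extent]
        if len(hits) != 1:
            raise DesignError(
                f"marker matches {len(hits)} pieces of {prod.name or 'input'}"
            )
        return hits[0]

    def execute(self, cfg: DesignConfig | None = None) -> AssemblyProduct:
        cfg = cfg or DEFAULT_CONFIG
        pieces = [
            self._select(prod, marker)
            for prod, marker in zip(self.sources, self.source_markers)
        ]
        if self.destination is not None:
            pieces.append(self._select(self.destination, self.dest_marker))
        products = assemble(pieces, self.method, cfg)
        if len(products) != 1:
            raise AmbiguousAssemblyError(
                f"subcloning yields {len(products)} products"
            )
        product = products[0]
        product.name = f"{self.method}-subclone"
        return product

    def junction_overhangs(self) -> list[str]:
        """Distinct sticky-end sequences the digestions expose (top sense)."""
        overhangs = set()
        inputs = list(self.sources) + ([self.destination] if self.destination else [])
        for prod in inputs:
            for piece in digest(Duplex.circle(prod.seq), list(self.enzymes)):
                for end in (piece.left_end(), piece.right_end()):
                    if end.seq:
                        overhangs.add(end.seq)
        return sorted(overhangs)


def plan_re_subcloning(
    sources: list[AssemblyProduct],
    enzymes: list[REDefinition],
    destination: AssemblyProduct | None,
    module_markers: str | list[str],
    dest_marker: str | None = None,
    method: str = "re",
) -> SubcloningPlan:
    """Validate site availability and return an executable subcloning plan."""
    if isinstance(module_markers, str):
        module_markers = [module_markers]
    if len(module_markers) != len(sources):
        raise DesignError("need one module marker per source plasmid")
    for prod in list(sources) + ([destination] if destination else []):
        for enz in enzymes:
            doubled = prod.seq + prod.seq[: len(enz.recognition) - 1]
            if not find_sites(doubled, enz):
                raise DesignError(
                    f"missing-site: {enz.name} has no site on {prod.name or 'input'}"
                )
    if method == "re" and len(sources) != 1:
        raise DesignError("conventional RE subcloning takes exactly one source")
    if method not in ("re", "goldengate"):
        raise DesignError(f"unknown subcloning method: {method!r}")
    return SubcloningPlan(
        method=method,
        sources=tuple(sources),
        source_markers=tuple(module_markers),
        destination=destination,
        enzymes=tuple(enzymes),
        dest_marker=dest_marker,
    )


# ------------------------------------------------------------------- I/O

def design_to_yaml(design: AssemblyDesign, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(
            {
                "name": design.name,
                "method": design.method,
                "parts": design.to_strings(),
            },
            sort_keys=False,
        )
    )


def design_from_yaml(path: str | Path) -> AssemblyDesign:
    raw = yaml.safe_load(Path(path).read_text())
    return AssemblyDesign.from_strings(
        name=raw["name"], parts=raw["parts"], method=raw.get("method", "cliva")
    )
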