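"""End-to-end execution of a design: oligo design, chemistry, assembly.

This is the round-trip verification the toolkit is built around: for any
valid design, designing the oligos, preparing and barcoding each fragment,
activating the sticky ends and assembling must yield exactly one circular
product whose canonical sequence equals the declarative concatenation of the
oriented parts.  A disagreement is a simulation-mismatch error, never a
silently returned product.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .config import DEFAULT_CONFIG, DesignConfig
from .errors import DesignValidationError, SimulationError
from .oligos import (
    Oligo,
    RouteChoice,
    design_aoligos,
    design_boligos,
    design_foligos_ps,
    design_foligos_re,
    design_noligos,
    choose_fragment_route,
)
from .parts import PartRegistry
from .planner import (
    AssemblyDesign,
    FragmentJunctions,
    declarative_product,
    resolve_junctions,
    validate_design,
)
from .simulate import (
    AssemblyProduct,
    BarcodedFragment,
    assemble,
    barcode_fragment,
    cliva_activate,
    prepare_fragment,
)

__all__ = ["SimulationResult", "simulate_design", "collect_design_oligos"]

_CHEMISTRY_METHODS = {"cliva", "gibson", "infusion"}


@dataclass
class SimulationResult:
    product: AssemblyProduct
    barcoded: list[BarcodedFragment]
    oligos: list[Oligo]
    junctions: list[FragmentJunctions]


def _prepare_oligos(fragment, route: RouteChoice, rng, cfg):
    if route.route == "noligo":
        return design_noligos(fragment, cfg)
    if route.route == "ps-pcr":
        return design_foligos_ps(fragment, cfg)
    if route.route == "re-pcr":
        return design_foligos_re(fragment, route.enzyme, rng, cfg)
    raise SimulationError(f"unknown route {route.route!r}")


def simulate_design(
    design: AssemblyDesign,
    registry: PartRegistry,
    cfg: DesignConfig | None = None,
    rng: random.Random | None = None,
    method: str | None = None,
    route_overrides: dict[str, RouteChoice] | None = None,
    full: bool = False,
) -> AssemblyProduct | SimulationResult:
    """Simulate a design from oligo design to assembled circular product.

    Covers the chemistries where barcode halves drive assembly directly:
    chemical-cleavage long sticky ends (``cliva``) and the overlap methods
    (``gibson``/``infusion``) that use the amplicons' shared SE regions as
    homology.  RE-driven second-tier assemblies go through
    :func:`gts.planner.plan_re_subcloning` instead.

    Returns the verified product annotated with the design's part features
    (or a :class:`SimulationResult` with all intermediates when ``full``).
    """
    cfg = cfg or DEFAULT_CONFIG
    rng = rng or random.Random(0)
    method = method or design.method
    if method not in _CHEMISTRY_METHODS:
        raise SimulationError(
            f"simulate_design covers {sorted(_CHEMISTRY_METHODS)}; "
            f"plan {method!r} assemblies with plan_re_subcloning"
        )
    verdict = validate_design(design, registry, cfg)
    if not verdict.ok:
        raise DesignValidationError(f"invalid design: {verdict.violations}")
    design = design.rotated_to_barcode(registry)

    junctions = resolve_junctions(design, registry)
    boligo_cache: dict[str, dict[str, Oligo]] = {}
    aoligo_cache: dict[str, dict[str, Oligo]] = {}

    def stock(barcode_id: str):
        if barcode_id not in boligo_cache:
            bc = registry.barcode(barcode_id)
            boligo_cache[barcode_id] = design_boligos(bc, cfg.loop, cfg)
            aoligo_cache[barcode_id] = design_aoligos(bc, cfg)
        return boligo_cache[barcode_id], aoligo_cache[barcode_id]

    barcoded: list[BarcodedFragment] = []
    used_oligos: list[Oligo] = []
    route_overrides = route_overrides or {}
    for fj in junctions:
        fragment = registry.fragment(fj.fragment.part_id)
        route = route_overrides.get(fragment.id) or choose_fragment_route(fragment, cfg=cfg)
        route_oligos = _prepare_oligos(fragment, route, rng, cfg)
        prepared = prepare_fragment(fragment, route.route, route_oligos, cfg)
        left, right = fj.native_left, fj.native_right
        left_bol, left_aol = stock(left.barcode_id)
        right_bol, right_aol = stock(right.barcode_id)
        bf = barcode_fragment(
            prepared,
            left_boligo=left_bol[left.boligo_role],
            right_boligo=right_bol[right.boligo_role],
            left_aoligo=left_aol[left.boligo_role],
            right_aoligo=right_aol[right.boligo_role],
        )
        barcoded.append(bf)
        used_oligos += [
            left_bol[left.boligo_role],
            right_bol[right.boligo_role],
            left_aol[left.boligo_role],
            right_aol[right.boligo_role],
        ]
        if isinstance(route_oligos, tuple):
            used_oligos += list(route_oligos)
        else:
            used_oligos += [route_oligos.foligo_f, route_oligos.foligo_r]

    if method == "cliva":
        pieces = [cliva_activate(bf) for bf in barcoded]
    else:
        pieces = [bf.amplicon for bf in barcoded]
    products = assemble(pieces, method, cfg)
    if len(products) != 1:
        raise SimulationError(f"expected one product, got {len(products)}")

    declared = declarative_product(design, registry, method)
    if not products[0].same_molecule(declared):
        raise SimulationError(
            f"simulation mismatch: assembled product differs from the "
            f"declared part concatenation for design {design.name}"
        )
    if full:
        return SimulationResult(
            product=declared, barcoded=barcoded, oligos=used_oligos, junctions=junctions
        )
    return declared


def collect_design_oligos(
    design: AssemblyDesign,
    registry: PartRegistry,
    cfg: DesignConfig | None = None,
    rng: random.Random | None = None,
) -> list[Oligo]:
    """All oligos needed to build a design (for the vendor order sheet)."""
    result = simulate_design(design, registry, cfg, rng, full=True)
    seen: dict[str, Oligo] = {}
    for o in result.oligos:
        seen.setdefault(o.id, o)
    return sorted(seen.values(), key=lambda o: o.id)
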