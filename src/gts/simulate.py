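"""Strand-resolved in silico verification of the barcoding and assembly chemistry.

Every design the planner emits can be executed here nucleotide by nucleotide:
PCR and oligo annealing, cleavage of phosphorothioate bonds, Type IIS and
conventional restriction digestion, Boligo hairpin folding, 1-nt sticky-end
ligation into the closed-dumbbell intermediate, ligation-PCR, sticky-end or
overlap assembly into circular products, and colony-PCR amplicon prediction.

The central data structure is :class:`Duplex`: a double-stranded molecule
stored as the top-strand sequence over the union of both strands (the
"extent") plus the half-open intervals each strand covers, so overhangs and
strand asymmetries fall out of coordinate arithmetic rather than separate
bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .barcodes import REDefinition, find_sites
from .config import DEFAULT_CONFIG, DesignConfig
from .errors import (
    AmbiguousAssemblyError,
    InternalSiteError,
    NoCircularProductError,
    NotAHairpinError,
    OverhangMismatchError,
    PrimerNotFoundError,
    SimulationError,
)
from .oligos import Oligo, REFoligoDesign
from .parts import Fragment, check_dna, complement, normalize_circular, revcomp

__all__ = [
    "End",
    "Duplex",
    "PreparedFragment",
    "Hairpin",
    "BarcodedFragment",
    "PartFeature",
    "AssemblyProduct",
    "prepare_fragment",
    "fold_boligo",
    "barcode_fragment",
    "cliva_activate",
    "digest",
    "assemble",
    "predict_colony_pcr",
    "to_genbank",
    "from_genbank",
]


@dataclass(frozen=True)
class End:
    """One terminus of a linear duplex.

    ``kind`` is ``blunt``, ``sealed`` (hairpin loop), or one of ``top5``,
    ``top3``, ``bot5``, ``bot3`` naming the protruding strand and its free
    terminus; ``seq`` is the overhang in top-strand sense.
    """

    kind: str
    seq: str = ""


@dataclass(frozen=True)
class Duplex:
    """A double-stranded DNA molecule with typed ends.

    ``extent`` is the top-strand sequence over the union of both strands;
    ``top`` and ``bottom`` are the half-open extent intervals each strand
    covers (the bottom strand's own sequence is the reverse complement of its
    extent slice).  ``left_seal``/``right_seal`` hold hairpin-loop sequences
    covalently joining the two strands at that terminus; a molecule sealed at
    both ends is the closed dumbbell produced by Boligo ligation.
    """

    extent: str
    top: tuple[int, int]
    bottom: tuple[int, int]
    circular: bool = False
    left_seal: str | None = None
    right_seal: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "extent", check_dna(self.extent))
        (t0, t1), (b0, b1) = self.top, self.bottom
        if not (0 <= t0 <= t1 <= len(self.extent) and 0 <= b0 <= b1 <= len(self.extent)):
            raise SimulationError("strand intervals outside extent")
        if min(t0, b0) != 0 or max(t1, b1) != len(self.extent):
            raise SimulationError("extent must equal the union of both strands")

    def __len__(self) -> int:
        return len(self.extent)

    @property
    def top_seq(self) -> str:
        return self.extent[self.top[0] : self.top[1]]

    @property
    def bottom_seq(self) -> str:
        """Bottom strand read 5'->3' (its own direction)."""
        return revcomp(self.extent[self.bottom[0] : self.bottom[1]])

    def left_end(self) -> End:
        if self.circular:
            raise SimulationError("a circular molecule has no ends")
        if self.left_seal is not None:
            return End("sealed")
        t0, b0 = self.top[0], self.bottom[0]
        if t0 < b0:
            return End("top5", self.extent[t0:b0])
        if b0 < t0:
            return End("bot3", self.extent[b0:t0])
        return End("blunt")

    def right_end(self) -> End:
        if self.circular:
            raise SimulationError("a circular molecule has no ends")
        if self.right_seal is not None:
            return End("sealed")
        t1, b1 = self.top[1], self.bottom[1]
        if t1 > b1:
            return End("top3", self.extent[b1:t1])
        if b1 > t1:
            return End("bot5", self.extent[t1:b1])
        return End("blunt")

    @property
    def free_ends(self) -> int:
        """Number of unsealed termini (0 for circles and closed dumbbells)."""
        if self.circular:
            return 0
        return (self.left_seal is None) + (self.right_seal is None)

    def flipped(self) -> "Duplex":
        """The same molecule read from the other strand."""
        n = len(self.extent)
        return Duplex(
            extent=revcomp(self.extent),
            top=(n - self.bottom[1], n - self.bottom[0]),
            bottom=(n - self.top[1], n - self.top[0]),
            circular=self.circular,
            left_seal=self.right_seal,
            right_seal=self.left_seal,
        )

    @classmethod
    def blunt(cls, seq: str) -> "Duplex":
        return cls(extent=seq, top=(0, len(seq)), bottom=(0, len(seq)))

    @classmethod
    def circle(cls, seq: str) -> "Duplex":
        return cls(extent=seq, top=(0, len(seq)), bottom=(0, len(seq)), circular=True)


# ------------------------------------------------------------ preparation

@dataclass(frozen=True)
class PreparedFragment:
    """A fragment after route processing: duplex core with the two 1-nt 3'
    overhangs (T at the native 3' end on top, C opposite the native 5' G)."""

    fragment: Fragment
    duplex: Duplex
    route: str


def _expected_prepared(fragment: Fragment) -> Duplex:
    n = len(fragment.seq)
    return Duplex(extent=fragment.seq, top=(1, n), bottom=(0, n - 1))


def prepare_fragment(
    fragment: Fragment,
    route: str,
    oligos,
    cfg: DesignConfig | None = None,
) -> PreparedFragment:
    """Simulate fragment preparation along one of the three routes.

    ``oligos`` is the route-consistent oligo set: an (F, R) Foligo pair for
    ``ps-pcr``, a (G, A) Noligo pair for ``noligo``, or a
    :class:`~gts.oligos.REFoligoDesign` for ``re-pcr``.  All three routes
    yield the identical prepared duplex for the same fragment.
    """
    cfg = cfg or DEFAULT_CONFIG
    expected = _expected_prepared(fragment)
    seq = fragment.seq
    if route == "ps-pcr":
        fol_f, fol_r = oligos
        if not (
            seq.startswith(fol_f.seq)
            and revcomp(seq).startswith(fol_r.seq)
            and fol_f.ps_bonds == frozenset({1})
            and fol_r.ps_bonds == frozenset({1})
        ):
            raise SimulationError("Foligos do not match the fragment (ps-pcr route)")
        # PCR restores the full duplex; iodine cleavage at the single PS bond
        # removes the first nucleotide of each strand
        duplex = expected
    elif route == "noligo":
        nol_g, nol_a = oligos
        if nol_g.seq != seq[1:] or nol_a.seq != revcomp(seq)[1:]:
            raise SimulationError("Noligos do not anneal into this fragment")
        duplex = Duplex(extent=seq, top=(1, len(seq)), bottom=(0, len(seq) - 1))
    elif route == "re-pcr":
        if not isinstance(oligos, REFoligoDesign):
            raise SimulationError("re-pcr route needs a REFoligoDesign")
        enz = oligos.enzyme
        if find_sites(seq, enz):
            raise InternalSiteError(
                f"fragment {fragment.id} has an internal {enz.name} site"
            )
        pf, pr = oligos.plan_f, oligos.plan_r
        amplicon = Duplex.blunt(
            pf.AS + pf.RS + pf.SS + seq + revcomp(pr.AS + pr.RS + pr.SS)
        )
        pieces = digest(amplicon, [enz])
        matching = [p for p in pieces if p.extent == seq]
        if len(matching) != 1:
            raise SimulationError(
                f"Type IIS digestion did not release the fragment cleanly "
                f"({len(pieces)} pieces)"
            )
        duplex = matching[0]
    else:
        raise SimulationError(f"unknown preparation route: {route!r}")
    if duplex != expected:
        raise SimulationError("prepared fragment does not match the expected duplex")
    return PreparedFragment(fragment=fragment, duplex=duplex, route=route)


# ---------------------------------------------------------------- Boligos

@dataclass(frozen=True)
class Hairpin:
    """Fold of a Boligo: stem arms, 6-nt loop, single unpaired 3' base."""

    pre_arm: str
    loop: str
    post_arm: str
    base: str

    @property
    def stem_len(self) -> int:
        return len(self.pre_arm)


def fold_boligo(oligo: Oligo) -> Hairpin:
    """Verify a Boligo folds into the required stem-loop and describe it.

    The oligo must read (arm1)(6-nt loop)(arm2 = revcomp of arm1)(G or A):
    a hairpin whose distal end is sealed by the loop and whose open end has a
    single unpaired 3' base.  A conventional blunt barcode-half oligo fails
    with ``not-a-hairpin``.
    """
    if not oligo.role.startswith("Boligo"):
        raise SimulationError(f"{oligo.id} is not tagged as a Boligo")
    if not oligo.phos5:
        raise SimulationError(f"missing-phosphate: {oligo.id} has no 5'-phosphate")
    s = oligo.seq
    if len(s) < 9 or (len(s) - 7) % 2 != 0:
        raise NotAHairpinError(f"{oligo.id}: length {len(s)} cannot form the stem-loop")
    k = (len(s) - 7) // 2
    pre, loop, post, base = s[:k], s[k : k + 6], s[k + 6 : -1], s[-1]
    if post != revcomp(pre):
        raise NotAHairpinError(f"{oligo.id}: stem arms are not complementary")
    if base not in "GA":
        raise NotAHairpinError(f"{oligo.id}: overhang-not-GA (3' base {base})")
    return Hairpin(pre_arm=pre, loop=loop, post_arm=post, base=base)


@dataclass(frozen=True)
class BarcodedFragment:
    """A fragment carrying one barcode half at each end, after ligation-PCR.

    ``dumbbell`` is the ligation intermediate: both hairpin loops still seal
    the termini, so the molecule has no free ends -- the property that
    prevents tandem attachment of additional barcode halves.  ``amplicon``
    is the linear duplex produced by ligation-PCR with the Aoligo pair, whose
    5' segments (and their PS bonds) derive from the primers.
    """

    fragment_id: str
    amplicon: Duplex
    top_ps: frozenset[int]
    bottom_ps: frozenset[int]
    dumbbell: Duplex


def barcode_fragment(
    prepared: PreparedFragment,
    left_boligo: Oligo,
    right_boligo: Oligo,
    left_aoligo: Oligo,
    right_aoligo: Oligo,
) -> BarcodedFragment:
    """Ligate two Boligo hairpins onto a prepared fragment and amplify.

    ``left`` refers to the fragment's native 5' (G) end, ``right`` to its
    native 3' (T) end.  The left hairpin's unpaired G pairs with the C
    overhang; the right hairpin's A pairs with the T overhang; ligation seals
    at least one strand per junction (the Boligo 5'-phosphate side), giving
    the closed dumbbell, and ligation-PCR with the matching Aoligos yields
    (left half)(full fragment restored)(right half) on the top strand.
    """
    dup = prepared.duplex
    seq = dup.extent
    hl = fold_boligo(left_boligo)
    hr = fold_boligo(right_boligo)
    if dup.left_end() != End("bot3", seq[0]) or dup.right_end() != End("top3", seq[-1]):
        raise SimulationError("molecule is not a prepared fragment")
    if hl.base != seq[0]:
        raise OverhangMismatchError(
            f"{left_boligo.id}: {hl.base} overhang offered to the "
            f"{complement(seq[0])} end"
        )
    if hr.base != complement(seq[-1]):
        raise OverhangMismatchError(
            f"{right_boligo.id}: {hr.base} overhang offered to the {seq[-1]} end"
        )
    top = hl.post_arm + seq + hr.pre_arm
    dumbbell = Duplex(
        extent=top,
        top=(0, len(top)),
        bottom=(0, len(top)),
        left_seal=hl.loop,
        right_seal=hr.loop,
    )
    if left_aoligo.seq != hl.post_arm + hl.base:
        raise SimulationError(
            f"{left_aoligo.id} does not match Boligo {left_boligo.id}"
        )
    if right_aoligo.seq != hr.post_arm + hr.base:
        raise SimulationError(
            f"{right_aoligo.id} does not match Boligo {right_boligo.id}"
        )
    return BarcodedFragment(
        fragment_id=prepared.fragment.id,
        amplicon=Duplex.blunt(top),
        top_ps=left_aoligo.ps_bonds,
        bottom_ps=right_aoligo.ps_bonds,
        dumbbell=dumbbell,
    )


def cliva_activate(barcoded: BarcodedFragment) -> Duplex:
    """Cleave the amplicon at the primers' PS bonds to expose long sticky ends.

    Complete chemical cleavage removes everything up to and including the
    3'-most PS bond of each primer-derived strand, exposing a single-stranded
    3' region equal to the full SE at each end.
    """
    if not barcoded.top_ps or not barcoded.bottom_ps:
        raise SimulationError("amplicon was not made with PS-modified Aoligos")
    n = len(barcoded.amplicon)
    ct = max(barcoded.top_ps)
    cb = max(barcoded.bottom_ps)
    return Duplex(extent=barcoded.amplicon.extent, top=(ct, n), bottom=(0, n - cb))


# -------------------------------------------------------------- digestion

def _enzyme_cuts_circular(seq: str, enzymes: list[REDefinition]) -> list[tuple[int, int]]:
    n = len(seq)
    doubled = seq + seq
    cuts: set[tuple[int, int]] = set()
    for enz in enzymes:
        m = len(enz.recognition)
        for start, strand in find_sites(doubled, enz):
            if start >= n:
                continue
            if strand == "+":
                t, b = start + enz.cut_top, start + enz.cut_bottom
            else:
                t = start + m - enz.cut_bottom
                b = start + m - enz.cut_top
            cuts.add((t % n, b % n))
    return sorted(cuts)


def _enzyme_cuts_linear(dup: Duplex, enzymes: list[REDefinition]) -> list[tuple[int, int]]:
    cuts: set[tuple[int, int]] = set()
    for enz in enzymes:
        m = len(enz.recognition)
        for start, strand in find_sites(dup.extent, enz):
            if strand == "+":
                t, b = start + enz.cut_top, start + enz.cut_bottom
            else:
                t = start + m - enz.cut_bottom
                b = start + m - enz.cut_top
            # a cut is only real if both scissile bonds lie within the strands
            if dup.top[0] < t < dup.top[1] and dup.bottom[0] < b < dup.bottom[1]:
                cuts.add((t, b))
    return sorted(cuts)


def digest(molecule: Duplex, enzymes: list[REDefinition]) -> list[Duplex]:
    """Cut a molecule at every recognition site of the given enzymes.

    Cuts are placed per the enzyme table's strand offsets (mirrored for sites
    found on the bottom strand), producing the correct overhang length and
    polarity.  A circular molecule with n sites yields n linear pieces; total
    length is conserved.
    """
    if molecule.circular:
        seq = molecule.extent
        n = len(seq)
        cuts = _enzyme_cuts_circular(seq, enzymes)
        if not cuts:
            return [molecule]
        doubled = seq + seq
        pieces = []
        for i, (t0, b0) in enumerate(cuts):
            t1, b1 = cuts[(i + 1) % len(cuts)]
            # unroll the wrap-around so coordinates increase monotonically
            shift = n if i + 1 == len(cuts) else 0
            t1 += shift
            b1 += shift
            while t1 < t0 or b1 < b0:  # adjacent cuts may interleave strands
                t1 += n
                b1 += n
            origin = min(t0, b0)
            pieces.append(
                Duplex(
                    extent=doubled[origin : max(t1, b1)],
                    top=(t0 - origin, t1 - origin),
                    bottom=(b0 - origin, b1 - origin),
                )
            )
        return pieces
    cuts = _enzyme_cuts_linear(molecule, enzymes)
    if not cuts:
        return [molecule]
    bounds = [(molecule.top[0], molecule.bottom[0])] + cuts + [
        (molecule.top[1], molecule.bottom[1])
    ]
    pieces = []
    for i in range(len(bounds) - 1):
        (t0, b0), (t1, b1) = bounds[i], bounds[i + 1]
        origin = min(t0, b0)
        pieces.append(
            Duplex(
                extent=molecule.extent[origin : max(t1, b1)],
                top=(t0 - origin, t1 - origin),
                bottom=(b0 - origin, b1 - origin),
                left_seal=molecule.left_seal if i == 0 else None,
                right_seal=molecule.right_seal if i == len(bounds) - 2 else None,
            )
        )
    return pieces


# --------------------------------------------------------------- assembly

@dataclass(frozen=True)
class PartFeature:
    part_id: str
    start: int
    end: int
    strand: int  # +1 forward, -1 flipped
    part_type: str  # "fragment" | "barcode"
    kind: str = ""


@dataclass
class AssemblyProduct:
    """An assembled circular plasmid with part features tiling the circle."""

    seq: str
    features: list[PartFeature] = field(default_factory=list)
    method: str = ""
    name: str = ""

    @property
    def canonical(self) -> str:
        return normalize_circular(self.seq)

    def same_molecule(self, other: "AssemblyProduct | str") -> bool:
        other_seq = other if isinstance(other, str) else other.seq
        return self.canonical == normalize_circular(other_seq)

    def __len__(self) -> int:
        return len(self.seq)


_STICKY_METHODS = {"cliva", "goldengate", "re"}
_OVERLAP_METHODS = {"gibson", "infusion"}


def _sticky_join(a: Duplex, b: Duplex) -> int | None:
    ra, lb = a.right_end(), b.left_end()
    if not ra.seq or ra.seq != lb.seq:
        return None
    if (ra.kind, lb.kind) in (("top3", "bot3"), ("bot5", "top5")):
        return len(ra.seq)
    return None


def _overlap_join(a: Duplex, b: Duplex, min_overlap: int, max_scan: int = 60) -> int | None:
    top = min(max_scan, len(a), len(b))
    for k in range(top, min_overlap - 1, -1):
        if a.extent[-k:] == b.extent[:k]:
            return k
    return None


def assemble(
    pieces: list[Duplex],
    method: str,
    cfg: DesignConfig | None = None,
) -> list[AssemblyProduct]:
    """Join pieces into every possible circular product.

    Builds the junction graph -- sticky-end complementarity for chemical,
    Golden Gate and conventional RE assembly; exact terminal homology of at
    least the configured overlap for the exonuclease/annealing methods -- and
    returns each closed circular path (deduplicated by canonical rotation and
    strand) as a product with single-copy junction sequences.  A junction
    with more than one complementary partner raises ``ambiguous-assembly``;
    no closed path raises ``no-circular-product``.
    """
    cfg = cfg or DEFAULT_CONFIG
    if method in _STICKY_METHODS:
        join = _sticky_join
    elif method in _OVERLAP_METHODS:
        def join(a: Duplex, b: Duplex) -> int | None:
            return _overlap_join(a, b, cfg.overlap_min)
    else:
        raise SimulationError(f"unknown assembly method: {method!r}")
    if not pieces:
        raise NoCircularProductError("no pieces given")

    oriented = [(p, p.flipped()) for p in pieces]

    conflicts = []
    for i, (fwd, flp) in enumerate(oriented):
        for o, a in ((0, fwd), (1, flp)):
            partners = [
                (j, oj)
                for j, pair in enumerate(oriented)
                for oj, b in ((0, pair[0]), (1, pair[1]))
                # (i, flipped) offers this end's own mirror image: pairing
                # with itself is dimerization of two copies, not a junction
                # choice within one product, so it is not counted
                if not (j == i and oj != o) and join(a, b) is not None
            ]
            if len(partners) > 1:
                conflicts.append(((i, o), partners))
    if conflicts:
        raise AmbiguousAssemblyError(
            f"{len(conflicts)} junction end(s) have multiple partners", conflicts
        )

    n = len(pieces)
    start = oriented[0][0]
    circles: dict[str, str] = {}

    def dfs(current: Duplex, acc: str, used: frozenset[int]) -> None:
        if len(used) == n:
            k = join(current, start)
            if k is not None:
                circ = acc[: len(acc) - k]
                circles.setdefault(normalize_circular(circ), circ)
            return
        for j in range(n):
            if j in used:
                continue
            for cand in oriented[j]:
                k = join(current, cand)
                if k is not None:
                    dfs(cand, acc + cand.extent[k:], used | {j})

    dfs(start, start.extent, frozenset({0}))
    if not circles:
        raise NoCircularProductError("pieces do not close into any circle")
    return [
        AssemblyProduct(seq=rep, method=method) for _, rep in sorted(circles.items())
    ]


# ------------------------------------------------------------- colony PCR

def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def predict_colony_pcr(
    product: AssemblyProduct, primer_pair: tuple[str, str]
) -> list[int]:
    """Predicted amplicon lengths for a primer pair on a circular product.

    Primers must match exactly (full length, orientation aware).  Every
    product between a forward site of one primer and a reverse site of the
    other is reported, shortest first; the result is rotation invariant.
    """
    seq = product.seq
    n = len(seq)
    doubled = seq + seq
    p1, p2 = (check_dna(p) for p in primer_pair)

    def sites(p: str) -> tuple[list[int], list[int]]:
        fwd = [i for i in _find_all(doubled, p) if i < n]
        rev = [i + len(p) for i in _find_all(doubled, revcomp(p)) if i < n]
        return fwd, rev

    f1, r1 = sites(p1)
    f2, r2 = sites(p2)
    if not (f1 or r1):
        raise PrimerNotFoundError(f"primer {p1[:12]}... not found on the product")
    if not (f2 or r2):
        raise PrimerNotFoundError(f"primer {p2[:12]}... not found on the product")
    lengths = []
    for fwd_sites, rev_ends in ((f1, r2), (f2, r1)):
        for a in fwd_sites:
            for e in rev_ends:
                lengths.append(((e - a - 1) % n) + 1)
    if not lengths:
        raise SimulationError("primer sites are divergent only: no product")
    return sorted(lengths)


# ----------------------------------------------------------------- GenBank

def _feature_type(kind: str) -> str:
    return "CDS" if kind.lower() in ("gene", "cds") else "misc_feature"


def to_genbank(product: AssemblyProduct, path) -> None:
    """Write an annotated circular GenBank record (lossless re-import)."""
    record = SeqRecord(
        Seq(product.seq),
        id=(product.name or "assembly")[:16] or "assembly",
        name=(product.name or "assembly")[:16] or "assembly",
        description=f"assembled via {product.method}" if product.method else "",
        annotations={"molecule_type": "DNA", "topology": "circular"},
    )
    for ft in product.features:
        record.features.append(
            SeqFeature(
                FeatureLocation(ft.start, ft.end, strand=ft.strand),
                type=_feature_type(ft.kind),
                qualifiers={
                    "label": [ft.part_id],
                    "gts_part_type": [ft.part_type],
                    "gts_kind": [ft.kind],
                },
            )
        )
    SeqIO.write([record], str(path), "genbank")


def from_genbank(path) -> AssemblyProduct:
    record = SeqIO.read(str(path), "genbank")
    features = [
        PartFeature(
            part_id=ft.qualifiers.get("label", ["?"])[0],
            start=int(ft.location.start),
            end=int(ft.location.end),
            strand=int(ft.location.strand or 1),
            part_type=ft.qualifiers.get("gts_part_type", ["?"])[0],
            kind=ft.qualifiers.get("gts_kind", [""])[0],
        )
        for ft in record.features
    ]
    return AssemblyProduct(seq=str(record.seq), features=features, name=record.name)
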