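"""Core part types and sequence primitives of the GT assembly standard.

The GT standard defines exactly two kinds of reusable DNA part:

* **Fragment** -- any sequence longer than 35 nt that starts with ``G`` and
  ends with ``T``.  The two terminal bases are the only conserved sequence and
  become the 1-nt sticky ends used to attach barcode halves.
* **Barcode** -- any sequence of 20-80 nt with the anatomy ``L-SE-R``.  The
  15-20 nt SE (sticky-end) core is shared by the two halves (``L+SE`` and
  ``SE+R``) that flank adjacent fragments and re-pair during assembly.

This module holds those domain types, the grammar validators, and the plain
sequence utilities (reverse complement, nearest-neighbor melting temperature,
canonical form of a circular sequence) everything else builds on.  All
coordinates are 0-based, half-open, on the top strand read 5'->3'.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqUtils import MeltingTemp as _mt

from .config import DEFAULT_CONFIG, DesignConfig, TmConfig
from .errors import MalformedSequenceError, RegistryError

__all__ = [
    "revcomp",
    "complement",
    "gc_fraction",
    "check_dna",
    "melting_temp",
    "normalize_circular",
    "has_self_complementary_run",
    "Verdict",
    "Orientation",
    "Fragment",
    "Barcode",
    "PartRegistry",
    "validate_fragment",
    "validate_barcode",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_DNA = frozenset("ACGT")


def check_dna(seq: str, *, allow_empty: bool = False) -> str:
    """Return ``seq`` uppercased, raising if it is not a plain A/C/G/T string.

    IUPAC ambiguity codes are deliberately rejected: the standard's grammar
    and the strand-level simulator both require fully specified sequences.
    """
    if not isinstance(seq, str):
        raise MalformedSequenceError(f"expected a string, got {type(seq).__name__}")
    seq = seq.upper()
    if not seq:
        if allow_empty:
            return seq
        raise MalformedSequenceError("empty sequence not allowed here")
    bad = set(seq) - _DNA
    if bad:
        raise MalformedSequenceError(f"non-ACGT characters in sequence: {sorted(bad)}")
    return seq


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    """Watson-Crick reverse complement (involution; empty input allowed)."""
    seq = check_dna(seq, allow_empty=True)
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def melting_temp(seq: str, cfg: TmConfig | None = None) -> float:
    """Duplex melting temperature (degC) under the unified nearest-neighbor model.

    Uses the SantaLucia (2004) unified parameter set with the entropic salt
    correction ``dS + 0.368 (N-1) ln[Na+]`` and the configured strand
    concentration.  Deterministic; symmetric under reverse complement.
    """
    cfg = cfg or DEFAULT_CONFIG.tm_se
    seq = check_dna(seq)
    if not 8 <= len(seq) <= 60:
        raise ValueError(f"melting_temp requires 8..60 nt, got {len(seq)}")
    return float(
        _mt.Tm_NN(
            seq,
            nn_table=_mt.DNA_NN4,
            Na=cfg.monovalent_mM,
            dnac1=cfg.oligo_nM,
            dnac2=cfg.oligo_nM,
            selfcomp=(seq == revcomp(seq)),
            saltcorr=5,
        )
    )


def _least_rotation_index(s: str) -> int:
    """Index of the lexicographically least rotation of ``s`` (Booth's algorithm)."""
    n = len(s)
    s2 = s + s
    f = [-1] * (2 * n)
    k = 0
    for j in range(1, 2 * n):
        i = f[j - k - 1]
        while i != -1 and s2[j] != s2[k + i + 1]:
            if s2[j] < s2[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if i == -1 and s2[j] != s2[k]:
            if s2[j] < s2[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return k


def normalize_circular(seq: str) -> str:
    """Canonical representative of a circular double-stranded sequence.

    Returns the lexicographically minimal string over all rotations of ``seq``
    and all rotations of its reverse complement, so any two descriptions of
    the same circular molecule (rotated and/or read from the other strand)
    normalize to the same string.  Idempotent.
    """
    seq = check_dna(seq)
    rc = revcomp(seq)
    i = _least_rotation_index(seq)
    j = _least_rotation_index(rc)
    return min(seq[i:] + seq[:i], rc[j:] + rc[:j])


def has_self_complementary_run(seq: str, min_len: int = 8) -> bool:
    """True if ``seq`` contains a self-reverse-complementary run >= ``min_len``.

    Such a palindromic run lets the sticky-end region anneal to itself (or to
    a second copy of the same molecule) instead of to its partner half, which
    is the failure mode the standard's self-ligation screen guards against.
    Only even lengths can be self-reverse-complementary; scanning at exactly
    the (even-rounded) minimum length is sufficient, since any longer run
    contains one of that length.
    """
    k = min_len + (min_len % 2)
    if k > len(seq):
        return False
    for i in range(len(seq) - k + 1):
        sub = seq[i : i + k]
        if sub == revcomp(sub):
            return True
    return False


@dataclass(frozen=True)
class Verdict:
    """Validation outcome: ``ok`` plus named rule violations and warnings."""

    violations: tuple[str, ...] = ()
    warnings: tuple[str, ...] = ()

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:
        return self.ok


class Orientation:
    """Orientation of a part in a design: forward or flipped (reverse strand).

    The textual form uses a ``<`` prefix for flipped parts, e.g. ``"<RO"``.
    """

    FORWARD = "forward"
    FLIPPED = "flipped"

    @staticmethod
    def flip(orientation: str) -> str:
        if orientation == Orientation.FORWARD:
            return Orientation.FLIPPED
        if orientation == Orientation.FLIPPED:
            return Orientation.FORWARD
        raise ValueError(f"not an orientation: {orientation!r}")

    @staticmethod
    def is_forward(orientation: str) -> bool:
        if orientation not in (Orientation.FORWARD, Orientation.FLIPPED):
            raise ValueError(f"not an orientation: {orientation!r}")
        return orientation == Orientation.FORWARD


@dataclass(frozen=True)
class Fragment:
    """A standard fragment part.

    ``kind`` is a free-text functional tag (promoter, gene, RO, AR, ...).
    ``cds_frame`` is the 0-based offset at which codons start for coding
    fragments (None for non-coding parts).
    """

    id: str
    seq: str
    kind: str = ""
    cds_frame: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", check_dna(self.seq))
        if not self.id or any(c.isspace() for c in self.id):
            raise RegistryError(f"fragment id must be a non-empty token: {self.id!r}")

    def __len__(self) -> int:
        return len(self.seq)

    def validate(self, cfg: DesignConfig | None = None) -> Verdict:
        return validate_fragment(self.seq, cfg)


@dataclass(frozen=True)
class Barcode:
    """A standard barcode part with anatomy ``L-SE-R`` (L and R may be empty)."""

    id: str
    L: str
    SE: str
    R: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "L", check_dna(self.L, allow_empty=True))
        object.__setattr__(self, "SE", check_dna(self.SE))
        object.__setattr__(self, "R", check_dna(self.R, allow_empty=True))
        if not self.id or any(c.isspace() for c in self.id):
            raise RegistryError(f"barcode id must be a non-empty token: {self.id!r}")

    @property
    def full_seq(self) -> str:
        return self.L + self.SE + self.R

    @property
    def left_half(self) -> str:
        """The L+SE half (pairs with the upstream fragment)."""
        return self.L + self.SE

    @property
    def right_half(self) -> str:
        """The SE+R half (pairs with the downstream fragment)."""
        return self.SE + self.R

    def __len__(self) -> int:
        return len(self.full_seq)

    def validate(self, cfg: DesignConfig | None = None) -> Verdict:
        return validate_barcode(self.L, self.SE, self.R, cfg)


def validate_fragment(seq: str, cfg: DesignConfig | None = None) -> Verdict:
    """Check a sequence against the fragment grammar rule.

    A fragment must be longer than 35 nt (i.e. >= 36), start with ``G`` and
    end with ``T``.  Each violated rule is reported by name; malformed
    (non-ACGT) input raises :class:`MalformedSequenceError` instead.
    """
    cfg = cfg or DEFAULT_CONFIG
    seq = check_dna(seq)
    violations: list[str] = []
    if len(seq) < cfg.fragment_min_len:
        violations.append("too-short")
    if not seq.startswith("G"):
        violations.append("must-start-with-G")
    if not seq.endswith("T"):
        violations.append("must-end-with-T")
    return Verdict(tuple(violations))


def validate_barcode(L: str, SE: str, R: str, cfg: DesignConfig | None = None) -> Verdict:
    """Check barcode components against the barcode grammar rule.

    The full sequence must be 20-80 nt; the SE core 15-20 nt; each half
    (``L+SE`` and ``SE+R``) at most 41 nt so that its Boligo hairpin
    (``2*half + 7`` nt) fits the 90-nt cap; and the SE must pass the
    self-ligation screen.
    """
    cfg = cfg or DEFAULT_CONFIG
    L = check_dna(L, allow_empty=True)
    SE = check_dna(SE, allow_empty=True)
    R = check_dna(R, allow_empty=True)
    violations: list[str] = []
    full = len(L) + len(SE) + len(R)
    if full < cfg.barcode_min_len:
        violations.append("too-short")
    if full > cfg.barcode_max_len:
        violations.append("too-long")
    if not cfg.se_min_len <= len(SE) <= cfg.se_max_len:
        violations.append("SE-length")
    if len(L) + len(SE) > cfg.half_max_len:
        violations.append("half-too-long-L")
    if len(SE) + len(R) > cfg.half_max_len:
        violations.append("half-too-long-R")
    if SE and has_self_complementary_run(SE, cfg.palindrome_min):
        violations.append("SE-self-ligation")
    return Verdict(tuple(violations))


class PartRegistry:
    """A registry of fragments and barcodes with unique ids across both maps."""

    def __init__(self, provenance: dict | None = None) -> None:
        self.fragments: dict[str, Fragment] = {}
        self.barcodes: dict[str, Barcode] = {}
        self.provenance: dict = dict(provenance or {})

    def __contains__(self, part_id: str) -> bool:
        return part_id in self.fragments or part_id in self.barcodes

    def __len__(self) -> int:
        return len(self.fragments) + len(self.barcodes)

    def add(self, part: Fragment | Barcode) -> None:
        if part.id in self:
            raise RegistryError(f"duplicate part id: {part.id!r}")
        if isinstance(part, Fragment):
            self.fragments[part.id] = part
        elif isinstance(part, Barcode):
            self.barcodes[part.id] = part
        else:
            raise RegistryError(f"not a standard part: {part!r}")

    def fragment(self, part_id: str) -> Fragment:
        try:
            return self.fragments[part_id]
        except KeyError:
            raise RegistryError(f"unknown fragment id: {part_id!r}") from None

    def barcode(self, part_id: str) -> Barcode:
        try:
            return self.barcodes[part_id]
        except KeyError:
            raise RegistryError(f"unknown barcode id: {part_id!r}") from None

    def part_type(self, part_id: str) -> str:
        if part_id in self.fragments:
            return "fragment"
        if part_id in self.barcodes:
            return "barcode"
        raise RegistryError(f"unknown part id: {part_id!r}")

    def validate_all(self, cfg: DesignConfig | None = None) -> dict[str, Verdict]:
        """Verdict for every part, keyed by id (all-ok registry => all ok)."""
        out: dict[str, Verdict] = {}
        for f in self.fragments.values():
            out[f.id] = f.validate(cfg)
        for b in self.barcodes.values():
            out[b.id] = b.validate(cfg)
        return out

    # ------------------------------------------------------------------ I/O
    _CSV_FIELDS = ["id", "type", "kind", "seq", "L", "SE", "R", "cds_frame"]

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=self._CSV_FIELDS)
            writer.writeheader()
            for f in sorted(self.fragments.values(), key=lambda p: p.id):
                writer.writerow(
                    {
                        "id": f.id,
                        "type": "fragment",
                        "kind": f.kind,
                        "seq": f.seq,
                        "cds_frame": "" if f.cds_frame is None else f.cds_frame,
                    }
                )
            for b in sorted(self.barcodes.values(), key=lambda p: p.id):
                writer.writerow(
                    {"id": b.id, "type": "barcode", "L": b.L, "SE": b.SE, "R": b.R}
                )

    @classmethod
    def from_csv(cls, path: str | Path) -> "PartRegistry":
        reg = cls(provenance={"source": str(path)})
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                if row["type"] == "fragment":
                    frame = row.get("cds_frame") or ""
                    reg.add(
                        Fragment(
                            id=row["id"],
                            seq=row["seq"],
                            kind=row.get("kind") or "",
                            cds_frame=int(frame) if frame != "" else None,
                        )
                    )
                elif row["type"] == "barcode":
                    reg.add(
                        Barcode(
                            id=row["id"],
                            L=row.get("L") or "",
                            SE=row["SE"],
                            R=row.get("R") or "",
                        )
                    )
                else:
                    raise RegistryError(f"unknown part type: {row['type']!r}")
        return reg

    def to_json(self, path: str | Path) -> None:
        payload = {
            "provenance": self.provenance,
            "fragments": [
                {"id": f.id, "seq": f.seq, "kind": f.kind, "cds_frame": f.cds_frame}
                for f in sorted(self.fragments.values(), key=lambda p: p.id)
            ],
            "barcodes": [
                {"id": b.id, "L": b.L, "SE": b.SE, "R": b.R}
                for b in sorted(self.barcodes.values(), key=lambda p: p.id)
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PartRegistry":
        payload = json.loads(Path(path).read_text())
        reg = cls(provenance=payload.get("provenance"))
        for f in payload.get("fragments", []):
            reg.add(Fragment(**f))
        for b in payload.get("barcodes", []):
            reg.add(Barcode(**b))
        return reg

    def fragments_to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(f.seq), id=f.id, description=f.kind)
            for f in sorted(self.fragments.values(), key=lambda p: p.id)
        ]
        SeqIO.write(records, str(path), "fasta")

    def add_fragments_from_fasta(self, path: str | Path, kind: str = "") -> list[str]:
        added = []
        for rec in SeqIO.parse(str(path), "fasta"):
            self.add(Fragment(id=rec.id, seq=str(rec.seq), kind=kind))
            added.append(rec.id)
        return added

    def iter_parts(self) -> Iterator[Fragment | Barcode]:
        yield from self.fragments.values()
        yield from self.barcodes.values()

    @classmethod
    def from_parts(cls, parts: Iterable[Fragment | Barcode]) -> "PartRegistry":
        reg = cls()
        for p in parts:
            reg.add(p)
        return reg
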