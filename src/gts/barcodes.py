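"""Barcode engineering: SE selection, compatibility screens, RE-bearing
barcodes, enzyme choice and silent mutagenesis for the Type IIS route.

The sticky-end (SE) core of a barcode does double duty: in chemical-cleavage
assembly it becomes the long single-stranded overhang, in overlap methods the
homology region, and it can host restriction-enzyme recognition sites so that
finished plasmids can be re-opened without PCR.  This module screens candidate
SEs (melting temperature plus a self-ligation palindrome screen), scores
whole barcode sets for cross-annealing, constructs RE-bearing barcodes, and
removes internal Type IIS sites from coding fragments by silent mutagenesis.
"""

from __future__ import annotations

import csv
import itertools
import random
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from Bio.Data import CodonTable

from .config import DEFAULT_CONFIG, DesignConfig
from .errors import (
    DesignError,
    NoSynonymousFixError,
    SeDesignError,
    UnknownEnzymeError,
)
from .parts import (
    Barcode,
    Fragment,
    PartRegistry,
    check_dna,
    has_self_complementary_run,
    melting_temp,
    revcomp,
)

__all__ = [
    "REDefinition",
    "load_enzyme_table",
    "get_enzyme",
    "type_iis_panel",
    "find_sites",
    "has_internal_site",
    "select_se",
    "longest_complementary_match",
    "CompatReport",
    "screen_barcode_set",
    "choose_enzyme",
    "barcodable_fraction",
    "make_re_barcode",
    "suggest_silent_mutation",
]


@dataclass(frozen=True)
class REDefinition:
    """A restriction enzyme as data: recognition sequence plus cut offsets.

    ``cut_top``/``cut_bottom`` are the phosphodiester bonds broken on the two
    strands, in top-strand coordinates relative to the recognition start (the
    bond at offset ``c`` lies between positions ``c-1`` and ``c``).  A cut
    with ``cut_top < cut_bottom`` leaves 5' overhangs; ``cut_top >
    cut_bottom`` leaves 3' overhangs; equality is blunt.
    """

    name: str
    recognition: str
    cut_top: int
    cut_bottom: int
    panel_1nt: bool = False
    notes: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "recognition", check_dna(self.recognition))

    @property
    def overhang_length(self) -> int:
        return abs(self.cut_top - self.cut_bottom)

    @property
    def overhang_polarity(self) -> str:
        if self.cut_top < self.cut_bottom:
            return "5p"
        if self.cut_top > self.cut_bottom:
            return "3p"
        return "blunt"

    @property
    def is_palindromic(self) -> bool:
        return self.recognition == revcomp(self.recognition)


def load_enzyme_table(path: str | Path | None = None) -> dict[str, REDefinition]:
    """Load enzyme definitions from CSV (bundled table if no path is given)."""
    if path is None:
        source = resources.files("gts.data").joinpath("enzymes.csv").read_text()
    else:
        source = Path(path).read_text()
    table: dict[str, REDefinition] = {}
    for row in csv.DictReader(source.splitlines()):
        enz = REDefinition(
            name=row["name"],
            recognition=row["recognition"],
            cut_top=int(row["cut_top"]),
            cut_bottom=int(row["cut_bottom"]),
            panel_1nt=row.get("panel_1nt", "0") == "1",
            notes=row.get("notes", ""),
        )
        table[enz.name] = enz
    return table


_TABLE: dict[str, REDefinition] | None = None


def _table() -> dict[str, REDefinition]:
    global _TABLE
    if _TABLE is None:
        _TABLE = load_enzyme_table()
    return _TABLE


def get_enzyme(name: str) -> REDefinition:
    try:
        return _table()[name]
    except KeyError:
        raise UnknownEnzymeError(f"enzyme not in table: {name!r}") from None


def type_iis_panel() -> list[REDefinition]:
    """The 1-nt 3'-overhang Type IIS panel, in fixed (tie-break) table order."""
    return [e for e in _table().values() if e.panel_1nt]


def find_sites(seq: str, enzyme: REDefinition) -> list[tuple[int, str]]:
    """All recognition-site occurrences on either strand of a linear sequence.

    Returns ``(start, strand)`` pairs in top-strand coordinates; a ``-``
    strand site means the recognition reads 5'->3' on the bottom strand.
    Palindromic recognitions report one ``+`` hit per position.
    """
    rec = enzyme.recognition
    sites = [(i, "+") for i in _find_all(seq, rec)]
    if not enzyme.is_palindromic:
        sites += [(i, "-") for i in _find_all(seq, revcomp(rec))]
    return sorted(sites)


def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def has_internal_site(fragment: Fragment | str, enzyme: REDefinition) -> bool:
    seq = fragment if isinstance(fragment, str) else fragment.seq
    return bool(find_sites(seq, enzyme))


def select_se(candidate_region: str, cfg: DesignConfig | None = None) -> str:
    """Pick the shortest qualifying SE prefix of a candidate region.

    Scans prefix lengths from the minimum (15 nt) upward and returns the first
    whose melting temperature reaches the SE threshold and which passes the
    self-ligation screen -- so the returned SE is minimal.  If no length in
    range qualifies, raises :class:`SeDesignError` carrying a per-length
    diagnosis.
    """
    cfg = cfg or DEFAULT_CONFIG
    region = check_dna(candidate_region)
    if len(region) < cfg.se_min_len:
        raise SeDesignError(
            f"candidate region shorter than the minimum SE length "
            f"({len(region)} < {cfg.se_min_len})"
        )
    diagnosis: dict[int, str] = {}
    for n in range(cfg.se_min_len, cfg.se_max_len + 1):
        if n > len(region):
            diagnosis[n] = "region-exhausted"
            continue
        se = region[:n]
        if has_self_complementary_run(se, cfg.palindrome_min):
            diagnosis[n] = "self-ligation"
            continue
        if melting_temp(se, cfg.tm_se) < cfg.tm_se.threshold_c:
            diagnosis[n] = "Tm-below-threshold"
            continue
        return se
    raise SeDesignError("no SE length in range qualifies", diagnosis)


def longest_complementary_match(a: str, b: str) -> int:
    """Length of the longest perfect duplex two single strands can form.

    Both inputs are read 5'->3'; the longest contiguous stretch where a
    substring of ``a`` is Watson-Crick antiparallel-complementary to a
    substring of ``b`` equals the longest common substring of ``a`` and
    ``revcomp(b)``.
    """
    b = revcomp(b)
    if not a or not b:
        return 0
    best = 0
    prev = [0] * (len(b) + 1)
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        for j in range(1, len(b) + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                best = max(best, cur[j])
        prev = cur
    return best


@dataclass(frozen=True)
class CompatReport:
    """Pairwise SE cross-annealing scores for a barcode set."""

    scores: dict[tuple[str, str], int]
    offending: tuple[tuple[str, str, str], ...]  # (id_i, id_j, reason)
    threshold: int

    @property
    def compatible(self) -> bool:
        return not self.offending

    def to_dict(self) -> dict:
        return {
            "compatible": self.compatible,
            "threshold": self.threshold,
            "scores": {f"{i}|{j}": s for (i, j), s in sorted(self.scores.items())},
            "offending": [list(t) for t in self.offending],
        }


def screen_barcode_set(
    barcodes: list[Barcode], threshold: int | None = None, cfg: DesignConfig | None = None
) -> CompatReport:
    """Score every barcode pair for sticky-end cross-annealing.

    For each unordered pair, the score is the longest perfect duplex formed
    between any two junction overhangs drawn from {SE, revcomp(SE)} of the two
    barcodes.  A pair is offending if its score reaches the threshold, and a
    duplicated SE (identical, or one the reverse complement of the other) is a
    hard failure regardless of threshold.
    """
    cfg = cfg or DEFAULT_CONFIG
    if threshold is None:
        threshold = cfg.cross_anneal_max
    if len(barcodes) < 2:
        raise DesignError("screen_barcode_set needs at least two barcodes")
    scores: dict[tuple[str, str], int] = {}
    offending: list[tuple[str, str, str]] = []
    for bi, bj in itertools.combinations(barcodes, 2):
        overhangs_i = (bi.SE, revcomp(bi.SE))
        overhangs_j = (bj.SE, revcomp(bj.SE))
        score = max(
            longest_complementary_match(a, b)
            for a in overhangs_i
            for b in overhangs_j
        )
        scores[(bi.id, bj.id)] = score
        if bi.SE == bj.SE or bi.SE == revcomp(bj.SE):
            offending.append((bi.id, bj.id, "duplicate-SE"))
        elif score >= threshold:
            offending.append((bi.id, bj.id, f"cross-anneal-{score}nt"))
    return CompatReport(scores, tuple(offending), threshold)


def choose_enzyme(
    fragment: Fragment | str, panel: list[REDefinition] | None = None
) -> REDefinition | None:
    """First panel enzyme with no internal site on either strand, else None."""
    panel = panel if panel is not None else type_iis_panel()
    for enz in panel:
        if not has_internal_site(fragment, enz):
            return enz
    return None


def barcodable_fraction(
    registry: PartRegistry, panel: list[REDefinition] | None = None
) -> float:
    """Fraction of registry fragments with at least one applicable panel enzyme."""
    panel = panel if panel is not None else type_iis_panel()
    frags = list(registry.fragments.values())
    if not frags:
        raise DesignError("registry has no fragments")
    ok = sum(1 for f in frags if choose_enzyme(f, panel) is not None)
    return ok / len(frags)


def make_re_barcode(
    enzymes: list[REDefinition],
    spacers: list[str] | str,
    rng: random.Random,
    cfg: DesignConfig | None = None,
    bc_id: str = "re-barcode",
    max_tries: int = 200,
) -> Barcode:
    """Build a valid barcode whose flanks carry RE recognition cassettes.

    Each enzyme contributes a ``recognition + spacer`` cassette; cassettes are
    packed into L first, overflowing into R, so that the half-length bounds
    still hold.  The SE core is drawn from seeded random GC-rich sequence and
    must pass the usual SE screens.  For an out-cutting (Type IIS) enzyme the
    spacer receives the cut, so digestion of a plasmid carrying the barcode
    produces the overhang encoded in the spacer.
    """
    cfg = cfg or DEFAULT_CONFIG
    if isinstance(spacers, str):
        spacers = [spacers] * len(enzymes)
    if len(spacers) != len(enzymes):
        raise DesignError("need one spacer per enzyme")
    cassettes = [e.recognition + check_dna(s, allow_empty=True) for e, s in zip(enzymes, spacers)]
    for enz, cassette in zip(enzymes, cassettes):
        # the cut of an out-cutting enzyme must land inside its own cassette
        if enz.cut_top > len(enz.recognition) and len(cassette) < max(enz.cut_top, enz.cut_bottom):
            raise DesignError(
                f"spacer too short for {enz.name}: cut at {enz.cut_top} falls "
                f"outside the {len(cassette)}-nt cassette"
            )
    for _ in range(max_tries):
        se_region = "".join(rng.choice("GCGCAT") for _ in range(cfg.se_max_len + 4))
        try:
            se = select_se(se_region, cfg)
        except SeDesignError:
            continue
        l_budget = cfg.half_max_len - len(se)
        r_budget = cfg.half_max_len - len(se)
        L_parts: list[str] = []
        R_parts: list[str] = []
        used_l = used_r = 0
        feasible = True
        for cassette in cassettes:
            if used_l + len(cassette) <= l_budget:
                L_parts.append(cassette)
                used_l += len(cassette)
            elif used_r + len(cassette) <= r_budget:
                R_parts.append(cassette)
                used_r += len(cassette)
            else:
                feasible = False
                break
        if not feasible:
            raise DesignError("does-not-fit: recognition cassettes exceed barcode bounds")
        bc = Barcode(id=bc_id, L="".join(L_parts), SE=se, R="".join(R_parts))
        verdict = bc.validate(cfg)
        if not verdict.ok:
            continue
        return bc
    raise DesignError(f"could not design an RE barcode in {max_tries} tries")


# --------------------------------------------------------------- mutagenesis

_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]


def _aa(codon: str) -> str:
    if codon in _CODON_TABLE.stop_codons:
        return "*"
    return _CODON_TABLE.forward_table[codon]


_ALL_CODONS = ["".join(c) for c in itertools.product("ACGT", repeat=3)]
_SYNONYMS: dict[str, list[str]] = {}
for _c in _ALL_CODONS:
    _SYNONYMS.setdefault(_aa(_c), []).append(_c)


def translate_cds(seq: str, frame: int) -> str:
    """Translate the in-frame portion of a fragment (standard genetic code)."""
    cds = seq[frame : frame + 3 * ((len(seq) - frame) // 3)]
    return "".join(_aa(cds[i : i + 3]) for i in range(0, len(cds), 3))


def suggest_silent_mutation(
    fragment: Fragment,
    site_span: tuple[int, int],
    enzyme: REDefinition,
    panel: list[REDefinition] | None = None,
    cfg: DesignConfig | None = None,
) -> tuple[Fragment, dict]:
    """Remove an internal recognition site by a minimal synonymous edit.

    Tries single-codon, then two-codon, synonymous substitutions within the
    codons overlapping ``site_span``, ranked by (number of changed
    nucleotides, position of the first change).  The winning edit must destroy
    the target site on both strands, create no new site for any panel enzyme
    anywhere in the fragment, preserve the translation, and leave the fragment
    grammar-valid.  Raises :class:`NoSynonymousFixError` if no edit qualifies.
    """
    cfg = cfg or DEFAULT_CONFIG
    panel = panel if panel is not None else type_iis_panel()
    if enzyme.name not in {e.name for e in panel}:
        panel = panel + [enzyme]
    if fragment.cds_frame is None:
        raise DesignError("fragment has no cds_frame; silent mutagenesis needs one")
    frame = fragment.cds_frame
    seq = fragment.seq
    start, end = site_span
    n_codons = (len(seq) - frame) // 3
    if not (frame <= start < end <= frame + 3 * n_codons):
        raise DesignError("site_span must lie inside the coding region")

    old_sites = {e.name: set(find_sites(seq, e)) for e in panel}

    first_codon = max(0, (start - frame) // 3)
    last_codon = min(n_codons - 1, (end - 1 - frame) // 3)
    codon_ids = list(range(first_codon, last_codon + 1))

    def codon_at(s: str, ci: int) -> str:
        p = frame + 3 * ci
        return s[p : p + 3]

    def substituted(s: str, edits: list[tuple[int, str]]) -> str:
        out = s
        for ci, new in edits:
            p = frame + 3 * ci
            out = out[:p] + new + out[p + 3 :]
        return out

    def edit_cost(edits: list[tuple[int, str]]) -> tuple[int, int]:
        changed, first = 0, len(seq)
        for ci, new in edits:
            old = codon_at(seq, ci)
            for k in range(3):
                if old[k] != new[k]:
                    changed += 1
                    first = min(first, frame + 3 * ci + k)
        return changed, first

    def acceptable(new_seq: str) -> bool:
        if translate_cds(new_seq, frame) != translate_cds(seq, frame):
            return False  # belt-and-braces; synonymous codons guarantee this
        if not new_seq.startswith("G") or not new_seq.endswith("T"):
            return False
        target_left = {s for s in find_sites(new_seq, enzyme) if s[0] < end and s[0] + len(enzyme.recognition) > start}
        if target_left:
            return False
        for e in panel:
            if not set(find_sites(new_seq, e)) <= old_sites[e.name]:
                return False
        return True

    candidates: list[tuple[tuple[int, int], list[tuple[int, str]], str]] = []

    def consider(edits: list[tuple[int, str]]) -> None:
        new_seq = substituted(seq, edits)
        if new_seq != seq and acceptable(new_seq):
            candidates.append((edit_cost(edits), edits, new_seq))

    for ci in codon_ids:
        old = codon_at(seq, ci)
        for alt in _SYNONYMS[_aa(old)]:
            if alt != old:
                consider([(ci, alt)])
    if not candidates:
        for ci, cj in itertools.combinations(codon_ids, 2):
            oi, oj = codon_at(seq, ci), codon_at(seq, cj)
            for ai in _SYNONYMS[_aa(oi)]:
                for aj in _SYNONYMS[_aa(oj)]:
                    if ai != oi and aj != oj:
                        consider([(ci, ai), (cj, aj)])
    if not candidates:
        raise NoSynonymousFixError(
            f"no synonymous edit removes the {enzyme.name} site at {site_span}"
        )
    candidates.sort(key=lambda t: t[0])
    (n_changed, first_pos), edits, new_seq = candidates[0]
    report = {
        "enzyme": enzyme.name,
        "site_span": list(site_span),
        "changed_nt": n_changed,
        "first_change": first_pos,
        "edits": [
            {"codon_index": ci, "old": codon_at(seq, ci), "new": new}
            for ci, new in edits
        ],
    }
    edited = Fragment(
        id=fragment.id, seq=new_seq, kind=fragment.kind, cds_frame=fragment.cds_frame
    )
    return edited, report
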