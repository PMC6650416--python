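"""Seeded synthetic part generation obeying the standard's grammar.

Real registries in this field hold a few hundred fragments (promoters,
genes, origins, markers, homology arms) and a few dozen barcodes.  The
generator emulates that at configurable scale: fragment lengths span the
Noligo range through multi-hundred-nt PCR amplicons, GC content stays in a
realistic mid band, barcodes are built around SEs that pass the melting
temperature and self-ligation screens, and enzyme recognition sites or
coding sequences can be implanted on request.  Everything is deterministic
per seed, and every generated part passes validation by construction.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .barcodes import get_enzyme, select_se
from .config import DEFAULT_CONFIG, DesignConfig
from .errors import DesignError, PrimerDesignError, SeDesignError
from .oligos import design_foligos_ps
from .parts import Barcode, Fragment, PartRegistry, gc_fraction

__all__ = ["FixtureSpec", "generate_parts", "random_fragment", "random_barcode"]

_KINDS = ("promoter", "gene", "RO", "AR", "terminator", "gRNA", "UHS", "DHS")
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic part registry."""

    seed: int = 0
    n_fragments: int = 8
    fragment_len: tuple[int, int] = (36, 400)
    n_barcodes: int = 8
    gc: tuple[float, float] = (0.35, 0.65)
    implant_site: str | None = None  # enzyme name; inserted inside every fragment
    n_cds_fragments: int = 0
    cds_implant_site: str | None = None


def _random_seq(rng: random.Random, n: int, gc: float = 0.5) -> str:
    strong, weak = "GC", "AT"
    return "".join(
        rng.choice(strong) if rng.random() < gc else rng.choice(weak)
        for _ in range(n)
    )


def random_fragment(
    rng: random.Random,
    spec: FixtureSpec,
    frag_id: str,
    kind: str = "",
    cfg: DesignConfig | None = None,
) -> Fragment:
    cfg = cfg or DEFAULT_CONFIG
    lo, hi = spec.fragment_len
    gc_lo, gc_hi = spec.gc
    for _ in range(500):
        n = rng.randint(lo, hi)
        seq = "G" + _random_seq(rng, n - 2, (gc_lo + gc_hi) / 2) + "T"
        if spec.implant_site:
            rec = get_enzyme(spec.implant_site).recognition
            if n - 1 - len(rec) <= 1:
                continue
            pos = rng.randint(1, n - 1 - len(rec))
            seq = seq[:pos] + rec + seq[pos + len(rec) :]
        if not gc_lo <= gc_fraction(seq) <= gc_hi:
            continue
        frag = Fragment(id=frag_id, seq=seq, kind=kind)
        if not frag.validate(cfg).ok:
            continue
        if not _amplifiable(frag, cfg):
            continue
        return frag
    raise DesignError(f"could not generate a fragment satisfying {spec}")


def _amplifiable(frag: Fragment, cfg: DesignConfig) -> bool:
    """PCR-route fragments must admit primers at the configured threshold."""
    if len(frag.seq) < 60:
        return True
    try:
        design_foligos_ps(frag, cfg)
        return True
    except PrimerDesignError:
        return False


def random_cds_fragment(
    rng: random.Random,
    spec: FixtureSpec,
    frag_id: str,
    cfg: DesignConfig | None = None,
) -> Fragment:
    """A coding fragment: G + ATG + codons + stop + T, frame 1.

    If ``cds_implant_site`` is set, the recognition sequence (padded to a
    codon multiple) is inserted at a codon boundary so silent-mutagenesis
    fixtures carry a removable in-frame site.
    """
    cfg = cfg or DEFAULT_CONFIG
    lo, hi = spec.fragment_len
    n_codons = max(4, rng.randint(max(lo, 60), hi) // 3 - 3)
    for _ in range(500):
        codons = []
        while len(codons) < n_codons:
            c = _random_seq(rng, 3, 0.5)
            if c not in _STOPS:
                codons.append(c)
        if spec.cds_implant_site:
            rec = get_enzyme(spec.cds_implant_site).recognition
            pad = (3 - len(rec) % 3) % 3
            cassette = rec + _random_seq(rng, pad, 0.5)
            at = rng.randint(1, len(codons) - 1)
            codons[at:at] = [cassette[i : i + 3] for i in range(0, len(cassette), 3)]
        seq = "G" + "ATG" + "".join(codons) + "TAA" + "T"
        frag = Fragment(id=frag_id, seq=seq, kind="gene", cds_frame=1)
        if frag.validate(cfg).ok and _amplifiable(frag, cfg):
            if spec.cds_implant_site and get_enzyme(spec.cds_implant_site).recognition not in seq:
                continue
            return frag
    raise DesignError(f"could not generate a CDS fragment satisfying {spec}")


def random_barcode(
    rng: random.Random,
    bc_id: str,
    cfg: DesignConfig | None = None,
) -> Barcode:
    cfg = cfg or DEFAULT_CONFIG
    for _ in range(500):
        region = _random_seq(rng, cfg.se_max_len + 6, 0.6)
        try:
            se = select_se(region, cfg)
        except SeDesignError:
            continue
        l_max = cfg.half_max_len - len(se)
        l_len = rng.randint(0, min(12, l_max))
        r_len = rng.randint(0, min(12, l_max))
        # keep the full barcode within its 20-80 nt window
        deficit = cfg.barcode_min_len - (l_len + len(se) + r_len)
        if deficit > 0:
            r_len = min(l_max, r_len + deficit)
        bc = Barcode(
            id=bc_id,
            L=_random_seq(rng, l_len, 0.5),
            SE=se,
            R=_random_seq(rng, r_len, 0.5),
        )
        if bc.validate(cfg).ok:
            return bc
    raise DesignError("could not generate a valid barcode")


def generate_parts(spec: FixtureSpec, cfg: DesignConfig | None = None) -> PartRegistry:
    """Deterministic synthetic registry for the given spec (same seed, same parts)."""
    cfg = cfg or DEFAULT_CONFIG
    rng = random.Random(spec.seed)
    reg = PartRegistry(provenance={"generator": "gts.fixtures", "seed": spec.seed})
    for i in range(spec.n_fragments):
        kind = _KINDS[i % len(_KINDS)]
        reg.add(random_fragment(rng, spec, f"f{i + 1:03d}", kind, cfg))
    for i in range(spec.n_cds_fragments):
        reg.add(random_cds_fragment(rng, spec, f"cds{i + 1:03d}", cfg))
    for i in range(spec.n_barcodes):
        bc = random_barcode(rng, f"N{i + 1:02d}", cfg)
        # regenerate on SE collision with an earlier barcode
        tries = 0
        while any(
            bc.SE == other.SE for other in reg.barcodes.values()
        ) and tries < 100:
            bc = random_barcode(rng, f"N{i + 1:02d}", cfg)
            tries += 1
        reg.add(bc)
    bad = [pid for pid, v in reg.validate_all(cfg).items() if not v.ok]
    if bad:  # post-generation filter; unreachable in practice
        raise DesignError(f"generated invalid parts: {bad}")
    return reg
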