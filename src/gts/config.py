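"""Configuration objects for thresholds used throughout the toolkit.

All tunable numbers live here so that a single YAML file can override them.
Defaults follow the GT standard's published bounds (fragment/barcode/SE length
limits, the 90-nt Boligo cap) plus this package's own numeric choices where the
standard leaves a value open (Tm model parameters and acceptance thresholds,
the self-ligation palindrome bound, the cross-annealing duplex bound).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import yaml

__all__ = ["TmConfig", "DesignConfig", "DEFAULT_CONFIG", "load_config"]


@dataclass(frozen=True)
class TmConfig:
    """Nearest-neighbor melting-temperature model settings.

    Attributes
    ----------
    method:
        Tag of the thermodynamic parameter set.  Only the SantaLucia (2004)
        unified nearest-neighbor table is implemented.
    monovalent_mM:
        Monovalent cation concentration in mM (entropic salt correction).
    oligo_nM:
        Concentration of each strand in nM.
    threshold_c:
        Acceptance threshold in degrees Celsius for the region being designed
        (sticky-end region or primer binding site).
    """

    method: str = "santalucia-2004"
    monovalent_mM: float = 50.0
    oligo_nM: float = 500.0
    threshold_c: float = 48.0

    def __post_init__(self) -> None:
        if self.threshold_c <= 0:
            raise ValueError("Tm acceptance threshold must be positive")


@dataclass(frozen=True)
class DesignConfig:
    """All design thresholds in one place.

    Length bounds (nt) mirror the GT standard: fragments are >35 nt, barcodes
    20-80 nt with a 15-20 nt sticky-end (SE) core, Boligos at most 90 nt.  The
    41-nt cap on each barcode half is derived from the Boligo cap (a hairpin of
    half-length ``h`` is ``2 h + 7`` nt long) and is enforced early, at barcode
    validation, so that oligo design can never fail late.
    """

    tm_se: TmConfig = field(default_factory=lambda: TmConfig(threshold_c=48.0))
    tm_primer: TmConfig = field(default_factory=lambda: TmConfig(threshold_c=60.0))

    fragment_min_len: int = 36
    noligo_max_len: int = 59

    barcode_min_len: int = 20
    barcode_max_len: int = 80
    se_min_len: int = 15
    se_max_len: int = 20
    half_max_len: int = 41

    boligo_max_len: int = 90
    loop: str = "TTTTTT"

    primer_min_len: int = 18
    primer_max_len: int = 30

    palindrome_min: int = 8          # self-ligation screen: reject SEs with a
    cross_anneal_max: int = 10       # self-reverse-complementary run >= this
    overlap_min: int = 15            # Gibson/In-fusion homology minimum
    warn_fragments_above: int = 7


DEFAULT_CONFIG = DesignConfig()


def load_config(path: str | Path) -> DesignConfig:
    """Load a :class:`DesignConfig` from YAML, merging over the defaults.

    Top-level keys map to :class:`DesignConfig` fields; ``tm_se`` and
    ``tm_primer`` are nested mappings with :class:`TmConfig` fields.
    """
    raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict[str, Any] = {}
    for key, value in raw.items():
        if key in ("tm_se", "tm_primer"):
            base = getattr(DEFAULT_CONFIG, key)
            kwargs[key] = replace(base, **value)
        elif hasattr(DEFAULT_CONFIG, key):
            kwargs[key] = value
        else:
            raise KeyError(f"unknown configuration key: {key!r}")
    return replace(DEFAULT_CONFIG, **kwargs)
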