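"""Combinatorial plasmid libraries: expansion, bookkeeping, QC prediction.

A library replaces one or more fragment slots of a template design by choice
sets (alternative parts barcoded the same way) or by operon permutation slots
(all orderings of a gene list, with positional internal barcodes).  The
expansion is the full cartesian product; a slot of n shuffled genes
contributes n! members.
"""

from __future__ import annotations

import itertools
import statistics
from dataclasses import dataclass, replace

from .config import DEFAULT_CONFIG, DesignConfig
from .errors import DesignError, DesignValidationError
from .parts import PartRegistry
from .planner import AssemblyDesign, PartUse, declarative_product, validate_design
from .simulate import predict_colony_pcr

__all__ = [
    "ChoiceSlot",
    "PermutationSlot",
    "LibrarySpec",
    "ExpansionReport",
    "expand_library",
    "screening_depth",
    "AccuracyRecord",
    "compute_accuracy",
    "aggregate_accuracy",
    "library_qc_report",
]


@dataclass(frozen=True)
class ChoiceSlot:
    """One fragment position filled by any of several alternatives."""

    options: tuple[PartUse, ...]


@dataclass(frozen=True)
class PermutationSlot:
    """One fragment position expanded into an operon of shuffled genes.

    ``internal_barcodes[i]`` joins operon positions i and i+1; barcodes are
    positional, so gene identity never changes which barcode is used.
    """

    genes: tuple[str, ...]
    internal_barcodes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.internal_barcodes) != len(self.genes) - 1:
            raise DesignError(
                "permutation slot needs exactly len(genes)-1 internal barcodes"
            )


@dataclass(frozen=True)
class LibrarySpec:
    template: AssemblyDesign
    slots: dict[int, ChoiceSlot | PermutationSlot]


@dataclass(frozen=True)
class ExpansionReport:
    expected_size: int
    actual_size: int
    slot_cardinalities: tuple[int, ...]


def _slot_expansions(slot: ChoiceSlot | PermutationSlot) -> list[list[PartUse]]:
    if isinstance(slot, ChoiceSlot):
        return [[opt] for opt in slot.options]
    expansions = []
    for perm in itertools.permutations(slot.genes):
        segment: list[PartUse] = []
        for i, gene in enumerate(perm):
            segment.append(PartUse(gene))
            if i < len(slot.internal_barcodes):
                segment.append(PartUse(slot.internal_barcodes[i]))
        expansions.append(segment)
    return expansions


def expand_library(
    spec: LibrarySpec,
    registry: PartRegistry,
    cfg: DesignConfig | None = None,
) -> tuple[list[AssemblyDesign], ExpansionReport]:
    """Expand a library spec into every member design, validated.

    Expansion order is deterministic: lexicographic by slot position, then
    option/permutation index, so manifests are reproducible.  Duplicate
    members (possible with degenerate specs) are removed.
    """
    cfg = cfg or DEFAULT_CONFIG
    template = spec.template
    for pos in spec.slots:
        if not 0 <= pos < len(template.parts):
            raise DesignError(f"slot position {pos} outside the template")
        if registry.part_type(template.parts[pos].part_id) != "fragment":
            raise DesignError(f"slot position {pos} is not a fragment slot")
    positions = sorted(spec.slots)
    expansions = [_slot_expansions(spec.slots[p]) for p in positions]
    cardinalities = tuple(len(e) for e in expansions)
    members: list[AssemblyDesign] = []
    seen: set[tuple] = set()
    index = 0
    for combo in itertools.product(*expansions):
        parts: list[PartUse] = []
        fill = dict(zip(positions, combo))
        for i, part in enumerate(template.parts):
            if i in fill:
                parts.extend(fill[i])
            else:
                parts.append(part)
        key = tuple((p.part_id, p.orientation) for p in parts)
        if key in seen:
            continue
        seen.add(key)
        member = replace(
            template, parts=parts, name=f"{template.name}-m{index:04d}"
        )
        verdict = validate_design(member, registry, cfg)
        if not verdict.ok:
            raise DesignValidationError(
                f"library member {member.name} invalid: {verdict.violations}"
            )
        members.append(member)
        index += 1
    expected = 1
    for c in cardinalities:
        expected *= c
    return members, ExpansionReport(expected, len(members), cardinalities)


def screening_depth(library_size: int, multiplier: int = 2) -> int:
    """Colonies to pick: library size times the screening multiplier."""
    if library_size < 1:
        raise DesignError("library size must be at least 1")
    return int(library_size * multiplier)


@dataclass(frozen=True)
class AccuracyRecord:
    """Colony-level bookkeeping of one assembly's two-step validation."""

    colonies_tested: int
    colony_pcr_positive: int
    plasmids_sequenced: int
    sequence_correct: int

    def __post_init__(self) -> None:
        if self.colony_pcr_positive > self.colonies_tested:
            raise DesignError("positives exceed tested colonies")
        if self.sequence_correct > self.plasmids_sequenced:
            raise DesignError("correct plasmids exceed sequenced plasmids")


def compute_accuracy(record: AccuracyRecord) -> dict[str, float]:
    """Assembly accuracy = assembly efficiency x sequencing accuracy.

    Efficiency is the colony-PCR positive rate; sequencing accuracy the
    fraction of sequenced plasmids free of mutation/deletion/insertion.
    """
    if record.colonies_tested <= 0 or record.plasmids_sequenced <= 0:
        raise DesignError("accuracy needs non-zero denominators")
    efficiency = record.colony_pcr_positive / record.colonies_tested
    seq_acc = record.sequence_correct / record.plasmids_sequenced
    return {
        "assembly_efficiency": efficiency,
        "sequencing_accuracy": seq_acc,
        "assembly_accuracy": efficiency * seq_acc,
    }


def aggregate_accuracy(records: list[AccuracyRecord]) -> dict[str, float]:
    values = [compute_accuracy(r)["assembly_accuracy"] for r in records]
    return {
        "n": len(values),
        "mean": statistics.mean(values),
        "median": statistics.median(values),
    }


def library_qc_report(
    members: list[AssemblyDesign],
    registry: PartRegistry,
    primer_pairs: list[tuple[str, str]],
) -> dict:
    """Predicted colony-PCR signatures per member, plus distinguishability.

    For each member and primer pair the predicted amplicon lengths are
    computed on the declared product; members whose signatures agree across
    every pair are flagged as indistinguishable by this QC.
    """
    signatures: dict[str, tuple] = {}
    lengths: dict[str, list[list[int]]] = {}
    for member in members:
        product = declarative_product(member, registry)
        per_pair = [predict_colony_pcr(product, pair) for pair in primer_pairs]
        lengths[member.name] = per_pair
        signatures[member.name] = tuple(tuple(x) for x in per_pair)
    groups: dict[tuple, list[str]] = {}
    for name, sig in signatures.items():
        groups.setdefault(sig, []).append(name)
    indistinguishable = sorted(g for g in groups.values() if len(g) > 1)
    return {
        "amplicon_lengths": lengths,
        "indistinguishable": indistinguishable,
        "all_distinguishable": not indistinguishable,
    }
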