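"""Consensus-register alignment of leucine-rich repeats.

LRR solenoid domains are stacks of rigid 20-30 aa units; in ribonuclease-
inhibitor (RI) class repeats the units strictly alternate between 28 and
29 aa against a single consensus.  Because the units are rigid building
blocks, alignment here is pure register tiling: no gaps or indels inside a
unit, just a choice of starting offset and alternation phase.  The tiling
maximizing the mean per-unit match score is returned, which also lets us
ask where exon-exon borders fall within the repeat register.

Consensus patterns (the RI class ``LxxLxLxx(N/C)xLxxxgoxxLxxoLxzxxxx`` and
the S/T class ``LxxLxLxxNxLxxLpxxoFxzxLxx``) use one code per position;
``(A/B)`` collapses to a single position allowing either class.  The
residue sets behind each code live in a YAML table (``_residue_classes.yaml``)
so alternative conventions can be tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .gene_models import GeneModel, exon_aa_span

__all__ = [
    "RI_CONSENSUS",
    "ST_CONSENSUS",
    "ConsensusPattern",
    "RepeatUnit",
    "RepeatSegmentation",
    "BoundaryPosition",
    "load_residue_classes",
    "parse_consensus",
    "match_residue",
    "align_register",
    "boundary_register",
]

RI_CONSENSUS = "LxxLxLxx(N/C)xLxxxgoxxLxxoLxzxxxx"
ST_CONSENSUS = "LxxLxLxxNxLxxLpxxoFxzxLxx"

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

# codes whose residue set is unconstrained; they do not enter match scores
_WILDCARD_CODES = frozenset({"x", "z"})


def load_residue_classes(path: str | Path | None = None) -> dict[str, frozenset[str]]:
    """Load the code -> allowed-residue-set table (package default or a file)."""
    if path is None:
        text = resources.files("lrrsplice").joinpath("_residue_classes.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw: Mapping[str, str] = yaml.safe_load(text)
    table = {}
    for code, residues in raw.items():
        residues = str(residues)
        table[str(code)] = (
            STANDARD_RESIDUES if residues == "*" else frozenset(residues.upper())
        )
        if not table[str(code)]:
            raise ValueError(f"code {code!r} maps to an empty residue set")
    return table


@dataclass(frozen=True)
class ConsensusPosition:
    code: str  # original code, "(N/C)" kept as "N/C"
    residues: frozenset[str]
    wildcard: bool  # excluded from match scoring


@dataclass(frozen=True)
class ConsensusPattern:
    class_name: str
    positions: tuple[ConsensusPosition, ...]

    @property
    def length_aa(self) -> int:
        return len(self.positions)


def parse_consensus(
    pattern_string: str,
    class_name: str = "RI",
    residue_classes: Mapping[str, frozenset[str]] | None = None,
) -> ConsensusPattern:
    """Parse a consensus string into per-position residue sets.

    Each character is one position; a parenthesized group like ``(N/C)``
    collapses to a single position whose residue set is the union of the
    alternatives.
    """
    table = residue_classes if residue_classes is not None else load_residue_classes()
    positions: list[ConsensusPosition] = []
    i = 0
    while i < len(pattern_string):
        ch = pattern_string[i]
        if ch == "(":
            j = pattern_string.find(")", i)
            if j < 0:
                raise ValueError(f"unclosed '(' at position {i}")
            codes = pattern_string[i + 1 : j].split("/")
            residues: frozenset[str] = frozenset()
            for c in codes:
                if c not in table:
                    raise ValueError(f"unknown consensus code {c!r} at position {i}")
                residues |= table[c]
            positions.append(
                ConsensusPosition("/".join(codes), residues,
                                  wildcard=all(c in _WILDCARD_CODES for c in codes))
            )
            i = j + 1
        else:
            if ch not in table:
                raise ValueError(f"unknown consensus code {ch!r} at position {i}")
            positions.append(
                ConsensusPosition(ch, table[ch], wildcard=ch in _WILDCARD_CODES)
            )
            i += 1
    return ConsensusPattern(class_name, tuple(positions))


def match_residue(
    aa: str,
    code: str,
    residue_classes: Mapping[str, frozenset[str]] | None = None,
) -> bool:
    """Does residue ``aa`` satisfy consensus code ``code``?"""
    table = residue_classes if residue_classes is not None else load_residue_classes()
    if code not in table:
        raise ValueError(f"unknown consensus code {code!r}")
    aa = aa.upper()
    if aa not in STANDARD_RESIDUES:
        warnings.warn(f"nonstandard residue {aa!r} treated as non-matching",
                      stacklevel=2)
        return False
    return aa in table[code]


@dataclass(frozen=True)
class RepeatUnit:
    start_aa: int  # 1-based inclusive, protein coordinates
    end_aa: int
    unit_length: int
    match_score: float


@dataclass
class RepeatSegmentation:
    """A gap-free tiling of a protein segment with consensus repeat units."""

    units: list[RepeatUnit]
    register_offset: int  # aa skipped before the first unit
    overall_score: float
    segment: str
    segment_start_aa: int = 1

    @property
    def span(self) -> tuple[int, int]:
        return self.units[0].start_aa, self.units[-1].end_aa


@dataclass(frozen=True)
class BoundaryPosition:
    boundary_index: int  # 1-based among reported junctions
    upstream_exon: int
    unit_index: int  # 1-based repeat unit
    offset_in_unit: int  # 0-based aa offset within the unit


def _skip_positions(pattern: ConsensusPattern, n_skip: int) -> list[int]:
    """Indices of the consensus positions dropped when a unit is shorter than
    the pattern: the last ``n_skip`` wildcard positions (default designated
    insertion position for 28-aa units = the pattern's final ``x``)."""
    if n_skip == 0:
        return []
    wild = [i for i, p in enumerate(pattern.positions) if p.wildcard]
    if len(wild) < n_skip:
        raise ValueError(
            f"unit shorter than pattern by {n_skip} but only {len(wild)} "
            "wildcard positions available to skip"
        )
    return wild[-n_skip:]


def _score_unit(unit_seq: str, pattern: ConsensusPattern) -> float:
    """Fraction of scored (non-wildcard) consensus positions matched."""
    n_skip = pattern.length_aa - len(unit_seq)
    if n_skip < 0:
        raise ValueError("unit longer than the consensus pattern")
    skipped = set(_skip_positions(pattern, n_skip))
    kept = [p for i, p in enumerate(pattern.positions) if i not in skipped]
    assert len(kept) == len(unit_seq)
    n_scored = 0
    n_matched = 0
    for aa, pos in zip(unit_seq.upper(), kept):
        if pos.wildcard:
            continue
        n_scored += 1
        if aa in pos.residues:
            n_matched += 1
    return n_matched / n_scored if n_scored else 1.0


def align_register(
    protein_segment: str,
    pattern: ConsensusPattern | None = None,
    unit_lengths: Sequence[int] = (28, 29),
    segment_start_aa: int = 1,
) -> RepeatSegmentation:
    """Tile a protein segment with consensus units of the declared lengths.

    All starting offsets ``0..max(unit_lengths)-1`` and all alternation
    phases are tried; units cycle through ``unit_lengths`` starting at the
    phase.  The tiling maximizing the mean unit score wins; ties go to the
    smallest offset, then to the phase starting with the shorter unit.
    Unit coordinates are reported in protein coordinates when the segment's
    position in the protein is given via ``segment_start_aa``.
    """
    if pattern is None:
        pattern = parse_consensus(RI_CONSENSUS)
    unit_lengths = list(unit_lengths)
    if not unit_lengths or min(unit_lengths) < 1:
        raise ValueError("unit_lengths must be positive")
    if len(protein_segment) < min(unit_lengths):
        raise ValueError(
            f"segment of {len(protein_segment)} aa shorter than one unit "
            f"({min(unit_lengths)} aa)"
        )

    best: tuple[float, list[RepeatUnit], int] | None = None
    phases = sorted(range(len(unit_lengths)), key=lambda k: unit_lengths[k])
    for offset in range(max(unit_lengths)):
        for phase in phases:
            pos = offset
            k = phase
            units: list[RepeatUnit] = []
            while pos + unit_lengths[k % len(unit_lengths)] <= len(protein_segment):
                u = unit_lengths[k % len(unit_lengths)]
                seq = protein_segment[pos : pos + u]
                units.append(
                    RepeatUnit(
                        start_aa=segment_start_aa + pos,
                        end_aa=segment_start_aa + pos + u - 1,
                        unit_length=u,
                        match_score=_score_unit(seq, pattern),
                    )
                )
                pos += u
                k += 1
            if not units:
                continue
            mean_score = sum(u.match_score for u in units) / len(units)
            if best is None or mean_score > best[0] + 1e-12:
                best = (mean_score, units, offset)
    if best is None:
        raise ValueError("segment admits no unit tiling")
    score, units, offset = best
    return RepeatSegmentation(
        units=units,
        register_offset=offset,
        overall_score=score,
        segment=protein_segment,
        segment_start_aa=segment_start_aa,
    )


def boundary_register(
    model: GeneModel,
    segmentation: RepeatSegmentation,
) -> list[BoundaryPosition]:
    """Locate each exon-exon border inside the repeat register.

    For every junction between consecutive coding exons lying inside the
    segmented span (both sides contribute codons to the span, so these are
    the domain-internal borders; a gene with a single domain exon has
    none), report the containing repeat unit and the 0-based offset of the
    downstream exon's first residue (first-base rule for split codons)
    within that unit.  In a canonical repeat-modular gene all offsets are
    identical.
    """
    if model.protein_seq is not None:
        lo = segmentation.segment_start_aa
        sub = model.protein_seq[lo - 1 : lo - 1 + len(segmentation.segment)]
        if sub != segmentation.segment:
            raise ValueError(
                "segmentation does not match the model's protein at the "
                f"stated position {lo}"
            )
    span_lo, span_hi = segmentation.span
    boundaries: list[BoundaryPosition] = []
    coding = [e.index for e in model.exons if e.coding_length_bp > 0]
    for upstream, downstream in zip(coding, coding[1:]):
        aa = exon_aa_span(model, downstream)
        up_aa = exon_aa_span(model, upstream)
        if aa is None or up_aa is None:
            continue
        first_aa = aa[0]
        if not (span_lo <= first_aa <= span_hi) or up_aa[1] < span_lo:
            continue
        for k, unit in enumerate(segmentation.units, start=1):
            if unit.start_aa <= first_aa <= unit.end_aa:
                boundaries.append(
                    BoundaryPosition(
                        boundary_index=len(boundaries) + 1,
                        upstream_exon=upstream,
                        unit_index=k,
                        offset_in_unit=first_aa - unit.start_aa,
                    )
                )
                break
    return boundaries
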