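"""Exon-skipping isoform enumeration and protein consequences.

Skipping a frame-preserving exon (length divisible by 3) deletes an exact
block of codons; skipping a frame-shifting exon scrambles the downstream
frame, usually producing a premature stop.  This module enumerates skip
isoforms of a gene model, translates their spliced CDS (premature stops
are detected by translation, never assumed absent), computes RT-PCR
amplicon lengths between anchor exons, and reports basic protein
properties (length and average mass) for the products.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .gene_models import GeneModel, translate_cds

__all__ = [
    "SpliceIsoform",
    "FrameshiftReport",
    "ProteinProperties",
    "enumerate_skip_isoforms",
    "translate_isoform",
    "cdna_amplicon_length",
    "protein_properties",
    "isoform_table",
    "write_isoform_fasta",
]

WATER_DA = 18.02


@dataclass
class SpliceIsoform:
    """One exon-skipping isoform of a base transcript."""

    transcript_id: str
    skipped_exons: frozenset[int]
    frame_preserving: bool
    cdna_length_bp: int
    protein_length_aa: int | None = None
    protein_seq: str | None = None
    premature_stop: bool = False

    @property
    def label(self) -> str:
        if not self.skipped_exons:
            return f"{self.transcript_id}:FL"
        return f"{self.transcript_id}:d" + "_".join(
            str(i) for i in sorted(self.skipped_exons)
        )


@dataclass(frozen=True)
class FrameshiftReport:
    """Consequence of a frame-shifting skip: where the frame breaks and what
    truncated product results."""

    first_shifted_codon: int  # 1-based protein position of first out-of-frame codon
    truncated_protein: str


@dataclass(frozen=True)
class ProteinProperties:
    length_aa: int
    average_mass_da: float


def _skipped_coding(model: GeneModel, skipped: Iterable[int]) -> int:
    return sum(model.exons[i - 1].coding_length_bp for i in skipped)


def enumerate_skip_isoforms(
    model: GeneModel,
    max_skipped: int = 2,
    internal_only: bool = True,
    translate: bool = True,
) -> list[SpliceIsoform]:
    """All isoforms skipping 1..max_skipped exons, in lexicographic order of
    the skipped set.

    Terminal exons are excluded by default (they carry UTR/promoter roles).
    ``max_skipped`` greater than the candidate count is capped with a
    warning.  When the model carries its CDS sequence the protein product
    is attached.
    """
    n = len(model.exons)
    if internal_only:
        if n < 3:
            raise ValueError("internal_only enumeration needs >= 3 exons")
        candidates = list(range(2, n))
    else:
        candidates = list(range(1, n + 1))
    if max_skipped >= len(candidates):
        warnings.warn(
            f"max_skipped={max_skipped} >= {len(candidates)} candidate exons; capped",
            stacklevel=2,
        )
        max_skipped = len(candidates)
    isoforms = []
    for k in range(1, max_skipped + 1):
        for combo in combinations(candidates, k):
            skipped = frozenset(combo)
            frame_ok = _skipped_coding(model, skipped) % 3 == 0
            cdna = model.total_exonic_length - sum(
                model.exons[i - 1].full_length_bp for i in skipped
            )
            iso = SpliceIsoform(
                transcript_id=model.transcript_id,
                skipped_exons=skipped,
                frame_preserving=frame_ok,
                cdna_length_bp=cdna,
            )
            if translate and model.cds_seq is not None:
                result = translate_isoform(model, iso)
                if isinstance(result, str):
                    iso.protein_seq = result
                    iso.protein_length_aa = len(result)
                    full_stop_free = len(result) == (
                        model.total_coding_length
                        - _skipped_coding(model, skipped)
                    ) // 3 - (1 if model.stop_in_cds else 0)
                    iso.premature_stop = not full_stop_free
                else:
                    iso.protein_seq = result.truncated_protein
                    iso.protein_length_aa = None
                    iso.premature_stop = True
            isoforms.append(iso)
    return isoforms


def translate_isoform(
    model: GeneModel, isoform: SpliceIsoform
) -> str | FrameshiftReport:
    """Translate the spliced CDS of an isoform.

    Frame-preserving skips return the protein (translation stops at any
    premature stop codon, so introduced stops are reported by a shortened
    product rather than assumed absent).  Frame-shifting skips return a
    FrameshiftReport locating the first out-of-frame codon.
    """
    if model.cds_seq is None:
        raise ValueError(
            f"{model.transcript_id}: model carries no CDS sequence; cannot translate"
        )
    segments = []
    shift_at_nt: int | None = None  # spliced-CDS offset where the frame first breaks
    offset = 0
    cum_phase = 0
    for exon in model.exons:
        seg = model.exon_coding_segment(exon.index)
        if exon.index in isoform.skipped_exons:
            if len(seg) % 3 != 0 and shift_at_nt is None:
                shift_at_nt = offset
            cum_phase = (cum_phase + len(seg)) % 3
        else:
            segments.append(seg)
            offset += len(seg)
    spliced = "".join(segments)
    frame_ok = (
        model.total_coding_length - _skipped_coding(model, isoform.skipped_exons)
    ) % 3 == 0
    if frame_ok:
        prot = translate_cds(spliced, stop_included=model.stop_in_cds)
        if "*" in prot:  # premature stop introduced at the new junction
            prot = prot.split("*")[0]
        return prot
    # frame-shifting: the first out-of-frame codon is the one containing the
    # junction left by the first frame-breaking skipped exon
    assert shift_at_nt is not None
    first_bad_codon = shift_at_nt // 3 + 1
    prot = translate_cds(spliced[: 3 * (len(spliced) // 3)], stop_included=False)
    truncated = prot.split("*")[0]
    return FrameshiftReport(first_shifted_codon=first_bad_codon,
                            truncated_protein=truncated)


def cdna_amplicon_length(
    model: GeneModel,
    isoform: SpliceIsoform,
    left_anchor_exon: int,
    right_anchor_exon: int,
) -> int:
    """Spliced length from the 5' end of the left anchor exon to the 3' end
    of the right anchor exon — the RT-PCR amplicon with primers on the
    anchor exons."""
    if left_anchor_exon >= right_anchor_exon:
        raise ValueError("left anchor must be 5' of right anchor")
    if {left_anchor_exon, right_anchor_exon} & isoform.skipped_exons:
        raise ValueError("anchor exon is skipped in this isoform")
    total = 0
    for exon in model.exons:
        if exon.index < left_anchor_exon or exon.index > right_anchor_exon:
            continue
        if exon.index in isoform.skipped_exons:
            continue
        total += exon.full_length_bp
    return total


def protein_properties(protein_seq: str) -> ProteinProperties:
    """Length and average molecular mass (Da) of a protein sequence."""
    if not protein_seq:
        raise ValueError("empty protein sequence")
    bad = set(protein_seq.upper()) - set("ACDEFGHIKLMNPQRSTVWY")
    if bad:
        raise ValueError(f"nonstandard residues: {sorted(bad)}")
    mass = ProteinAnalysis(protein_seq.upper()).molecular_weight()
    return ProteinProperties(length_aa=len(protein_seq), average_mass_da=float(mass))


def isoform_table(model: GeneModel, isoforms: Sequence[SpliceIsoform]) -> pd.DataFrame:
    """Tabular summary of isoforms (the TSV interface)."""
    rows = []
    for iso in isoforms:
        rows.append(
            {
                "transcript_id": iso.transcript_id,
                "skipped_exons": ",".join(map(str, sorted(iso.skipped_exons))),
                "frame_preserving": iso.frame_preserving,
                "cdna_length_bp": iso.cdna_length_bp,
                "protein_length_aa": iso.protein_length_aa,
                "premature_stop": iso.premature_stop,
            }
        )
    return pd.DataFrame(rows)


def write_isoform_fasta(isoforms: Sequence[SpliceIsoform], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iso in isoforms:
            if iso.protein_seq:
                fh.write(f">{iso.label}\n{iso.protein_seq}\n")
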