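"""Gene models with coding-frame awareness.

Transcript structures are represented as ordered exons on the coding
strand, each carrying its full (exonic) length, the portion inside the
CDS, and the codon phase at its coding start.  Internally all genomic
intervals are 0-based half-open; GTF I/O converts to and from the
standard 1-based inclusive convention.

The protein<->exon coordinate mapping implemented here assigns a codon
that is split across an exon junction to the exon containing the codon's
FIRST base.  This makes the intersection of protein-coordinate domain
annotations (e.g. SMART LRR spans) with exons deterministic.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GenomicInterval",
    "Exon",
    "GeneModel",
    "DomainAnnotation",
    "GtfParseError",
    "read_gene_models",
    "write_gtf",
    "read_domain_annotations",
    "write_domain_annotations",
    "protein_to_exon",
    "exon_aa_span",
]


class GtfParseError(ValueError):
    """Raised for a malformed GTF line; the message names the line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval on one strand."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Exon:
    """One exon of a transcript, ranked 5'->3' on the coding strand.

    ``start_phase`` is the codon position (0, 1 or 2) of the exon's first
    coding base: 0 means the exon starts a fresh codon.
    """

    transcript_id: str
    index: int  # 1-based rank in transcript, 5'->3'
    interval: GenomicInterval
    full_length_bp: int
    coding_length_bp: int
    start_phase: int

    def __post_init__(self) -> None:
        if self.full_length_bp != self.interval.length:
            raise ValueError("full_length_bp must equal interval length")
        if not (0 <= self.coding_length_bp <= self.full_length_bp):
            raise ValueError("coding_length_bp outside [0, full_length_bp]")
        if self.start_phase not in (0, 1, 2):
            raise ValueError("start_phase must be 0, 1 or 2")


@dataclass
class GeneModel:
    """A transcript: ordered exons, CDS extent and (optionally) its protein.

    ``cds_start``/``cds_end`` are 0-based half-open bounds on the spliced
    transcript.  ``cds_seq`` (spliced CDS nucleotides, stop included when
    ``stop_in_cds``) is carried by synthetic models so isoforms can be
    translated; models read from GTF alone do not have it.
    """

    gene_id: str
    gene_name: str
    transcript_id: str
    exons: list[Exon]
    cds_start: int
    cds_end: int
    protein_seq: str | None = None
    cds_seq: str | None = None
    stop_in_cds: bool = True
    canonical: bool = True
    cds_frame_ok: bool = True

    def __post_init__(self) -> None:
        for rank, exon in enumerate(self.exons, start=1):
            if exon.index != rank:
                raise ValueError("exon indices must be consecutive from 1")
        total = self.total_coding_length
        self.cds_frame_ok = total % 3 == 0
        if self.protein_seq is not None and self.cds_frame_ok:
            n_codons = total // 3
            expected = n_codons - 1 if self.stop_in_cds else n_codons
            if len(self.protein_seq) != expected:
                raise ValueError(
                    f"protein length {len(self.protein_seq)} inconsistent with "
                    f"CDS of {total} bp (stop_in_cds={self.stop_in_cds})"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].interval.chrom

    @property
    def strand(self) -> str:
        return self.exons[0].interval.strand

    @property
    def total_exonic_length(self) -> int:
        return sum(e.full_length_bp for e in self.exons)

    @property
    def total_coding_length(self) -> int:
        return sum(e.coding_length_bp for e in self.exons)

    @property
    def coding_exon_indices(self) -> list[int]:
        return [e.index for e in self.exons if e.coding_length_bp > 0]

    def coding_offset_of_exon(self, index: int) -> int:
        """CDS nucleotide offset (0-based) at which exon ``index`` starts coding."""
        return sum(e.coding_length_bp for e in self.exons[: index - 1])

    def exon_coding_segment(self, index: int) -> str:
        """Spliced-CDS nucleotides contributed by exon ``index``."""
        if self.cds_seq is None:
            raise ValueError(f"{self.transcript_id}: no CDS sequence attached")
        off = self.coding_offset_of_exon(index)
        return self.cds_seq[off : off + self.exons[index - 1].coding_length_bp]

    @property
    def protein_length(self) -> int:
        if self.protein_seq is None:
            raise ValueError(f"{self.transcript_id}: no protein attached")
        return len(self.protein_seq)


@dataclass(frozen=True)
class DomainAnnotation:
    """Protein-coordinate domain span with a class accession (e.g. SM00369)."""

    protein_id: str
    domain_class: str
    start_aa: int  # 1-based inclusive
    end_aa: int

    def __post_init__(self) -> None:
        if not (1 <= self.start_aa <= self.end_aa):
            raise ValueError("require 1 <= start_aa <= end_aa")


# ---------------------------------------------------------------------------
# coordinate mapping


def exon_aa_span(model: GeneModel, exon_index: int) -> tuple[int, int] | None:
    """Range of codons (1-based, inclusive) whose first base lies in the exon.

    Returns ``None`` for exons with no codon first base (non-coding exons,
    or exons too short to host a codon start).  Split codons follow the
    first-base rule.
    """
    exon = model.exons[exon_index - 1]
    if exon.coding_length_bp == 0:
        return None
    c = model.coding_offset_of_exon(exon_index)
    c_end = c + exon.coding_length_bp
    aa_first = c // 3 + 1 if c % 3 == 0 else c // 3 + 2
    aa_last = (c_end - 1) // 3 + 1
    # restrict to real codons (exclude the stop codon from protein space)
    n_aa = model.total_coding_length // 3 - (1 if self_stop(model) else 0)
    aa_last = min(aa_last, n_aa)
    if aa_first > aa_last:
        return None
    return aa_first, aa_last


def self_stop(model: GeneModel) -> bool:
    return model.stop_in_cds


def protein_to_exon(model: GeneModel, aa_pos: int) -> tuple[int, int]:
    """Map a 1-based protein position to (exon index, codon offset in exon).

    The exon is the one containing the first nucleotide of codon ``aa_pos``;
    the offset is 0-based among the codons assigned to that exon.
    """
    n_aa = model.total_coding_length // 3 - (1 if model.stop_in_cds else 0)
    if model.protein_seq is not None:
        n_aa = len(model.protein_seq)
    if not (1 <= aa_pos <= n_aa):
        raise ValueError(f"aa_pos {aa_pos} outside protein 1..{n_aa}")
    first_base = 3 * (aa_pos - 1)
    cum = 0
    for exon in model.exons:
        if exon.coding_length_bp == 0:
            continue
        if cum <= first_base < cum + exon.coding_length_bp:
            span = exon_aa_span(model, exon.index)
            assert span is not None
            return exon.index, aa_pos - span[0]
        cum += exon.coding_length_bp
    raise AssertionError("unreachable: aa_pos inside validated range")


# ---------------------------------------------------------------------------
# GTF I/O


def _validate_gtf_lines(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise GtfParseError(
                f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
            )
        try:
            start, end = int(fields[3]), int(fields[4])
        except ValueError as exc:
            raise GtfParseError(f"line {lineno}: non-integer coordinates") from exc
        if start < 1 or end < start:
            raise GtfParseError(f"line {lineno}: invalid coordinate range {start}-{end}")
        if fields[6] not in {"+", "-", "."}:
            raise GtfParseError(f"line {lineno}: invalid strand {fields[6]!r}")


def read_gene_models(
    gtf_path: str | Path,
    protein_fasta_path: str | Path | None = None,
) -> list[GeneModel]:
    """Read exon/CDS features from a GTF into GeneModels.

    Exon indices are assigned 5'->3' on the coding strand (index 1 is the
    5'-most exon of the mRNA, not the lowest genomic coordinate).  Coding
    lengths and phases are computed from CDS features.  Proteins are
    attached by transcript id when a FASTA is supplied.  Transcripts whose
    CDS is not divisible by 3 are flagged (``cds_frame_ok=False``), never
    dropped.
    """
    gtf_path = Path(gtf_path)
    text = gtf_path.read_text()
    _validate_gtf_lines(text)
    db = gffutils.create_db(
        text,
        dbfn=":memory:",
        from_string=True,
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    proteins: dict[str, str] = {}
    if protein_fasta_path is not None:
        for rec in SeqIO.parse(str(protein_fasta_path), "fasta"):
            proteins[rec.id] = str(rec.seq)

    by_tx: dict[str, dict[str, list]] = {}
    meta: dict[str, dict[str, str]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tx = feat.attributes["transcript_id"][0]
        slot = by_tx.setdefault(tx, {"exon": [], "CDS": []})
        slot[feat.featuretype].append(feat)
        meta.setdefault(
            tx,
            {
                "gene_id": feat.attributes.get("gene_id", [tx])[0],
                "gene_name": feat.attributes.get("gene_name", [tx])[0],
            },
        )

    models = []
    for tx, feats in by_tx.items():
        exon_feats = sorted(feats["exon"], key=lambda f: f.start)
        if not exon_feats:
            continue
        strand = exon_feats[0].strand
        if strand == "-":
            exon_feats = exon_feats[::-1]
        cds_ivs = [(f.start - 1, f.end) for f in feats["CDS"]]  # to 0-based half-open

        exons: list[Exon] = []
        phase = 0
        utr5 = 0
        seen_coding = False
        for rank, f in enumerate(exon_feats, start=1):
            iv = GenomicInterval(f.seqid, f.start - 1, f.end, strand)
            coding = sum(
                max(0, min(iv.end, ce) - max(iv.start, cs)) for cs, ce in cds_ivs
            )
            exons.append(
                Exon(
                    transcript_id=tx,
                    index=rank,
                    interval=iv,
                    full_length_bp=iv.length,
                    coding_length_bp=coding,
                    start_phase=phase if coding else 0,
                )
            )
            phase = (phase + coding) % 3
            if coding and not seen_coding:
                seen_coding = True
                # offset of first coding base within this exon, strand-aware
                if strand == "+":
                    cds_lo = min(cs for cs, _ in cds_ivs if cs < iv.end and _ > iv.start)
                    utr5 += max(0, cds_lo - iv.start)
                else:
                    cds_hi = max(ce for cs, ce in cds_ivs if ce > iv.start and cs < iv.end)
                    utr5 += max(0, iv.end - cds_hi)
            elif not seen_coding:
                utr5 += iv.length

        total_cds = sum(e.coding_length_bp for e in exons)
        protein = proteins.get(tx)
        stop_in_cds = True
        if protein is not None and total_cds % 3 == 0:
            stop_in_cds = total_cds // 3 == len(protein) + 1
        model = GeneModel(
            gene_id=meta[tx]["gene_id"],
            gene_name=meta[tx]["gene_name"],
            transcript_id=tx,
            exons=exons,
            cds_start=utr5,
            cds_end=utr5 + total_cds,
            protein_seq=protein,
            stop_in_cds=stop_in_cds,
        )
        if not model.cds_frame_ok:
            warnings.warn(
                f"{tx}: CDS length {total_cds} not divisible by 3; flagged",
                stacklevel=2,
            )
        models.append(model)
    return models


def _gtf_attrs(model: GeneModel) -> str:
    return (
        f'gene_id "{model.gene_id}"; transcript_id "{model.transcript_id}"; '
        f'gene_name "{model.gene_name}";'
    )


def write_gtf(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write exon and CDS features (1-based inclusive) for the given models."""
    lines = []
    for m in models:
        attrs = _gtf_attrs(m)
        for e in m.exons:
            iv = e.interval
            lines.append(
                f"{iv.chrom}\tlrrsplice\texon\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attrs}"
            )
            if e.coding_length_bp > 0:
                # coding sub-interval inside the exon, strand-aware
                off5 = _coding_offset5(m, e)
                if iv.strand == "+":
                    cs = iv.start + off5
                    ce = cs + e.coding_length_bp
                else:
                    ce = iv.end - off5
                    cs = ce - e.coding_length_bp
                frame = (3 - e.start_phase) % 3
                lines.append(
                    f"{iv.chrom}\tlrrsplice\tCDS\t{cs + 1}\t{ce}\t.\t"
                    f"{iv.strand}\t{frame}\t{attrs}"
                )
    Path(path).write_text("\n".join(lines) + "\n")


def _coding_offset5(model: GeneModel, exon: Exon) -> int:
    """5' offset of the coding sub-interval within an exon (UTR5 on first exon)."""
    prior_full = sum(e.full_length_bp for e in model.exons[: exon.index - 1])
    prior_coding = model.coding_offset_of_exon(exon.index)
    if prior_coding == 0:
        return model.cds_start - prior_full
    return 0


# ---------------------------------------------------------------------------
# domain annotation TSV


def read_domain_annotations(path: str | Path) -> list[DomainAnnotation]:
    df = pd.read_csv(path, sep="\t")
    required = {"protein_id", "domain_class", "start_aa", "end_aa"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"domain TSV missing columns: {sorted(missing)}")
    return [
        DomainAnnotation(
            protein_id=row.protein_id,
            domain_class=row.domain_class,
            start_aa=int(row.start_aa),
            end_aa=int(row.end_aa),
        )
        for row in df.itertuples()
    ]


def write_domain_annotations(domains: Iterable[DomainAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "protein_id": d.protein_id,
                "domain_class": d.domain_class,
                "start_aa": d.start_aa,
                "end_aa": d.end_aa,
            }
            for d in domains
        ]
    ).to_csv(path, sep="\t", index=False)


def translate_cds(cds_seq: str, stop_included: bool = True) -> str:
    """Translate a spliced CDS; strips the terminal stop when present."""
    prot = str(Seq(cds_seq).translate())
    if stop_included and prot.endswith("*"):
        prot = prot[:-1]
    return prot
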