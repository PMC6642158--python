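"""Synthetic inputs with ground truth for every pipeline stage.

The generators build repeat-modular gene models in which everything the
downstream analyses estimate is known exactly by construction: which exons
encode LRR units (and are therefore frame-preserving multiples of 3 bp),
where every exon border falls within the repeat register, what every skip
isoform's cDNA and protein look like, which junction counts correspond to a
chosen true inclusion level, and which single-cell detection patterns arise
from chosen burst kinetics.  All randomness flows from one explicit seed
per call; residues, codons and decoy exon lengths are integer draws from a
``numpy`` Generator so output is reproducible across platforms.

The default gene spec mirrors the canonical NLR architecture: a ribonuclease-
inhibitor-class LRR domain in which every domain exon is 171 bp and encodes
two repeats strictly alternating between 28 and 29 aa, flanked by non-repeat
exons (PYD/NACHT-like stand-ins) and terminal UTRs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from . import lrr_consensus as lc
from .gene_models import (
    DomainAnnotation,
    Exon,
    GeneModel,
    GenomicInterval,
    write_domain_annotations,
    write_gtf,
)
from .psi_quant import junctions_for_exon

__all__ = [
    "LrrGeneSpec",
    "CohortSpec",
    "GeneTruth",
    "SyntheticGene",
    "CohortFixture",
    "make_lrr_gene",
    "make_decoy_gene",
    "make_gene_cohort",
    "default_cohort_spec",
    "simulate_junction_reads",
]

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODONS_FOR: dict[str, list[str]] = {}
for _codon, _aa in sorted(_STANDARD_TABLE.forward_table.items()):
    _CODONS_FOR.setdefault(_aa, []).append(_codon)
_RESIDUES = sorted(_CODONS_FOR)

# canonical residue used when a consensus position is constrained
_CANONICAL = {"L": "L", "N": "N", "C": "C", "F": "F", "g": "G", "o": "A", "p": "S"}


@dataclass(frozen=True)
class LrrGeneSpec:
    """Blueprint of a repeat-modular gene.

    Defaults give the canonical architecture: 9 domain exons of 171 bp, each
    encoding two LRR units alternating 28/29 aa, with every exon border at
    register offset 0.  ``perturbations`` move the 3' junction of an exon by
    the given number of bp (the exon grows, its 3' neighbour shrinks; the
    CDS and protein are unchanged) - a +1 shift makes that exon
    frame-shifting, a +3 shift moves one border within the repeat register.
    """

    gene_name: str = "NLRP3L"
    n_domain_exons: int = 9
    repeats_per_exon: int = 2
    unit_lengths_aa: tuple[int, ...] = (28, 29)
    n_upstream_flank: int = 3
    n_downstream_flank: int = 1
    flank_coding_bp_range: tuple[int, int] = (100, 320)
    utr_bp: tuple[int, int] = (200, 300)  # 5' and 3' UTR lengths
    boundary_offset_aa: int = 0
    perturbations: tuple[tuple[int, int], ...] = ()
    chrom: str = "chrS"
    gene_start: int = 1000
    strand: str = "+"
    consensus: str = lc.RI_CONSENSUS


@dataclass(frozen=True)
class GeneTruth:
    """Ground truth of a synthetic gene, for parameter-recovery tests."""

    gene_name: str
    transcript_id: str
    domain_exon_indices: tuple[int, ...]
    exon_full_bp: tuple[int, ...]
    exon_coding_bp: tuple[int, ...]
    frame_preserving: tuple[bool, ...]
    domain_span_aa: tuple[int, int]
    boundary_offset_aa: int
    unit_schedule_aa: tuple[int, ...]
    protein_length_aa: int


@dataclass
class SyntheticGene:
    model: GeneModel
    domain: DomainAnnotation | None
    truth: GeneTruth


@dataclass(frozen=True)
class CohortSpec:
    """Families of repeat-modular genes plus non-repeat decoys."""

    families: tuple[tuple[str, LrrGeneSpec, int], ...]
    n_decoys: int
    seed: int


@dataclass
class CohortFixture:
    genes: list[SyntheticGene]
    gtf_path: Path
    fasta_path: Path
    domain_tsv_path: Path
    truth_tsv_path: Path
    truth: pd.DataFrame


def _instantiate_unit(
    unit_len: int, pattern: lc.ConsensusPattern, rng: np.random.Generator
) -> str:
    """One repeat unit matching the consensus perfectly: constrained
    positions get their canonical residue, wildcards a seeded random one."""
    if unit_len <= pattern.length_aa:
        skipped = set(lc._skip_positions(pattern, pattern.length_aa - unit_len))
        kept = [p for i, p in enumerate(pattern.positions) if i not in skipped]
        extra = 0
    else:
        kept = list(pattern.positions)
        extra = unit_len - pattern.length_aa
    out = []
    for pos in kept:
        if pos.wildcard:
            out.append(_RESIDUES[rng.integers(len(_RESIDUES))])
        else:
            code = pos.code.split("/")[0]
            out.append(_CANONICAL.get(code, sorted(pos.residues)[0]))
    for _ in range(extra):
        out.append(_RESIDUES[rng.integers(len(_RESIDUES))])
    return "".join(out)


def _random_protein(n_aa: int, rng: np.random.Generator) -> str:
    return "".join(_RESIDUES[i] for i in rng.integers(len(_RESIDUES), size=n_aa))


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    return "".join(
        _CODONS_FOR[aa][rng.integers(len(_CODONS_FOR[aa]))] for aa in protein
    )


def _assemble_model(
    *,
    gene_name: str,
    transcript_id: str,
    chrom: str,
    gene_start: int,
    strand: str,
    exon_full_bp: Sequence[int],
    exon_coding_bp: Sequence[int],
    utr5: int,
    protein: str,
    cds_seq: str,
    rng: np.random.Generator,
) -> GeneModel:
    """Lay exons onto genomic coordinates (introns 300-1500 bp) and build the
    GeneModel.  On the minus strand exon 1 sits at the highest coordinates."""
    introns = [int(rng.integers(300, 1501)) for _ in range(len(exon_full_bp) - 1)]
    span = sum(exon_full_bp) + sum(introns)
    exons: list[Exon] = []
    phase = 0
    pos = gene_start if strand == "+" else gene_start + span
    for i, (full, coding) in enumerate(zip(exon_full_bp, exon_coding_bp)):
        if strand == "+":
            iv = GenomicInterval(chrom, pos, pos + full, strand)
            pos += full + (introns[i] if i < len(introns) else 0)
        else:
            iv = GenomicInterval(chrom, pos - full, pos, strand)
            pos -= full + (introns[i] if i < len(introns) else 0)
        exons.append(
            Exon(
                transcript_id=transcript_id,
                index=i + 1,
                interval=iv,
                full_length_bp=full,
                coding_length_bp=coding,
                start_phase=phase if coding else 0,
            )
        )
        phase = (phase + coding) % 3
    total_coding = sum(exon_coding_bp)
    return GeneModel(
        gene_id=f"{gene_name}_g",
        gene_name=gene_name,
        transcript_id=transcript_id,
        exons=exons,
        cds_start=utr5,
        cds_end=utr5 + total_coding,
        protein_seq=protein,
        cds_seq=cds_seq,
        stop_in_cds=True,
    )


def make_lrr_gene(spec: LrrGeneSpec = LrrGeneSpec(), seed: int = 0) -> SyntheticGene:
    """Build one repeat-modular gene with full ground truth.

    The domain exons tile the LRR repeat schedule; with the default spec
    every domain exon is 171 bp (two 28/29-aa units), every border falls at
    register offset 0, and the protein equals the translated CDS.
    """
    if spec.n_domain_exons < 1 or spec.repeats_per_exon < 1:
        raise ValueError("need >= 1 domain exon and >= 1 repeat per exon")
    if spec.strand not in {"+", "-"}:
        raise ValueError("strand must be '+' or '-'")
    pattern = lc.parse_consensus(spec.consensus)
    if min(spec.unit_lengths_aa) < 1:
        raise ValueError("unit lengths must be positive")
    rng = np.random.default_rng(seed)

    r = spec.repeats_per_exon
    n_units = spec.n_domain_exons * r
    schedule = [spec.unit_lengths_aa[k % len(spec.unit_lengths_aa)] for k in range(n_units + 2)]
    b = spec.boundary_offset_aa
    if b:
        per_exon = {sum(schedule[k * r : (k + 1) * r]) for k in range(spec.n_domain_exons)}
        if len(per_exon) != 1:
            raise ValueError(
                "boundary_offset_aa > 0 requires a constant per-exon unit cycle"
            )
        if b >= min(spec.unit_lengths_aa):
            raise ValueError("boundary_offset_aa must be smaller than the shortest unit")
    repeat_seq = "".join(_instantiate_unit(u, pattern, rng) for u in schedule)
    exon_aa = [sum(schedule[k * r : (k + 1) * r]) for k in range(spec.n_domain_exons)]
    domain_aa = sum(exon_aa)
    domain_seq = repeat_seq[b : b + domain_aa]
    register_tail = repeat_seq[:b]  # partial unit carried by the upstream flank

    # upstream flank: total coding divisible by 3 so domain exons start in
    # phase 0; individual flank exons are free to be frame-shifting
    lo, hi = spec.flank_coding_bp_range
    up_coding = [int(rng.integers(lo, hi + 1)) for _ in range(spec.n_upstream_flank)]
    extra = 3 * len(register_tail)
    rem = (sum(up_coding) + extra) % 3
    if rem:
        up_coding[-1] += 3 - rem
    up_coding[-1] += extra  # register tail encoded at the end of the flank
    down_coding = [int(rng.integers(lo, hi + 1)) for _ in range(spec.n_downstream_flank)]
    rem = sum(down_coding) % 3
    if rem:
        down_coding[-1] += 3 - rem

    up_aa = sum(up_coding) // 3
    down_aa = sum(down_coding) // 3 - 1  # last codon is the stop
    if down_aa < 1:
        raise ValueError("downstream flank too short to hold the stop codon")
    up_protein = _random_protein(up_aa - len(register_tail), rng) + register_tail
    down_protein = _random_protein(down_aa, rng)
    protein = up_protein + domain_seq + down_protein
    cds_seq = _reverse_translate(protein, rng) + "TAA"

    exon_coding = up_coding + [3 * a for a in exon_aa] + down_coding
    exon_full = list(exon_coding)
    exon_full[0] += spec.utr_bp[0]
    exon_full[-1] += spec.utr_bp[1]

    # perturbations: move the exon's 3' junction by delta bp
    for exon_index, delta in spec.perturbations:
        i = exon_index - 1
        if not (0 <= i < len(exon_coding) - 1):
            raise ValueError(f"perturbation exon {exon_index} has no 3' junction")
        if exon_coding[i] + delta <= 0 or exon_coding[i + 1] - delta <= 0:
            raise ValueError(f"perturbation {delta:+d} bp empties an exon")
        for arr in (exon_coding, exon_full):
            arr[i] += delta
            arr[i + 1] -= delta

    transcript_id = f"{spec.gene_name}_t1"
    model = _assemble_model(
        gene_name=spec.gene_name,
        transcript_id=transcript_id,
        chrom=spec.chrom,
        gene_start=spec.gene_start,
        strand=spec.strand,
        exon_full_bp=exon_full,
        exon_coding_bp=exon_coding,
        utr5=spec.utr_bp[0],
        protein=protein,
        cds_seq=cds_seq,
        rng=rng,
    )
    first_dom = spec.n_upstream_flank + 1
    dom_idx = tuple(range(first_dom, first_dom + spec.n_domain_exons))
    domain = DomainAnnotation(
        protein_id=transcript_id,
        domain_class="SM00369",
        start_aa=up_aa + 1,
        end_aa=up_aa + domain_aa,
    )
    truth = GeneTruth(
        gene_name=spec.gene_name,
        transcript_id=transcript_id,
        domain_exon_indices=dom_idx,
        exon_full_bp=tuple(exon_full),
        exon_coding_bp=tuple(exon_coding),
        frame_preserving=tuple(l % 3 == 0 for l in exon_full),
        domain_span_aa=(up_aa + 1, up_aa + domain_aa),
        boundary_offset_aa=b,
        unit_schedule_aa=tuple(schedule[:n_units]),
        protein_length_aa=len(protein),
    )
    return SyntheticGene(model=model, domain=domain, truth=truth)


def make_decoy_gene(
    name: str,
    seed: int,
    n_exons_range: tuple[int, int] = (4, 8),
    chrom: str = "chrD",
    gene_start: int = 1000,
    strand: str = "+",
) -> SyntheticGene:
    """A non-repeat gene whose exon lengths follow a geometric-like law, so
    only about one third are frame-preserving by chance."""
    rng = np.random.default_rng(seed)
    n_exons = int(rng.integers(n_exons_range[0], n_exons_range[1] + 1))
    coding = [60 + int(rng.geometric(0.012)) for _ in range(n_exons)]
    rem = sum(coding) % 3
    if rem:
        coding[-1] += 3 - rem
    full = list(coding)
    utr5, utr3 = int(rng.integers(50, 400)), int(rng.integers(100, 600))
    full[0] += utr5
    full[-1] += utr3
    n_aa = sum(coding) // 3 - 1
    protein = _random_protein(n_aa, rng)
    cds_seq = _reverse_translate(protein, rng) + "TAA"
    transcript_id = f"{name}_t1"
    model = _assemble_model(
        gene_name=name,
        transcript_id=transcript_id,
        chrom=chrom,
        gene_start=gene_start,
        strand=strand,
        exon_full_bp=full,
        exon_coding_bp=coding,
        utr5=utr5,
        protein=protein,
        cds_seq=cds_seq,
        rng=rng,
    )
    truth = GeneTruth(
        gene_name=name,
        transcript_id=transcript_id,
        domain_exon_indices=(),
        exon_full_bp=tuple(full),
        exon_coding_bp=tuple(coding),
        frame_preserving=tuple(l % 3 == 0 for l in full),
        domain_span_aa=(0, 0),
        boundary_offset_aa=0,
        unit_schedule_aa=(),
        protein_length_aa=n_aa,
    )
    return SyntheticGene(model=model, domain=None, truth=truth)


def default_cohort_spec(seed: int = 1, genes_per_family: int = 5, n_decoys: int = 10) -> CohortSpec:
    """Four repeat families whose exon lengths land in the four canonical
    peak windows (69-75, 81-87, 141-147, 168-174 bp), plus decoys."""
    fam = lambda **kw: LrrGeneSpec(n_upstream_flank=2, n_downstream_flank=1, **kw)
    return CohortSpec(
        families=(
            ("LRRa", fam(n_domain_exons=6, repeats_per_exon=1,
                         unit_lengths_aa=(23, 24, 25)), genes_per_family),
            ("LRRb", fam(n_domain_exons=6, repeats_per_exon=1,
                         unit_lengths_aa=(28,)), genes_per_family),
            ("LRRc", fam(n_domain_exons=5, repeats_per_exon=2,
                         unit_lengths_aa=(23, 24)), genes_per_family),
            ("LRRd", fam(n_domain_exons=5, repeats_per_exon=2,
                         unit_lengths_aa=(28, 29)), genes_per_family),
        ),
        n_decoys=n_decoys,
        seed=seed,
    )


def make_gene_cohort(cohort_spec: CohortSpec, out_dir: str | Path) -> CohortFixture:
    """Generate a cohort and write GTF + protein FASTA + domain TSV + truth TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(cohort_spec.seed)
    genes: list[SyntheticGene] = []
    gi = 0
    for fam_name, spec, n_genes in cohort_spec.families:
        for j in range(n_genes):
            child = int(root.spawn(1)[0].generate_state(1)[0] % 2**31)
            gi += 1
            gspec = replace(
                spec,
                gene_name=f"{fam_name}{j + 1}",
                chrom=f"chr{gi}",
                strand="+" if gi % 2 else "-",
            )
            genes.append(make_lrr_gene(gspec, seed=child))
    for j in range(cohort_spec.n_decoys):
        child = int(root.spawn(1)[0].generate_state(1)[0] % 2**31)
        gi += 1
        genes.append(
            make_decoy_gene(
                f"DEC{j + 1}", seed=child, chrom=f"chr{gi}",
                strand="+" if gi % 2 else "-",
            )
        )

    gtf_path = out_dir / "cohort.gtf"
    fasta_path = out_dir / "cohort_proteins.fasta"
    domain_tsv = out_dir / "cohort_domains.tsv"
    truth_tsv = out_dir / "cohort_truth.tsv"
    write_gtf([g.model for g in genes], gtf_path)
    with open(fasta_path, "w") as fh:
        for g in genes:
            fh.write(f">{g.model.transcript_id}\n{g.model.protein_seq}\n")
    write_domain_annotations([g.domain for g in genes if g.domain], domain_tsv)

    rows = []
    from .exon_modularity import DEFAULT_PEAK_WINDOWS

    for g in genes:
        t = g.truth
        for i, (full, coding) in enumerate(zip(t.exon_full_bp, t.exon_coding_bp), start=1):
            in_dom = i in t.domain_exon_indices
            window = ""
            if in_dom:
                for a, bnd in DEFAULT_PEAK_WINDOWS:
                    if a <= full <= bnd:
                        window = f"{a}-{bnd}"
                        break
            rows.append(
                {
                    "gene_name": t.gene_name,
                    "transcript_id": t.transcript_id,
                    "exon_index": i,
                    "length_bp": full,
                    "coding_bp": coding,
                    "frame_preserving": full % 3 == 0,
                    "in_domain": in_dom,
                    "terminal": i in (1, len(t.exon_full_bp)),
                    "window": window,
                }
            )
    truth_df = pd.DataFrame(rows)
    truth_df.to_csv(truth_tsv, sep="\t", index=False)
    return CohortFixture(
        genes=genes,
        gtf_path=gtf_path,
        fasta_path=fasta_path,
        domain_tsv_path=domain_tsv,
        truth_tsv_path=truth_tsv,
        truth=truth_df,
    )


def simulate_junction_reads(
    psi_true: float,
    depth: int,
    seed: int,
    model: GeneModel | None = None,
    target_exon: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate junction-spanning reads for a cassette exon at known psi.

    A read supports inclusion with probability 2*psi/(1+psi) (two inclusion
    junction positions against one skip position); inclusion reads split
    uniformly between the upstream and downstream junctions.  Coordinates
    come from the given gene model (default: the canonical synthetic gene,
    target = its second domain exon, the exon-5 analogue).
    """
    if not (0.0 <= psi_true <= 1.0):
        raise ValueError("psi_true must be in [0, 1]")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if model is None:
        model = make_lrr_gene(LrrGeneSpec(), seed=0).model
        if target_exon is None:
            target_exon = 5  # second domain exon of the default architecture
    if target_exon is None:
        raise ValueError("target_exon required when a model is supplied")
    rng = np.random.default_rng(seed)
    p_inc = 2.0 * psi_true / (1.0 + psi_true)
    n_inc = int(rng.binomial(depth, p_inc))
    n_skip = depth - n_inc
    n_up = int(rng.binomial(n_inc, 0.5))
    n_down = n_inc - n_up
    coords = junctions_for_exon(model, target_exon)
    df = pd.DataFrame(
        [
            {
                "chrom": model.chrom,
                "intron_start": coords["inclusion_upstream"][0],
                "intron_end": coords["inclusion_upstream"][1],
                "strand": model.strand,
                "unique_read_count": n_up,
            },
            {
                "chrom": model.chrom,
                "intron_start": coords["inclusion_downstream"][0],
                "intron_end": coords["inclusion_downstream"][1],
                "strand": model.strand,
                "unique_read_count": n_down,
            },
            {
                "chrom": model.chrom,
                "intron_start": coords["skip"][0],
                "intron_end": coords["skip"][1],
                "strand": model.strand,
                "unique_read_count": n_skip,
            },
        ]
    )
    truth = {
        "psi_true": psi_true,
        "p_inc": p_inc,
        "n_inc": n_inc,
        "n_skip": n_skip,
        "depth": depth,
        "target_exon": target_exon,
        "transcript_id": model.transcript_id,
    }
    return df, truth
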