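"""Exon/domain modularity analysis.

Given gene models and protein-coordinate repeat-domain annotations, this
module extracts the exons spanning those domains, classifies every exon as
frame-preserving (length divisible by 3, so skipping it leaves the reading
frame intact) or frame-shifting, builds the exon-length spectrum up to a
cutoff, assigns exons to the canonical LRR peak-length windows, and tests
whether frame preservation is enriched among domain exons with a two-tailed
Fisher exact test.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .gene_models import DomainAnnotation, GeneModel, exon_aa_span

__all__ = [
    "DomainExonRecord",
    "LengthSpectrum",
    "PeakGroup",
    "EnrichmentResult",
    "LRR_SMART_CLASSES",
    "DEFAULT_PEAK_WINDOWS",
    "classify_frame",
    "extract_domain_exons",
    "length_spectrum",
    "assign_peak_groups",
    "fisher_two_tailed",
    "frame_enrichment",
]

# SMART accessions for LRR repeat classes used to select domain annotations.
LRR_SMART_CLASSES = (
    "SM00369",
    "SM00370",
    "SM00364",
    "SM00367",
    "SM00368",
    "SM00365",
)

# Canonical peak windows (bp, closed ranges) of the frame-preserving
# LRR-exon length distribution: one repeat of 23-25 aa, one of 28-29 aa,
# and two-repeat composites.
DEFAULT_PEAK_WINDOWS: tuple[tuple[int, int], ...] = (
    (69, 75),
    (81, 87),
    (141, 147),
    (168, 174),
)


@dataclass
class DomainExonRecord:
    """One exon with its frame, domain-membership and terminal flags."""

    gene_name: str
    transcript_id: str
    exon_index: int
    length_bp: int
    frame_preserving: bool
    in_domain: bool
    terminal: bool
    peak_group: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.frame_preserving != (self.length_bp % 3 == 0):
            raise ValueError("frame_preserving inconsistent with length_bp mod 3")


@dataclass
class LengthSpectrum:
    """Per-length exon counts for one frame stratum, lengths 1..max_length_bp."""

    stratum: str  # "frame_preserving" | "frame_shifting"
    max_length_bp: int
    counts: np.ndarray  # counts[L-1] = number of exons of length L
    n_excluded: int = 0

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def count_at(self, length_bp: int) -> int:
        return int(self.counts[length_bp - 1])


@dataclass
class PeakGroup:
    """A peak-length window and the multiset of genes contributing exons."""

    window: tuple[int, int]
    member_genes: Counter = field(default_factory=Counter)

    @property
    def n_exons(self) -> int:
        return sum(self.member_genes.values())


@dataclass
class EnrichmentResult:
    """2x2 contingency result: rows domain/non-domain, columns shifting/preserving."""

    table: np.ndarray
    p_two_tailed: float
    odds_ratio: float
    degenerate: bool = False


def classify_frame(length_bp: int) -> bool:
    """True iff an exon of this length preserves the reading frame when skipped."""
    if length_bp < 1:
        raise ValueError(f"exon length must be positive, got {length_bp}")
    return length_bp % 3 == 0


def _domain_hit(
    model: GeneModel,
    exon_index: int,
    spans: Sequence[tuple[int, int]],
    full_containment: bool,
) -> bool:
    """Does the exon carry >=1 codon (first-base rule) inside any domain span?

    In ``full_containment`` mode every codon of the exon must lie inside a
    single span.
    """
    aa = exon_aa_span(model, exon_index)
    if aa is None:
        return False
    lo, hi = aa
    if full_containment:
        return any(s <= lo and hi <= e for s, e in spans)
    return any(max(lo, s) <= min(hi, e) for s, e in spans)


def extract_domain_exons(
    models: Iterable[GeneModel],
    domains: Iterable[DomainAnnotation],
    domain_classes: Sequence[str] = LRR_SMART_CLASSES,
    *,
    cds_only: bool = False,
    full_containment: bool = False,
    include_undomained_transcripts: bool = False,
) -> list[DomainExonRecord]:
    """Extract domain-spanning exons plus the non-domain exons of the same
    transcripts.

    An exon is in-domain when at least one codon whose first base lies in
    the exon falls within a requested domain span (``full_containment``
    demands every such codon does).  ``length_bp`` is the FULL exonic
    length including UTR portions unless ``cds_only``.  Transcripts whose
    protein id matches no model are skipped with a warning; with
    ``include_undomained_transcripts`` the exons of models having no
    requested domain are also returned (all ``in_domain=False``), which is
    useful when contrasting against decoy genes.
    """
    if not domain_classes:
        raise ValueError("domain_classes must be non-empty")
    wanted = [d for d in domains if d.domain_class in domain_classes]
    by_tx = {m.transcript_id: m for m in models}

    spans_by_tx: dict[str, list[tuple[int, int]]] = {}
    n_unresolved = 0
    for d in wanted:
        if d.protein_id not in by_tx:
            warnings.warn(f"domain protein id {d.protein_id!r} unresolvable; skipped",
                          stacklevel=2)
            n_unresolved += 1
            continue
        spans_by_tx.setdefault(d.protein_id, []).append((d.start_aa, d.end_aa))

    records: list[DomainExonRecord] = []
    for tx, model in by_tx.items():
        spans = spans_by_tx.get(tx)
        if spans is None and not include_undomained_transcripts:
            continue
        n = len(model.exons)
        for exon in model.exons:
            length = exon.coding_length_bp if cds_only else exon.full_length_bp
            if length == 0:
                continue
            records.append(
                DomainExonRecord(
                    gene_name=model.gene_name,
                    transcript_id=tx,
                    exon_index=exon.index,
                    length_bp=length,
                    frame_preserving=classify_frame(length),
                    in_domain=bool(spans)
                    and _domain_hit(model, exon.index, spans, full_containment),
                    terminal=exon.index in (1, n),
                )
            )
    if n_unresolved:
        warnings.warn(f"{n_unresolved} domain annotations had unresolvable protein ids",
                      stacklevel=2)
    return records


def length_spectrum(
    records: Sequence[DomainExonRecord],
    max_length_bp: int = 200,
) -> tuple[LengthSpectrum, LengthSpectrum]:
    """Exact per-length counts split into frame-preserving/-shifting strata.

    Records longer than ``max_length_bp`` are excluded from the counts but
    tallied in ``n_excluded``.
    """
    if not records:
        raise ValueError("no records to build a spectrum from")
    out = {}
    for stratum, keep in (("frame_preserving", True), ("frame_shifting", False)):
        counts = np.zeros(max_length_bp, dtype=int)
        excluded = 0
        for r in records:
            if r.frame_preserving != keep:
                continue
            if r.length_bp > max_length_bp:
                excluded += 1
            else:
                counts[r.length_bp - 1] += 1
        out[stratum] = LengthSpectrum(stratum, max_length_bp, counts, excluded)
    return out["frame_preserving"], out["frame_shifting"]


def assign_peak_groups(
    records: Sequence[DomainExonRecord],
    windows: Sequence[tuple[int, int]] = DEFAULT_PEAK_WINDOWS,
) -> list[PeakGroup]:
    """Assign each record to at most one closed bp window; label records in place.

    Returns one PeakGroup per window carrying the multiset of contributing
    gene names (the word-cloud data).
    """
    windows = [tuple(w) for w in windows]
    for (a1, b1) in windows:
        if a1 > b1:
            raise ValueError(f"window {a1}-{b1} is empty")
    for i, (a1, b1) in enumerate(windows):
        for a2, b2 in windows[i + 1 :]:
            if max(a1, a2) <= min(b1, b2):
                raise ValueError(f"windows ({a1},{b1}) and ({a2},{b2}) overlap")
    groups = [PeakGroup(window=w) for w in windows]
    for r in records:
        r.peak_group = None
        for g in groups:
            if g.window[0] <= r.length_bp <= g.window[1]:
                r.peak_group = g.window
                g.member_genes[r.gene_name] += 1
                break
    return groups


def detect_peak_windows(
    spectrum: LengthSpectrum,
    half_width: int = 3,
    min_fold_over_median: float = 2.0,
) -> list[tuple[int, int]]:
    """Data-driven peak finding: local maxima of a +/-1 bp smoothed spectrum
    exceeding ``min_fold_over_median`` times the local (+/-10 bp) median.

    Provided as an exploratory alternative to the fixed windows; the fixed
    defaults are what the analysis pipeline uses.
    """
    c = spectrum.counts.astype(float)
    kernel = np.ones(3) / 3.0
    smooth = np.convolve(c, kernel, mode="same")
    windows = []
    for i in range(1, len(smooth) - 1):
        if smooth[i] <= smooth[i - 1] or smooth[i] < smooth[i + 1]:
            continue
        lo, hi = max(0, i - 10), min(len(smooth), i + 11)
        local_med = float(np.median(smooth[lo:hi]))
        if smooth[i] > min_fold_over_median * max(local_med, 1e-9):
            windows.append((max(1, i + 1 - half_width), i + 1 + half_width))
    return windows


def fisher_two_tailed(table: Sequence[Sequence[int]]) -> EnrichmentResult:
    """Two-tailed Fisher exact test on a 2x2 count table.

    The two-tailed p is the sum of hypergeometric probabilities of all
    tables with the same margins whose probability does not exceed the
    observed table's.  The odds ratio is the sample ratio (a*d)/(b*c),
    infinite when b*c = 0 with a*d > 0.  A table with any zero margin is
    degenerate: p = 1 by convention.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative integer counts")
    (a, b), (c, d) = t
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    row0, row1 = a + b, c + d
    col0, col1 = a + c, b + d
    if 0 in (row0, row1, col0, col1):
        return EnrichmentResult(table=t, p_two_tailed=1.0, odds_ratio=odds,
                                degenerate=True)
    lo, hi = max(0, col0 - row1), min(row0, col0)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, row0 + row1, row0, col0)
    p_obs = pmf[a - lo]
    p = float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))
    return EnrichmentResult(table=t, p_two_tailed=p, odds_ratio=odds)


def frame_enrichment(records: Sequence[DomainExonRecord]) -> EnrichmentResult:
    """Fisher test of frame preservation in domain vs non-domain exons.

    Table orientation: rows are (domain exons, non-domain exons), columns
    are (frame-shifting, frame-preserving).  An odds ratio < 1 therefore
    means domain exons are LESS often frame-shifting, i.e. frame
    preservation is enriched in the domain.
    """
    a = sum(r.in_domain and not r.frame_preserving for r in records)
    b = sum(r.in_domain and r.frame_preserving for r in records)
    c = sum(not r.in_domain and not r.frame_preserving for r in records)
    d = sum(not r.in_domain and r.frame_preserving for r in records)
    if (a + b) == 0 or (c + d) == 0:
        warnings.warn("records lack one of the domain strata; test degenerate",
                      stacklevel=2)
    return fisher_two_tailed([[a, b], [c, d]])
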