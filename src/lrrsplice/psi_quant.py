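"""Exon-centric percent-spliced-in (psi) from splice-junction reads.

For a cassette exon with flanking exons U and D, three junctions carry the
signal: the two inclusion junctions U->E and E->D, and the skipping
junction U->D.  The inclusion isoform exposes two junction positions where
the skipping isoform exposes one, so under uniform junction sampling a
junction-spanning read comes from the inclusion isoform with probability

    p_inc = 2*psi / (1 + psi)

giving the closed-form MLE psi_hat = r / (2 - r) with r = n_inc/(n_inc+n_skip).
A grid posterior over psi with a uniform prior supplies the point estimate
(posterior mean) and an equal-tailed credible interval.  This is a
junction-only model: exon-body coverage is deliberately excluded from the
likelihood because body coverage is not uniform in real libraries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .gene_models import GeneModel

__all__ = [
    "JunctionCounts",
    "PsiEstimate",
    "read_junction_table",
    "junctions_for_exon",
    "assign_junction_support",
    "psi_mle",
    "psi_posterior",
]

JUNCTION_COLUMNS = ["chrom", "intron_start", "intron_end", "strand", "unique_read_count"]


@dataclass(frozen=True)
class JunctionCounts:
    """Junction read support for one cassette exon."""

    n_inc: int  # reads on the two inclusion junctions
    n_skip: int  # reads on the skipping junction
    n_ignored: int = 0  # reads on junctions matching none of the three

    def __post_init__(self) -> None:
        if min(self.n_inc, self.n_skip, self.n_ignored) < 0:
            raise ValueError("junction counts must be non-negative")


@dataclass(frozen=True)
class PsiEstimate:
    """Posterior summary of the inclusion level of one exon."""

    psi_hat: float
    ci_low: float
    ci_high: float
    n_inc: int
    n_skip: int
    grid_resolution: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.psi_hat <= self.ci_high <= 1.0):
            raise ValueError("require 0 <= ci_low <= psi_hat <= ci_high <= 1")


def read_junction_table(path: str | Path, dialect: str = "lrrsplice") -> pd.DataFrame:
    """Read a junction count TSV.

    ``lrrsplice`` dialect: header columns chrom, intron_start (1-based
    first intronic base), intron_end (1-based last intronic base), strand
    (+/-), unique_read_count.  ``star`` dialect: the headerless 9-column
    SJ.out.tab layout (strand coded 0/1/2; column 7 = unique reads).
    """
    if dialect == "lrrsplice":
        df = pd.read_csv(path, sep="\t")
        missing = set(JUNCTION_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"junction TSV missing columns: {sorted(missing)}")
        return df[JUNCTION_COLUMNS].copy()
    if dialect == "star":
        raw = pd.read_csv(path, sep="\t", header=None)
        if raw.shape[1] < 7:
            raise ValueError("STAR SJ.out.tab needs >= 7 columns")
        df = pd.DataFrame(
            {
                "chrom": raw[0],
                "intron_start": raw[1],
                "intron_end": raw[2],
                "strand": raw[3].map({0: ".", 1: "+", 2: "-"}),
                "unique_read_count": raw[6],
            }
        )
        return df
    raise ValueError(f"unknown junction dialect {dialect!r}")


def junctions_for_exon(
    model: GeneModel,
    target_exon: int,
    upstream_exon: int | None = None,
    downstream_exon: int | None = None,
) -> dict[str, tuple[int, int]]:
    """Expected (intron_start, intron_end) coordinates, 1-based inclusive
    intronic bases, for the two inclusion junctions and the skip junction of
    a cassette exon."""
    if upstream_exon is None:
        upstream_exon = target_exon - 1
    if downstream_exon is None:
        downstream_exon = target_exon + 1
    if not (1 <= upstream_exon < target_exon < downstream_exon <= len(model.exons)):
        raise ValueError("need upstream < target < downstream within the model")

    def intron(a: int, b: int) -> tuple[int, int]:
        """Intron between transcript exons a < b in genomic 1-based inclusive."""
        ea, eb = model.exons[a - 1].interval, model.exons[b - 1].interval
        if model.strand == "+":
            return ea.end + 1, eb.start
        return eb.end + 1, ea.start

    return {
        "inclusion_upstream": intron(upstream_exon, target_exon),
        "inclusion_downstream": intron(target_exon, downstream_exon),
        "skip": intron(upstream_exon, downstream_exon),
    }


def assign_junction_support(
    junction_table: pd.DataFrame,
    model: GeneModel,
    target_exon: int,
    upstream_exon: int | None = None,
    downstream_exon: int | None = None,
) -> JunctionCounts:
    """Sum reads onto the inclusion/skipping junctions of a cassette exon.

    Junction coordinates must match the model's exon boundaries exactly;
    every non-matching junction is ignored and tallied in ``n_ignored``
    (each read is counted at most once because the three target junctions
    are distinct coordinate pairs).  Zero matches is allowed but warned
    about.
    """
    expected = junctions_for_exon(model, target_exon, upstream_exon, downstream_exon)
    inc_keys = {expected["inclusion_upstream"], expected["inclusion_downstream"]}
    skip_key = expected["skip"]
    n_inc = n_skip = n_ignored = 0
    for row in junction_table.itertuples():
        if row.chrom != model.chrom:
            n_ignored += int(row.unique_read_count)
            continue
        key = (int(row.intron_start), int(row.intron_end))
        count = int(row.unique_read_count)
        if key in inc_keys:
            n_inc += count
        elif key == skip_key:
            n_skip += count
        else:
            n_ignored += count
    if n_inc == 0 and n_skip == 0:
        warnings.warn(
            f"no junctions matched exon {target_exon} of {model.transcript_id}; "
            "check coordinates",
            stacklevel=2,
        )
    return JunctionCounts(n_inc=n_inc, n_skip=n_skip, n_ignored=n_ignored)


def psi_mle(n_inc: int, n_skip: int) -> float:
    """Closed-form MLE of psi from junction counts.

    With r the inclusion-read fraction, psi_hat = r / (2 - r): the factor 2
    corrects for the inclusion isoform exposing two junction positions.
    """
    if n_inc < 0 or n_skip < 0:
        raise ValueError("counts must be non-negative")
    if n_inc + n_skip == 0:
        raise ValueError("psi undefined: no junction reads")
    r = n_inc / (n_inc + n_skip)
    return float(min(1.0, max(0.0, r / (2.0 - r))))


def psi_posterior(
    n_inc: int,
    n_skip: int,
    grid_step: float = 0.001,
    ci: float = 0.95,
) -> PsiEstimate:
    """Grid posterior of psi under a uniform prior.

    Likelihood per junction read: inclusion with probability 2*psi/(1+psi),
    skipping with (1-psi)/(1+psi).  The point estimate is the posterior
    mean; the credible interval is equal-tailed from the normalized grid
    CDF.  Deterministic by construction (no sampling).
    """
    if n_inc < 0 or n_skip < 0:
        raise ValueError("counts must be non-negative")
    if n_inc + n_skip == 0:
        raise ValueError("psi posterior undefined: no junction reads")
    if not (0.0 < grid_step <= 0.1):
        raise ValueError("grid_step must be in (0, 0.1]")
    if not (0.0 < ci < 1.0):
        raise ValueError("ci must be in (0, 1)")

    psi = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    loglik = np.zeros_like(psi)
    with np.errstate(divide="ignore"):
        # guard the grid endpoints: a zero count contributes nothing, so the
        # -inf log there must not turn into 0 * -inf = nan
        if n_inc:
            loglik += n_inc * np.log(2 * psi / (1 + psi))
        if n_skip:
            loglik += n_skip * np.log((1 - psi) / (1 + psi))
    loglik -= loglik.max()
    w = np.exp(loglik)
    w /= w.sum()
    mean = float(np.sum(psi * w))
    cdf = np.cumsum(w)
    alpha = (1.0 - ci) / 2.0
    lo = float(psi[int(np.searchsorted(cdf, alpha))])
    hi = float(psi[int(np.searchsorted(cdf, 1.0 - alpha))])
    lo = min(lo, mean)
    hi = max(hi, mean)
    return PsiEstimate(
        psi_hat=mean,
        ci_low=lo,
        ci_high=hi,
        n_inc=int(n_inc),
        n_skip=int(n_skip),
        grid_resolution=grid_step,
    )
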