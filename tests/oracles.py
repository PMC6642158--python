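"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities from first principles (codon
enumeration, hypergeometric enumeration, exhaustive register tilings,
numerical integration) without calling the implementation paths they
check.
"""

from __future__ import annotations

from math import comb, exp

import numpy as np
from scipy import integrate, stats

# ---------------------------------------------------------------------------
# Fisher exact test: full enumeration over margin-consistent tables


from functools import lru_cache


@lru_cache(maxsize=None)
def _margin_probs(r1: int, r2: int, c1: int) -> dict[int, float]:
    denom = comb(r1 + r2, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return {x: comb(r1, x) * comb(r2, c1 - x) / denom for x in range(lo, hi + 1)}


def fisher_two_tailed_enumeration(table) -> float:
    (a, b), (c, d) = table
    probs = _margin_probs(a + b, c + d, a + c)
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-7))


# ---------------------------------------------------------------------------
# domain-exon membership: test every codon of every exon against every span


def brute_force_domain_exons(model, spans) -> set[int]:
    """Exon indices owning >=1 codon (first-base rule) inside any aa span."""
    n_aa = len(model.protein_seq)
    exon_of_nt = []
    for e in model.exons:
        exon_of_nt.extend([e.index] * e.coding_length_bp)
    hits = set()
    for aa in range(1, n_aa + 1):
        exon = exon_of_nt[3 * (aa - 1)]
        if any(s <= aa <= t for s, t in spans):
            hits.add(exon)
    return hits


# ---------------------------------------------------------------------------
# register alignment: exhaustive (offset, phase) tilings with independent scoring


def _parse_positions(pattern_string: str) -> list[str]:
    out, i = [], 0
    while i < len(pattern_string):
        if pattern_string[i] == "(":
            j = pattern_string.index(")", i)
            out.append(pattern_string[i + 1 : j].replace("/", ""))
            i = j + 1
        else:
            out.append(pattern_string[i])
            i += 1
    return out


def brute_force_align(segment: str, pattern_string: str, residue_sets: dict,
                      unit_lengths=(28, 29)):
    """Best (mean score, offset) over all offsets and alternation phases.

    Scoring: per unit, fraction of non-wildcard consensus positions matched;
    units shorter than the pattern drop its trailing wildcard positions.
    Preference order on ties: smaller offset, then shorter starting unit.
    """
    codes = _parse_positions(pattern_string)
    wild = [all(ch in "xz" for ch in c) for c in codes]

    def allowed(code):
        s = set()
        for ch in code:
            s |= set(residue_sets[ch])
        return s

    sets = [allowed(c) for c in codes]

    def score_unit(seq):
        n_skip = len(codes) - len(seq)
        wild_idx = [i for i, w in enumerate(wild) if w]
        skipped = set(wild_idx[len(wild_idx) - n_skip :]) if n_skip else set()
        kept = [i for i in range(len(codes)) if i not in skipped]
        scored = [(aa, i) for aa, i in zip(seq, kept) if not wild[i]]
        return sum(aa in sets[i] for aa, i in scored) / len(scored)

    best = None
    phases = sorted(range(len(unit_lengths)), key=lambda k: unit_lengths[k])
    for offset in range(max(unit_lengths)):
        for phase in phases:
            pos, k, scores = offset, phase, []
            while pos + unit_lengths[k % len(unit_lengths)] <= len(segment):
                u = unit_lengths[k % len(unit_lengths)]
                scores.append(score_unit(segment[pos : pos + u]))
                pos += u
                k += 1
            if not scores:
                continue
            mean = sum(scores) / len(scores)
            if best is None or mean > best[0] + 1e-12:
                best = (mean, offset)
    return best


# ---------------------------------------------------------------------------
# telegraph detection probability by numerical integration


def detection_probability(k_on, k_off, k_syn, k_deg, capture_p) -> float:
    """P(captured >= 1): captured is Poisson(k_syn/k_deg * capture_p * p)
    marginally over p ~ Beta(k_on/k_deg, k_off/k_deg)."""
    a, b = k_on / k_deg, k_off / k_deg
    lam = k_syn / k_deg * capture_p

    def integrand(p):
        return (1.0 - exp(-lam * p)) * stats.beta.pdf(p, a, b)

    val, _ = integrate.quad(integrand, 0.0, 1.0, limit=200)
    return float(val)
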