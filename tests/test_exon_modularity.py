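"""Frame classification, domain-exon extraction, spectra, peaks, Fisher test."""

import numpy as np
import pytest

from lrrsplice import exon_modularity as em
from lrrsplice import synthetic_data as sd

from oracles import brute_force_domain_exons, fisher_two_tailed_enumeration


def test_classify_frame_exhaustive():
    """Frame preservation is exactly (length mod 3 == 0) for 1..10,000 bp."""
    for L in range(1, 10_001):
        assert em.classify_frame(L) == (L % 3 == 0)
    with pytest.raises(ValueError):
        em.classify_frame(0)


@pytest.mark.parametrize("length, expected", [(171, True), (170, False), (84, True)])
def test_classify_frame_examples(length, expected):
    assert em.classify_frame(length) is expected


def test_canonical_gene_domain_exons(canonical_gene):
    """All 9 LRR exons of the canonical gene extracted, 171 bp, frame-preserving."""
    g = canonical_gene
    recs = em.extract_domain_exons([g.model], [g.domain])
    dom = [r for r in recs if r.in_domain]
    assert [r.exon_index for r in dom] == list(g.truth.domain_exon_indices)
    assert all(r.length_bp == 171 and r.frame_preserving for r in dom)
    nondom = [r for r in recs if not r.in_domain]
    assert {r.exon_index for r in nondom} == {1, 2, 3, 13}
    assert {r.exon_index for r in recs if r.terminal} == {1, 13}


def test_empty_domain_class_errors(canonical_gene):
    with pytest.raises(ValueError):
        em.extract_domain_exons([canonical_gene.model], [canonical_gene.domain], [])


def test_domain_touching_one_codon_still_extracts(canonical_gene):
    """A domain covering only the first 10 aa of a 57-aa exon extracts it."""
    g = canonical_gene
    start = g.truth.domain_span_aa[0]
    tiny = sd.DomainAnnotation(
        protein_id=g.model.transcript_id, domain_class="SM00369",
        start_aa=start, end_aa=start + 9,
    )
    recs = em.extract_domain_exons([g.model], [tiny])
    dom = [r.exon_index for r in recs if r.in_domain]
    assert dom == [g.truth.domain_exon_indices[0]]


def test_extraction_equals_codon_brute_force(cohort_models):
    """Extraction agrees with testing every codon of every exon on <= 50 genes."""
    models, domains = cohort_models
    spans_by_tx = {}
    for d in domains:
        spans_by_tx.setdefault(d.protein_id, []).append((d.start_aa, d.end_aa))
    recs = em.extract_domain_exons(models, domains)
    got = {}
    for r in recs:
        got.setdefault(r.transcript_id, set())
        if r.in_domain:
            got[r.transcript_id].add(r.exon_index)
    assert set(got) == set(spans_by_tx)
    for m in models:
        if m.transcript_id not in spans_by_tx:
            continue
        expected = brute_force_domain_exons(m, spans_by_tx[m.transcript_id])
        assert got[m.transcript_id] == expected, m.transcript_id


def test_unresolvable_protein_id_warns(canonical_gene):
    g = canonical_gene
    orphan = sd.DomainAnnotation("no_such_tx", "SM00369", 1, 50)
    with pytest.warns(UserWarning, match="unresolvable"):
        recs = em.extract_domain_exons([g.model], [g.domain, orphan])
    assert any(r.in_domain for r in recs)


def _records(lengths, in_domain=True):
    return [
        em.DomainExonRecord(
            gene_name=f"G{i}", transcript_id=f"t{i}", exon_index=1,
            length_bp=L, frame_preserving=L % 3 == 0,
            in_domain=in_domain, terminal=False,
        )
        for i, L in enumerate(lengths)
    ]


def test_length_spectrum_point_mass():
    fp, fs = em.length_spectrum(_records([171] * 9))
    assert fp.count_at(171) == 9
    assert fp.total == 9 and fs.total == 0
    assert fp.counts.sum() == 9 and np.count_nonzero(fp.counts) == 1


def test_length_spectrum_excludes_long_records():
    fp, fs = em.length_spectrum(_records([300, 301, 302]))
    assert fp.total == fs.total == 0
    assert fp.n_excluded + fs.n_excluded == 3


def test_length_spectrum_permutation_invariant_and_partitions():
    rng = np.random.default_rng(0)
    lengths = rng.integers(10, 260, size=200).tolist()
    recs = _records(lengths)
    fp1, fs1 = em.length_spectrum(recs)
    perm = [recs[i] for i in rng.permutation(len(recs))]
    fp2, fs2 = em.length_spectrum(perm)
    assert (fp1.counts == fp2.counts).all() and (fs1.counts == fs2.counts).all()
    n_le = sum(1 for L in lengths if L <= 200)
    assert fp1.total + fs1.total == n_le


def test_spectrum_matches_generator_truth(cohort):
    recs = _records(
        cohort.truth.loc[cohort.truth.in_domain, "length_bp"].tolist()
    )
    fp, fs = em.length_spectrum(recs)
    truth_fp = (cohort.truth.in_domain & cohort.truth.frame_preserving).sum()
    assert fp.total + fp.n_excluded == truth_fp
    assert fs.total + fs.n_excluded == (cohort.truth.in_domain & ~cohort.truth.frame_preserving).sum()


@pytest.mark.parametrize("length, window", [
    (171, (168, 174)), (84, (81, 87)), (100, None), (69, (69, 75)), (147, (141, 147)),
])
def test_peak_window_assignment(length, window):
    recs = _records([length])
    groups = em.assign_peak_groups(recs)
    assert recs[0].peak_group == window
    total = sum(g.n_exons for g in groups)
    assert total == (0 if window is None else 1)


def test_overlapping_windows_rejected():
    with pytest.raises(ValueError, match="overlap"):
        em.assign_peak_groups(_records([100]), windows=[(69, 80), (75, 90)])


def test_cohort_peak_assignment_matches_planted_windows(cohort):
    """Every in-domain cohort exon falls in its planted window, none outside."""
    truth = cohort.truth[cohort.truth.in_domain]
    recs = _records(truth.length_bp.tolist())
    em.assign_peak_groups(recs)
    got = ["" if r.peak_group is None else f"{r.peak_group[0]}-{r.peak_group[1]}"
           for r in recs]
    assert got == truth.window.fillna("").tolist()
    assert all(w != "" for w in got)


@pytest.mark.parametrize("table, expected", [
    ([[3, 0], [0, 3]], 0.1),            # extremes of margins (3,3)/(3,3): 2/20
    ([[1, 1], [1, 1]], 1.0),            # observed table is the most probable
    ([[5, 0], [0, 5]], 2 / 252),        # hypergeometric enumeration
])
def test_fisher_known_tables(table, expected):
    res = em.fisher_two_tailed(table)
    assert res.p_two_tailed == pytest.approx(expected, rel=1e-7)


def test_fisher_equals_enumeration_and_scipy_random_tables():
    from scipy import stats

    rng = np.random.default_rng(2)
    for _ in range(300):
        t = rng.integers(0, 11, size=(2, 2))
        if 0 in t.sum(axis=0) or 0 in t.sum(axis=1):
            continue
        res = em.fisher_two_tailed(t)
        assert res.p_two_tailed == pytest.approx(
            fisher_two_tailed_enumeration(t), rel=1e-7
        ), t.tolist()
        assert res.p_two_tailed == pytest.approx(
            stats.fisher_exact(t)[1], rel=1e-7, abs=1e-12
        ), t.tolist()


def test_fisher_degenerate_margin():
    res = em.fisher_two_tailed([[0, 0], [3, 4]])
    assert res.degenerate and res.p_two_tailed == 1.0


def test_fisher_odds_ratio_conventions():
    assert em.fisher_two_tailed([[6, 2], [1, 3]]).odds_ratio == pytest.approx(9.0)
    assert em.fisher_two_tailed([[3, 0], [0, 3]]).odds_ratio == np.inf


def test_frame_enrichment_perfect_separation():
    """All domain exons preserving, all others shifting: OR = 0 (rows are
    domain/non-domain, columns shifting/preserving) and p from enumeration."""
    recs = _records([171] * 6, in_domain=True) + _records([100] * 6, in_domain=False)
    res = em.frame_enrichment(recs)
    assert res.odds_ratio == 0.0
    assert res.table.tolist() == [[0, 6], [6, 0]]
    assert res.p_two_tailed == pytest.approx(
        fisher_two_tailed_enumeration([[0, 6], [6, 0]]), rel=1e-7
    )


def test_frame_enrichment_identical_rates_p_one():
    recs = _records([171, 171, 100, 100], in_domain=True) + _records(
        [171, 171, 100, 100], in_domain=False
    )
    assert em.frame_enrichment(recs).p_two_tailed == pytest.approx(1.0)


def test_frame_enrichment_planted_cohort():
    """90% vs 33% frame-preserving at 60 exons is detected at p < 0.01."""
    rng = np.random.default_rng(7)
    dom = [57 * 3 if rng.random() < 0.9 else 170 for _ in range(30)]
    non = [57 * 3 if rng.random() < 1 / 3 else 170 for _ in range(30)]
    recs = _records(dom, in_domain=True) + _records(non, in_domain=False)
    res = em.frame_enrichment(recs)
    assert res.p_two_tailed < 0.01
    assert res.p_two_tailed == pytest.approx(
        fisher_two_tailed_enumeration(res.table), rel=1e-7
    )
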