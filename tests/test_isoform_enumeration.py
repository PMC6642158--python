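"""Skip-isoform enumeration, translation consequences, amplicons, masses."""

from math import comb

import numpy as np
import pytest

from lrrsplice import isoform_enumeration as ie
from lrrsplice import synthetic_data as sd


def _full_length(model):
    return ie.SpliceIsoform(
        model.transcript_id, frozenset(), True, model.total_exonic_length
    )


def test_enumeration_counts_match_binomial(canonical_gene):
    """13-exon gene has 11 internal exons: C(11,1) and C(11,1)+C(11,2) isoforms."""
    m = canonical_gene.model
    n_internal = len(m.exons) - 2
    singles = ie.enumerate_skip_isoforms(m, max_skipped=1, translate=False)
    assert len(singles) == comb(n_internal, 1)
    doubles = ie.enumerate_skip_isoforms(m, max_skipped=2, translate=False)
    assert len(doubles) == comb(n_internal, 1) + comb(n_internal, 2)


def test_nine_internal_exon_gene_counts():
    """9 internal exons: 9 single-skip isoforms, 45 with up to two skips."""
    g = sd.make_lrr_gene(
        sd.LrrGeneSpec(n_domain_exons=9, n_upstream_flank=1, n_downstream_flank=1),
        seed=2,
    )
    assert len(ie.enumerate_skip_isoforms(g.model, 1, translate=False)) == 9
    assert len(ie.enumerate_skip_isoforms(g.model, 2, translate=False)) == 45


def test_enumeration_order_deterministic(canonical_gene):
    isos = ie.enumerate_skip_isoforms(canonical_gene.model, 2, translate=False)
    keys = [tuple(sorted(i.skipped_exons)) for i in isos]
    singles = [k for k in keys if len(k) == 1]
    doubles = [k for k in keys if len(k) == 2]
    assert singles == sorted(singles) and doubles == sorted(doubles)


def test_max_skipped_capped_with_warning():
    g = sd.make_lrr_gene(
        sd.LrrGeneSpec(n_domain_exons=1, n_upstream_flank=1, n_downstream_flank=1),
        seed=0,
    )
    with pytest.warns(UserWarning, match="capped"):
        isos = ie.enumerate_skip_isoforms(g.model, max_skipped=5, translate=False)
    assert {tuple(i.skipped_exons) for i in isos} == {(2,)}


def test_lrr_exon_skip_is_frame_preserving(canonical_gene):
    """Skipping any 171-bp domain exon preserves frame; protein loses 57 aa."""
    m = canonical_gene.model
    for idx in canonical_gene.truth.domain_exon_indices:
        iso = [
            i for i in ie.enumerate_skip_isoforms(m, 1)
            if i.skipped_exons == {idx}
        ][0]
        assert iso.frame_preserving
        assert not iso.premature_stop
        assert iso.protein_length_aa == len(m.protein_seq) - 57
        assert len(iso.protein_seq) == iso.protein_length_aa


def test_skip_nothing_identity(canonical_gene):
    m = canonical_gene.model
    iso = _full_length(m)
    assert ie.translate_isoform(m, iso) == m.protein_seq


def test_frameshift_skip_reported_at_junction():
    """Skipping a 172-bp exon shifts frame; the first bad codon is at the
    junction where the skipped exon began."""
    g = sd.make_lrr_gene(sd.LrrGeneSpec(perturbations=((5, 1),)), seed=4)
    m = g.model
    assert m.exons[4].full_length_bp == 172
    iso = [
        i for i in ie.enumerate_skip_isoforms(m, 1)
        if i.skipped_exons == {5}
    ][0]
    assert not iso.frame_preserving
    rep = ie.translate_isoform(m, iso)
    assert isinstance(rep, ie.FrameshiftReport)
    junction_nt = m.coding_offset_of_exon(5)
    assert rep.first_shifted_codon == junction_nt // 3 + 1
    assert rep.truncated_protein.startswith(m.protein_seq[: junction_nt // 3 - 1])


def test_amplicon_difference_of_one_skipped_exon(canonical_gene):
    """Full-length minus single-skip amplicon equals the skipped exon: 171 bp."""
    m = canonical_gene.model
    first_dom = canonical_gene.truth.domain_exon_indices[0]
    last_dom = canonical_gene.truth.domain_exon_indices[-1]
    left, right = first_dom - 1, last_dom + 1
    fl = _full_length(m)
    d1 = ie.SpliceIsoform(m.transcript_id, frozenset({first_dom + 1}), True, 0)
    assert (
        ie.cdna_amplicon_length(m, fl, left, right)
        - ie.cdna_amplicon_length(m, d1, left, right)
        == 171
    )
    d2 = ie.SpliceIsoform(
        m.transcript_id, frozenset({first_dom + 1, first_dom + 2}), True, 0
    )
    assert (
        ie.cdna_amplicon_length(m, fl, left, right)
        - ie.cdna_amplicon_length(m, d2, left, right)
        == 342
    )


def test_full_length_amplicon_equals_unspliced_span(canonical_gene):
    m = canonical_gene.model
    fl = _full_length(m)
    assert ie.cdna_amplicon_length(m, fl, 1, len(m.exons)) == m.total_exonic_length


def test_amplicon_anchor_in_skipped_set_rejected(canonical_gene):
    m = canonical_gene.model
    iso = ie.SpliceIsoform(m.transcript_id, frozenset({5}), True, 0)
    with pytest.raises(ValueError):
        ie.cdna_amplicon_length(m, iso, 5, 10)


def test_single_skip_deltas_match_exon_lengths(cohort):
    """For every frame-preserving single skip: protein shrinks by coding/3,
    cDNA by the full exon length."""
    for g in cohort.genes[:8]:
        m = g.model
        for iso in ie.enumerate_skip_isoforms(m, 1):
            (idx,) = iso.skipped_exons
            exon = m.exons[idx - 1]
            assert iso.cdna_length_bp == m.total_exonic_length - exon.full_length_bp
            if iso.frame_preserving and not iso.premature_stop:
                assert (
                    iso.protein_length_aa
                    == len(m.protein_seq) - exon.coding_length_bp // 3
                )


@pytest.mark.parametrize("seq, mass", [("G", 75.07), ("GG", 132.12)])
def test_average_mass_known_values(seq, mass):
    props = ie.protein_properties(seq)
    assert props.average_mass_da == pytest.approx(mass, abs=0.02)
    assert props.length_aa == len(seq)


def test_protein_length_reported():
    assert ie.protein_properties("A" * 57).length_aa == 57


def test_mass_additivity_random_peptides():
    """mass(AB) = mass(A) + mass(B) - water for random peptides."""
    rng = np.random.default_rng(3)
    residues = sorted("ACDEFGHIKLMNPQRSTVWY")
    for _ in range(20):
        a = "".join(residues[i] for i in rng.integers(20, size=rng.integers(1, 30)))
        b = "".join(residues[i] for i in rng.integers(20, size=rng.integers(1, 30)))
        m_ab = ie.protein_properties(a + b).average_mass_da
        m_a = ie.protein_properties(a).average_mass_da
        m_b = ie.protein_properties(b).average_mass_da
        assert m_ab == pytest.approx(m_a + m_b - ie.WATER_DA, abs=0.05)


def test_protein_properties_input_validation():
    with pytest.raises(ValueError):
        ie.protein_properties("")
    with pytest.raises(ValueError):
        ie.protein_properties("ACDEZ")


def test_missing_cds_unsupported(canonical_gene, tmp_path):
    from lrrsplice import gene_models as gm

    gm.write_gtf([canonical_gene.model], tmp_path / "g.gtf")
    (m,) = gm.read_gene_models(tmp_path / "g.gtf")
    iso = ie.SpliceIsoform(m.transcript_id, frozenset({5}), True, 0)
    with pytest.raises(ValueError, match="CDS"):
        ie.translate_isoform(m, iso)
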