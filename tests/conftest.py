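import pytest

from lrrsplice import gene_models as gm
from lrrsplice import synthetic_data as sd


@pytest.fixture(scope="session")
def canonical_gene():
    """The default repeat-modular gene: 9 domain exons of 171 bp (2x 28/29 aa)."""
    return sd.make_lrr_gene(sd.LrrGeneSpec(), seed=42)


@pytest.fixture(scope="session")
def cohort(tmp_path_factory):
    """Four repeat families + decoys written to disk, with ground truth."""
    out = tmp_path_factory.mktemp("cohort")
    return sd.make_gene_cohort(sd.default_cohort_spec(seed=1), out)


@pytest.fixture(scope="session")
def cohort_models(cohort):
    """The cohort as re-read from its GTF/FASTA/TSV fixtures."""
    models = gm.read_gene_models(cohort.gtf_path, cohort.fasta_path)
    domains = gm.read_domain_annotations(cohort.domain_tsv_path)
    return models, domains
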