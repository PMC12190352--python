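import pytest

from vdjannot.annotator import annotate_locus
from vdjannot.rss_ric import scan, train_ric
from vdjannot.synthetic_locus import (
    LocusSpec,
    generate_reference,
    generate_rss_training,
    plant_locus,
)


@pytest.fixture(scope="session")
def spec():
    return LocusSpec(seed=1)


@pytest.fixture(scope="session")
def small_spec():
    return LocusSpec(seed=5, n_v=2, n_d=1, n_j=2, n_c=1)


@pytest.fixture(scope="session")
def reference(spec):
    return generate_reference(spec)


@pytest.fixture(scope="session")
def gene_set(reference):
    return reference.gene_set()


@pytest.fixture(scope="session")
def small_reference(small_spec):
    return generate_reference(small_spec)


@pytest.fixture(scope="session")
def small_gene_set(small_reference):
    return small_reference.gene_set()


@pytest.fixture(scope="session")
def models(spec):
    m12 = train_ric(generate_rss_training(12, seed=spec.seed), 12)
    m23 = train_ric(generate_rss_training(23, seed=spec.seed), 23)
    return {12: m12, 23: m23}


@pytest.fixture(scope="session")
def planted(spec, gene_set):
    return plant_locus(spec, gene_set)


@pytest.fixture(scope="session")
def rss_candidates(models, planted):
    return scan(models[12], models[23], planted.contig)


@pytest.fixture(scope="session")
def annotation(gene_set, planted, rss_candidates):
    return annotate_locus(gene_set, planted.contig, rss_candidates)
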