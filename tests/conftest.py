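import pytest

from anticoex import fixtures, network


@pytest.fixture(scope="session")
def default_spec():
    return fixtures.FixtureSpec(seed=7)


@pytest.fixture(scope="session")
def default_bundle(default_spec):
    return fixtures.make_bundle(default_spec)


def build_merged(bundle):
    conserved = []
    for expr_a, expr_b in bundle.expression_pairs:
        san_a = network.build_san(expr_a, bundle.psmap_a)
        san_b = network.build_san(expr_b, bundle.psmap_b)
        conserved.append(network.build_conserved_network(san_a, san_b, bundle.orthology))
    return network.merge_networks(conserved)


@pytest.fixture(scope="session")
def default_merged(default_bundle):
    return build_merged(default_bundle)


@pytest.fixture(scope="session")
def default_clusters(default_merged):
    return network.extract_all_cagcs(default_merged)


@pytest.fixture(scope="session")
def small_spec():
    # light-weight world for I/O and pipeline plumbing tests
    return fixtures.FixtureSpec(
        seed=3, n_genes=80, n_dataset_pairs=2, n_modules=2, module_size=6,
        n_samples_per_species=20,
    )


@pytest.fixture(scope="session")
def small_bundle(small_spec):
    return fixtures.make_bundle(small_spec)
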