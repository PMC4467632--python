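import numpy as np
import pytest

import diseaseflow as df


@pytest.fixture(scope="session")
def catalog():
    return df.tiny_fixtures()


@pytest.fixture(scope="session")
def path2(catalog):
    return catalog["path2"]["network"]


@pytest.fixture(scope="session")
def path2_model(path2):
    return df.FlowModel.from_network(path2)


@pytest.fixture(scope="session")
def planted():
    """Default planted 3-module fixture with ground-truth labels (seed 0)."""
    net, labels = df.generate(df.FixtureSpec(seed=0))
    return net, labels


@pytest.fixture(scope="session")
def planted_model(planted):
    net, _ = planted
    model = df.FlowModel.from_network(net)
    model.fit_clusters(K=3, seed=0)
    return model


def small_fixture(seed, **overrides):
    """Small 2-module network used by perturbation and walk sweeps."""
    params = dict(
        n_modules=2, proteins_per_module=8, p_within=0.4, p_between=0.05,
        diseases_per_module=3, genes_per_disease=2, seed=seed,
    )
    params.update(overrides)
    net, labels = df.generate(df.FixtureSpec(**params))
    return net, labels


def best_label_accuracy(P, true_labels, n_modules):
    """Argmax-membership accuracy under the best cluster-to-module map."""
    from itertools import permutations

    arg = P.argmax(axis=1)
    K = P.shape[1]
    if K < n_modules:
        return 0.0
    return max(
        float(np.mean([perm[t] == a for t, a in zip(true_labels, arg)]))
        for perm in permutations(range(K), n_modules)
    )
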