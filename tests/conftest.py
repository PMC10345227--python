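import numpy as np
import pytest

import hmotriad as ht


@pytest.fixture(scope="session")
def cohort105():
    """Default-sized cohort (105 subjects, ~170 visits)."""
    return ht.generate_cohort(ht.default_config(seed=1))


@pytest.fixture(scope="session")
def dataset105(cohort105):
    return ht.dataset_from_samples(cohort105)


@pytest.fixture(scope="session")
def prepared105(dataset105):
    return ht.prepare(dataset105)


@pytest.fixture(scope="session")
def design105(prepared105):
    spec = ht.ModelSpec(outcome="composite",
                        species_names=tuple(prepared105.retained_species))
    design = ht.build_design(prepared105.frame, spec)
    return design, ht.build_groups(design)


def random_group_problem(rng, n=None, n_groups=None):
    """A random group-LASSO problem: design, response, group structure."""
    n = int(rng.integers(30, 201)) if n is None else n
    n_groups = int(rng.integers(2, 41)) if n_groups is None else n_groups
    sizes = rng.integers(1, 4, size=n_groups)
    p = 1 + int(sizes.sum())  # unpenalized intercept + penalized columns
    X = rng.normal(size=(n, p))
    X[:, 0] = 1.0
    beta = np.zeros(p)
    nz = rng.choice(np.arange(1, p), size=max(1, p // 4), replace=False)
    beta[nz] = rng.normal(scale=2.0, size=nz.size)
    y = X @ beta + rng.normal(size=n)
    cols, groups = 1, []
    for s in sizes:
        groups.append(np.arange(cols, cols + s))
        cols += int(s)
    structure = ht.GroupStructure(n_columns=p,
                                  unpenalized_columns=np.array([0]),
                                  group_columns=groups)
    return X, y, structure
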