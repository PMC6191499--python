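import pytest

from symmorph import SymmetryPCA, layout_sample

LAYOUT_SEEDS = {"fedia": 11, "erysimum": 12, "vinca": 13, "trillium": 14}


@pytest.fixture(scope="session")
def fitted_layout():
    """Lazily fit the symmetry decomposition for a named floral layout once
    per session; returns (spec, template, map, dataset, fitted model)."""
    cache = {}

    def get(name):
        if name not in cache:
            spec, template, rmap, dataset = layout_sample(
                name, seed=LAYOUT_SEEDS[name]
            )
            model = SymmetryPCA(spec.group, rmap).fit(dataset)
            cache[name] = (spec, template, rmap, dataset, model)
        return cache[name]

    return get
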