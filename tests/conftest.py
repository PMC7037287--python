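import pytest

import vinemetals as vm


@pytest.fixture(scope="session")
def soil_table():
    return vm.load_table1()


@pytest.fixture(scope="session")
def plant_table():
    return vm.load_table2()


@pytest.fixture(scope="session")
def beverage_table():
    return vm.load_table3()


@pytest.fixture(scope="session")
def noise_free_dataset():
    """Default three-site gradient without replicate noise."""
    return vm.generate_dataset(vm.default_config(seed=11, cv_noise=0.0))
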