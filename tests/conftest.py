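import pytest

from sqbscreen import CountFingerprint


@pytest.fixture
def toy_library():
    """Four compounds over a small fragment universe, counts > 1 included."""
    return [
        CountFingerprint("A", {1: 2, 2: 1, 5: 3}),
        CountFingerprint("B", {2: 3, 5: 1}),
        CountFingerprint("C", {1: 1, 7: 2}),
        CountFingerprint("D", {7: 1, 9: 4}),
    ]


@pytest.fixture(scope="session")
def small_benchmark():
    """A compact calibrated synthetic benchmark shared across tests."""
    from sqbscreen import default_benchmark_spec, generate_benchmark

    spec = default_benchmark_spec(seed=11)
    library, labels = generate_benchmark(spec)
    return spec, library, labels
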