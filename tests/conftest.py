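import pytest

import epibinseq as eb


@pytest.fixture(scope="session")
def library():
    return eb.default_library()


@pytest.fixture(scope="session")
def library_by_id(library):
    return {c.clone_id: c for c in library}


@pytest.fixture(scope="session")
def rabs():
    return eb.default_rabs()


@pytest.fixture(scope="session")
def design():
    return eb.default_design()


@pytest.fixture(scope="session")
def clean_design(design):
    """Error-free design with uniformly high qualities (lossless chain)."""
    from dataclasses import replace

    return replace(
        design,
        per_base_error_rate=0.0,
        quality_profile=tuple([35.0] * design.read_length),
        quality_jitter_sd=0.0,
    )


PER_SET = ["Per", "Per-N52A", "Per-P53A", "Per-N54A", "Per-S55A", "Per-G56A"]
TRA_SET = ["Tra", "Tra-G101A", "Tra-D102A", "Tra-G103A", "Tra-F104A", "Tra-Y105A"]
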