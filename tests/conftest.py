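import numpy as np
import pytest

from synmorph import ClassificationParams, TerminalAnnotation, Trace


@pytest.fixture
def square_terminal() -> TerminalAnnotation:
    """Hand-built 400x400 nm square terminal with known compartments.

    PSD runs parallel to the bottom edge (y = -20, x in [150, 250]);
    a glial trace runs parallel to the top edge (y = 406, x in [100, 300]).
    Vesicles sit at easily checked positions.
    """
    square = Trace(
        np.array([[0.0, 0.0], [400.0, 0.0], [400.0, 400.0], [0.0, 400.0]]),
        closed=True,
    )
    psd = Trace(np.array([[150.0, -20.0], [250.0, -20.0]]))
    glial = Trace(np.array([[100.0, 406.0], [300.0, 406.0]]))
    vesicles = np.array([[200.0, 40.0], [200.0, 140.0], [50.0, 200.0]])
    return TerminalAnnotation(
        terminal_id="sq0",
        condition="unstimulated",
        perimeter=square,
        psd=[psd],
        glial=[glial],
        vesicles=vesicles,
    )


@pytest.fixture
def params() -> ClassificationParams:
    return ClassificationParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
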