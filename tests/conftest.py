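import itertools
import math

import numpy as np
import pytest

from sipquant.isotopes import NATURAL_ABUNDANCE


@pytest.fixture(scope="session")
def natural_table():
    return NATURAL_ABUNDANCE


def brute_force_envelope(comp: dict, c13: float, table=NATURAL_ABUNDANCE) -> np.ndarray:
    """Independent oracle: exhaustive enumeration over isotope placements.

    Every atom independently picks one of its isotopes; the envelope is the
    total probability per summed neutron offset.  Exponential in atom count,
    usable only for tiny compositions.
    """
    per_atom = []
    for el, n in comp.items():
        if n == 0:
            continue
        if el == "C":
            choices = [(0, 1.0 - c13), (1, c13)]
        else:
            choices = [(int(o), float(p)) for o, p in dict(table.data)[el]]
        per_atom.extend([choices] * n)
    max_off = sum(max(o for o, _ in ch) for ch in per_atom)
    out = np.zeros(max_off + 1)
    for combo in itertools.product(*per_atom):
        off = sum(o for o, _ in combo)
        out[off] += math.prod(p for _, p in combo)
    return out
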