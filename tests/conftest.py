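"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from ldpopsize.genotype_io import GenotypePanel, MarkerMap


def make_map(n, chroms=None, positions=None, spacing=10_000):
    """Small marker map; one chromosome, evenly spaced by default."""
    if chroms is None:
        chroms = ["1"] * n
    if positions is None:
        positions = []
        last = {}
        for c in chroms:
            last[c] = last.get(c, 0) + spacing
            positions.append(last[c])
    return MarkerMap(
        np.array([f"m{i}" for i in range(n)], dtype=object),
        np.array([str(c) for c in chroms], dtype=object),
        np.asarray(positions, dtype=np.int64),
        np.array(["A"] * n, dtype=object),
        np.array(["C"] * n, dtype=object),
    )


def make_panel(dosages, chroms=None, positions=None, name="pop", spacing=10_000):
    d = np.asarray(dosages, dtype=np.int8)
    mm = make_map(d.shape[1], chroms=chroms, positions=positions, spacing=spacing)
    return GenotypePanel(name, [f"s{i}" for i in range(d.shape[0])], d, mm)


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_101)


@pytest.fixture
def random_panel(rng):
    """40 samples x 60 markers on 2 chromosomes, moderate MAF, some missing."""
    n, m = 40, 60
    p = rng.uniform(0.1, 0.9, m)
    d = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    miss = rng.random((n, m)) < 0.02
    d[miss] = -1
    chroms = ["1"] * 30 + ["2"] * 30
    return make_panel(d, chroms=chroms)
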