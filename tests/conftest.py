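"""Shared fixtures: tiny hand-built panels and one session-scoped simulated
fixture panel (2 chromosomes, 5,000 markers, 120 lines)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ldgwas.core import (GeneticMap, GenotypeMatrix, MARKER_COLUMNS,
                         filter_markers, recomb_profile)
from ldgwas.popgen import kinship_chr
from ldgwas.simulate import fixture_config, simulate_panel, simulate_phenotypes


def make_markers(specs):
    """specs: list of (marker_id, chrom, pos_bp, pos_cM)."""
    return pd.DataFrame(
        [(m, c, p, g, "A/B", "") for m, c, p, g in specs], columns=MARKER_COLUMNS
    )


def make_panel(dose, chrom=None, pos=None, cm=None, line_ids=None):
    """Small GenotypeMatrix from a dose array with auto marker metadata."""
    dose = np.asarray(dose, dtype=float)
    n, l = dose.shape
    chrom = chrom if chrom is not None else [1] * l
    pos = pos if pos is not None else [1000 * (k + 1) for k in range(l)]
    cm = cm if cm is not None else [p / 1e6 for p in pos]
    markers = make_markers(
        [(f"m{k+1}", chrom[k], pos[k], cm[k]) for k in range(l)]
    )
    lines = line_ids or [f"L{i+1}" for i in range(n)]
    return GenotypeMatrix(lines, markers, dose)


@pytest.fixture(scope="session")
def sim_bundle():
    """Simulated fixture panel: raw pool, map, Q, truth."""
    return simulate_panel(fixture_config(seed=1))


@pytest.fixture(scope="session")
def sim_panel(sim_bundle):
    """MAF-filtered simulated panel ready for LD/GWAS work."""
    G, gmap, Q, truth = sim_bundle
    return filter_markers(G)


@pytest.fixture(scope="session")
def sim_map(sim_bundle):
    return sim_bundle[1]


@pytest.fixture(scope="session")
def sim_truth(sim_bundle):
    return sim_bundle[3]


@pytest.fixture(scope="session")
def sim_Q(sim_bundle):
    return sim_bundle[2]


@pytest.fixture(scope="session")
def sim_profile(sim_map):
    return recomb_profile(sim_map)


@pytest.fixture(scope="session")
def sim_kchr(sim_panel):
    return {c: kinship_chr(sim_panel, c, missing_policy="mean")
            for c in sim_panel.chroms}


@pytest.fixture(scope="session")
def sim_phenotypes(sim_panel, sim_truth):
    return simulate_phenotypes(sim_panel, sim_truth)


@pytest.fixture()
def two_anchor_map():
    return GeneticMap(
        pd.DataFrame(
            {"chrom": [1, 1], "pos_bp": [1_000_000, 3_000_000], "pos_cM": [1.0, 5.0]}
        )
    )
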