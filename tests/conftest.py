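"""Shared fixtures: synthetic conformer pairs built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from coldpath import (
    LateContext,
    PathState,
    harmonize_geometry,
    read_structure,
    refine_early,
    resolve_flips,
    select_pairs,
)
from coldpath.fixtures import build_peptide, preset


def _pair_from_preset(name):
    start_txt, end_txt = build_peptide(preset(name))
    start, topo = read_structure(start_txt)
    end, _ = read_structure(end_txt)
    return harmonize_geometry(start, end, topology=topo)


@pytest.fixture(scope="session")
def helix_coil_pair():
    """5-residue helix-to-strand transition (AASAA)."""
    return _pair_from_preset("helix-coil")


@pytest.fixture(scope="session")
def helix_coil_texts():
    return build_peptide(preset("helix-coil"))


@pytest.fixture(scope="session")
def clash_pair():
    """Phe/Leu sidechains crossing mid-path on a short helix."""
    return _pair_from_preset("clash")


@pytest.fixture(scope="session")
def rotamer_pair():
    """Phe/Thr crossing resolvable by a single chi1 harmonic."""
    return _pair_from_preset("rotamer")


@pytest.fixture(scope="session")
def flip_pair():
    """Leu chi1 travelling 140 deg: a flip candidate."""
    return _pair_from_preset("flip")


@pytest.fixture(scope="session")
def symmetric_pair():
    """Phe chi2 labelled 180 deg apart between the end states."""
    return _pair_from_preset("symmetric")


@pytest.fixture()
def helix_coil_path(helix_coil_pair):
    path = PathState(helix_coil_pair)
    resolve_flips(path)
    return path


@pytest.fixture(scope="session")
def early_refined(helix_coil_pair):
    """Helix-coil path after a bounded early-stage refinement."""
    path = PathState(helix_coil_pair)
    resolve_flips(path)
    pairs = select_pairs(helix_coil_pair)
    report = refine_early(path, pairs, max_cycles=3, lbfgs_maxiter=15)
    return path, pairs, report


@pytest.fixture(scope="session")
def rotamer_refined(rotamer_pair):
    """Rotamer-clash path after the full late-stage protocol."""
    from coldpath import refine_late

    path = PathState(rotamer_pair)
    resolve_flips(path)
    ctx = LateContext(rotamer_pair)
    amps_before = path.amplitude_matrix()
    report = refine_late(path, ctx)
    return path, ctx, report, amps_before


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)
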