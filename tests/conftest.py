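"""Shared fixtures: small structures and the precomputed profile suite."""

from __future__ import annotations

import numpy as np
import pytest

from pbforce import (
    Atom,
    ComplexStructure,
    DielectricParams,
    PartnerStructure,
    SolverSettings,
    build_force_profile,
    find_interface_pairs,
    orient_axis,
    separation_direction,
    shipped_fixtures,
)
from pbforce.forces import profile_grid

#: Grid spacing used for the end-to-end profile computations (Å).  0.5 Å is
#: commensurate with the 1 Å separation step along the (lattice-aligned)
#: fixture axes, so the moved partner's grid self-terms cancel exactly in
#: association-energy differences.
PROFILE_SPACING = 0.5


def two_atom_complex(q1: float, q2: float, d: float, radius: float = 1.8) -> ComplexStructure:
    a = Atom(1, "A", "Q1", (0.0, 0.0, 0.0), q1, radius)
    b = Atom(2, "B", "Q2", (0.0, 0.0, d), q2, radius)
    return ComplexStructure(PartnerStructure("A", [a]), PartnerStructure("B", [b]))


@pytest.fixture(scope="session")
def profile_suite():
    """F_int/F_ene profiles of every kept shipped fixture under both models.

    Returns ``{(fixture_name, model_tag): ForceProfile}``.  The attractive
    contact fixture is additionally profiled under Gaussian sigma = 0.7 for
    the desolvation-bump comparison.
    """
    settings = SolverSettings()
    results = {}
    for name, fix in shipped_fixtures().items():
        if not fix.passes_pruning:
            continue
        cx = fix.build()
        pairs = find_interface_pairs(cx)
        axis = orient_axis(cx, separation_direction(pairs))
        grid = profile_grid(cx, axis, spacing=PROFILE_SPACING)
        models = [
            DielectricParams(model="two_dielectric"),
            DielectricParams(model="gaussian", sigma=0.96),
        ]
        if name == "attract_bound":
            models.append(DielectricParams(model="gaussian", sigma=0.7))
        for params in models:
            results[(name, params.tag)] = build_force_profile(
                cx, axis, params, settings, grid=grid
            )
    return results
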