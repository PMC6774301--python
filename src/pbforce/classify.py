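"""Four-way classification of electrostatic force profiles.

A force-vs-distance profile f(d) (projection on the separation axis,
negative = attractive) falls into exactly one of four categories:

* ``REPULSIVE`` — never meaningfully attractive at any distance;
* ``MAX_AT_BOUND`` — the most attractive force occurs in the bound state
  (d = 0);
* ``SOFT_LANDING`` — attractive minimum at some d > 0 but repulsive at the
  bound state: electrostatics decelerates the final approach;
* ``MAX_AT_DISTANCE`` — attractive minimum at some d > 0, still attractive
  at the bound state.

A small force tolerance (default 0.01 kT/Å) absorbs solver noise around
zero when deciding "attractive" vs "repulsive".
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np


class Category(str, enum.Enum):
    MAX_AT_DISTANCE = "MAX_AT_DISTANCE"
    MAX_AT_BOUND = "MAX_AT_BOUND"
    SOFT_LANDING = "SOFT_LANDING"
    REPULSIVE = "REPULSIVE"


#: Force tolerance around zero, kT/Å.
DEFAULT_TOL = 0.01


@dataclass(frozen=True)
class ProfileCategory:
    """Category call for one profile, with the location of the force minimum."""

    label: Category
    d_min: float
    f_at_bound: float


def classify_profile(
    distances: Sequence[float],
    forces: Sequence[float],
    tol: float = DEFAULT_TOL,
) -> ProfileCategory:
    """Assign a force profile to one of the four categories.

    Rules, applied in order:  (1) if f(d) > -tol everywhere the profile is
    REPULSIVE; (2) otherwise, if the most attractive point is at d = 0 it is
    MAX_AT_BOUND (argmin ties break toward smaller d); (3) otherwise, if the
    bound-state force is repulsive (f(0) > +tol) it is SOFT_LANDING;
    (4) otherwise MAX_AT_DISTANCE.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    d = np.asarray(distances, dtype=float)
    f = np.asarray(forces, dtype=float)
    if len(d) < 5 or d[0] != 0:
        raise ValueError("profile must start at d = 0 and contain >= 5 points")
    if np.any(np.diff(d) <= 0):
        raise ValueError("distances must be strictly increasing")
    if len(d) != len(f):
        raise ValueError("distances and forces differ in length")

    i_min = int(np.argmin(f))  # np.argmin returns the first minimum: ties -> smaller d
    d_min = float(d[i_min])
    f0 = float(f[0])
    if np.all(f > -tol):
        label = Category.REPULSIVE
    elif i_min == 0:
        label = Category.MAX_AT_BOUND
    elif f0 > tol:
        label = Category.SOFT_LANDING
    else:
        label = Category.MAX_AT_DISTANCE
    return ProfileCategory(label, d_min, f0)
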