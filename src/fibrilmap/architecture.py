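"""Final-model arithmetic: the N-terminal overlap and module geometry.

With dimers of mean end-to-end length ``E`` arranged in a staggered ladder
of repeat ``L``, adjacent molecules overlap over ``O = E - L``.  The two
inputs are measured independently (two-Gaussian spot fitting for ``E``,
autocorrelation periodicity for ``L``), so their standard errors add in
quadrature.

Module geometry converts a list of fibronectin module types into the
length of their linear (beads-on-a-string) arrangement, using the
crystallographic per-module lengths: FnI 2.8 nm, FnII 2.5 nm.  No
comparable single length exists for FnIII modules in fibrillar context, so
FnIII requires an explicit user-supplied length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "MODULE_LENGTHS_NM",
    "OverlapEstimate",
    "compute_overlap",
    "linear_module_length",
]

#: Linear length of one module along an extended chain (nm).
MODULE_LENGTHS_NM: Mapping[str, float] = {
    "FnI": 2.8,
    "FnII": 2.5,
}


@dataclass(frozen=True)
class OverlapEstimate:
    """N-terminal overlap with propagated standard error (nm)."""

    O: float  # noqa: E741 - domain symbol
    se_O: float
    E: float
    se_E: float
    L: float
    se_L: float


def compute_overlap(
    E_mean: float, se_E: float, L_mean: float, se_L: float
) -> OverlapEstimate:
    """Overlap O = E - L with quadrature error propagation.

    ``E_mean`` is the mean dimer end-to-end distance, ``L_mean`` the mean
    repeat length, each with its standard error.  E must exceed L: a repeat
    longer than the molecule leaves no overlap to stagger on.
    """
    if not E_mean > L_mean > 0:
        raise ValueError(
            f"need E > L > 0 for an overlap, got E={E_mean}, L={L_mean}"
        )
    if se_E < 0 or se_L < 0:
        raise ValueError("standard errors must be >= 0")
    return OverlapEstimate(
        O=E_mean - L_mean,
        se_O=float(np.hypot(se_E, se_L)),
        E=E_mean, se_E=se_E, L=L_mean, se_L=se_L,
    )


def linear_module_length(
    composition: Sequence[str],
    extra_lengths: Mapping[str, float] | None = None,
) -> float:
    """Length (nm) of a linear arrangement of modules.

    ``composition`` is a list like ``["FnI"] * 5`` or
    ``["FnI"] * 4 + ["FnII"] * 2``; unknown module types raise unless a
    length is supplied via ``extra_lengths``.
    """
    lengths = dict(MODULE_LENGTHS_NM)
    if extra_lengths:
        lengths.update(extra_lengths)
    total = 0.0
    for module in composition:
        if module not in lengths:
            raise ValueError(
                f"no linear length known for module type {module!r}; "
                "supply one via extra_lengths"
            )
        total += lengths[module]
    return total
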