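"""Mass distribution vectors.

An MDV stores the fractions of a molecular population carrying m = 0, 1, 2, ...
extra mass units relative to the monoisotopic, tracer-free molecule.  It is the
universal labeling currency of the package: substrate pools, elementary
metabolite units (EMUs), amino acids and peptides all carry their labeling
state as an MDV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import MeasurementError

#: absolute tolerance on the unit-sum invariant
SUM_TOL = 1e-9


def as_mdv_array(values, *, tol: float = SUM_TOL, renormalize: bool = False) -> np.ndarray:
    """Validate ``values`` as an MDV and return it as a float array.

    Fractions must be non-negative (within ``tol``) and sum to one within
    ``tol``; with ``renormalize`` the sum is rescaled to exactly one provided
    the deviation is already within ``tol``.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise MeasurementError("an MDV must be a non-empty 1-D sequence")
    if np.any(arr < -tol):
        raise MeasurementError(f"MDV has negative fraction: {arr.min():g}")
    s = arr.sum()
    if abs(s - 1.0) > tol:
        raise MeasurementError(f"MDV fractions sum to {s:.12g}, not 1")
    arr = np.clip(arr, 0.0, None)
    if renormalize and arr.sum() != 1.0:  # keep exact-sum data bit-identical
        arr = arr / arr.sum()
    return arr


@dataclass(frozen=True)
class MDV:
    """A validated mass distribution vector with an optional label.

    Parameters
    ----------
    values:
        Fractions for m = 0 .. len-1; must sum to one within ``SUM_TOL``.
    label:
        Free-form identifier of the EMU, amino acid or peptide the vector
        describes.
    """

    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "values", as_mdv_array(self.values))

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, m):
        return self.values[m]

    @property
    def mean_mass(self) -> float:
        """Average number of extra mass units, sum_m m * MDV(m)."""
        return mean_mass(self.values)

    def convolve(self, other: "MDV") -> "MDV":
        label = f"{self.label}*{other.label}" if self.label or other.label else ""
        return MDV(np.convolve(self.values, other.values), label=label)


def mean_mass(values) -> float:
    arr = np.asarray(values, dtype=float)
    return float(np.dot(np.arange(arr.size), arr))


def convolve_many(mdvs) -> np.ndarray:
    """Cauchy product of a sequence of MDV arrays (left fold of convolutions)."""
    out = np.array([1.0])
    for v in mdvs:
        out = np.convolve(out, np.asarray(v, dtype=float))
    return out


def delta_mdv(n: int = 1) -> np.ndarray:
    """The fully unlabeled MDV [1, 0, ..., 0] of length ``n``."""
    out = np.zeros(n)
    out[0] = 1.0
    return out


def positional_mdv(purities) -> np.ndarray:
    """MDV of a fragment whose carbon positions are independently labeled.

    ``purities`` is a sequence of per-position heavy-isotope probabilities;
    the result is the convolution of the per-position [1-p, p] distributions.
    """
    out = np.array([1.0])
    for p in purities:
        out = np.convolve(out, [1.0 - p, p])
    return out


__all__ = [
    "MDV",
    "SUM_TOL",
    "as_mdv_array",
    "convolve_many",
    "delta_mdv",
    "mean_mass",
    "positional_mdv",
]
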