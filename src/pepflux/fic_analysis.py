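"""Flux Information Content (FIC).

FIC quantifies how strongly an experimental data set constrains the flux
profile.  The set of profiles compatible with the data is approximated by its
enveloping box — the product of per-flux allowable ranges — and

    FIC = -k * ln( prod_j max(v_max_j - v_min_j, eps) )

with k = 1 and a floor eps = 0.01 on each range so that fully determined
fluxes contribute a finite ln(1/eps).  Higher FIC means a smaller compatible
volume, i.e. more information about the fluxes.  FIC-versus-panel-size curves
show how adding peptides recovers the information lost by convolving amino
acid labeling into peptide labeling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .emu_core import EMU
from .errors import PepfluxError
from .flux_fitting import (
    FitConfig,
    FitResult,
    FluxBounds,
    FluxProfile,
    FreeFluxSpace,
    flux_bounds,
)
from .model_io import MeasurementSet, Network
from .peptide_labeling import PeptidePanel, peptide_mdv

DEFAULT_EPSILON = 0.01
DEFAULT_K = 1.0


@dataclass
class FICResult:
    fic: float
    omega: float
    ranges: dict[str, tuple[float, float]]
    epsilon: float = DEFAULT_EPSILON
    k: float = DEFAULT_K
    panel_size: int | None = None


def compute_fic(
    bounds: FluxBounds | Mapping[str, tuple[float, float]],
    epsilon: float = DEFAULT_EPSILON,
    k: float = DEFAULT_K,
    panel_size: int | None = None,
) -> FICResult:
    """FIC = -k ln prod_j max(width_j, epsilon) over every flux range."""
    ranges = bounds.ranges if isinstance(bounds, FluxBounds) else dict(bounds)
    if not ranges:
        raise PepfluxError("no flux ranges supplied")
    log_omega = 0.0
    for rid, (lo, hi) in ranges.items():
        if hi < lo:
            raise PepfluxError(f"flux {rid!r} has inverted range [{lo}, {hi}]")
        log_omega += math.log(max(hi - lo, epsilon))
    return FICResult(
        fic=-k * log_omega,
        omega=math.exp(log_omega),
        ranges=dict(ranges),
        epsilon=epsilon,
        k=k,
        panel_size=panel_size,
    )


@dataclass
class FICCurve:
    sizes: list[int]
    fics: list[float]
    amino_acid_fic: float
    #: smallest panel size whose FIC reaches the amino-acid reference, if any
    crossing: int | None
    results: list[FICResult] = field(default_factory=list)
    failures: dict[int, str] = field(default_factory=dict)

    def to_csv(self, path=None) -> str | None:
        lines = ["panel_size,fic,amino_acid_fic"]
        for n, f in zip(self.sizes, self.fics):
            lines.append(f"{n},{float(f)!r},{float(self.amino_acid_fic)!r}")
        text = "\n".join(lines) + "\n"
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None

    def plot(self, path):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(self.sizes, self.fics, "o-", label="peptide-based")
        ax.axhline(self.amino_acid_fic, color="crimson", label="amino-acid-based")
        ax.set_xlabel("number of peptides")
        ax.set_ylabel("FIC")
        ax.legend()
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def _measurement_from_mdvs(mdvs: Mapping[str, np.ndarray], sigma: float, mode: str) -> MeasurementSet:
    return MeasurementSet(
        entries={t: (np.asarray(v, float), np.full(len(v), sigma)) for t, v in mdvs.items()},
        mode=mode,
    )


def fic_curve(
    net: Network,
    aa_mdvs: Mapping[str, np.ndarray],
    panel: PeptidePanel,
    counts: Sequence[int],
    residue_map: Mapping[str, EMU],
    truth_profile: FluxProfile,
    sigma: float = 0.01,
    config: FitConfig = FitConfig(),
    epsilon: float = DEFAULT_EPSILON,
    k: float = DEFAULT_K,
    crossing_tol: float = 1e-6,
    stop_at_crossing: bool = False,
) -> FICCurve:
    """FIC as peptides are added cumulatively, against the amino-acid reference.

    ``aa_mdvs`` is the (noiseless) amino-acid labeling implied by
    ``truth_profile``; peptide target MDVs are derived from it by convolution,
    so both FICs are computed from the same underlying data with the same
    error bound ``sigma`` — the comparison is like-for-like.  The truth
    profile seeds every bound subproblem with a feasible point.  With
    ``stop_at_crossing`` the curve stops at the first size whose FIC reaches
    the amino-acid FIC (within ``crossing_tol``).
    """
    space = FreeFluxSpace(net, big=config.big)
    theta_truth = space.project(truth_profile)
    pseudo_fit = FitResult(
        profile=dict(truth_profile),
        objective=0.0,
        fitted_mdvs={},
        starts_log=[],
        mode="amino_acid",
        theta=np.atleast_1d(theta_truth),
        space=space,
    )
    aa_meas = _measurement_from_mdvs(aa_mdvs, sigma, "amino_acid")
    aa_bounds = flux_bounds(net, aa_meas, pseudo_fit, config, residue_map=residue_map)
    aa_fic = compute_fic(aa_bounds, epsilon, k).fic

    sizes, fics, results = [], [], []
    failures: dict[int, str] = {}
    crossing = None
    for n in counts:
        seqs = panel.prefix(n).sequences()
        if len(seqs) < n:
            failures[n] = f"panel holds only {len(seqs)} peptides"
            continue
        pep_mdvs = {s: peptide_mdv(s, aa_mdvs) for s in seqs}
        meas = _measurement_from_mdvs(pep_mdvs, sigma, "peptide")
        pseudo_fit.mode = "peptide"
        try:
            b = flux_bounds(net, meas, pseudo_fit, config, residue_map=residue_map)
        except PepfluxError as exc:
            failures[n] = str(exc)
            continue
        res = compute_fic(b, epsilon, k, panel_size=n)
        sizes.append(n)
        fics.append(res.fic)
        results.append(res)
        if crossing is None and res.fic >= aa_fic - crossing_tol:
            crossing = n
            if stop_at_crossing:
                break
    return FICCurve(
        sizes=sizes,
        fics=fics,
        amino_acid_fic=aa_fic,
        crossing=crossing,
        results=results,
        failures=failures,
    )


__all__ = [
    "DEFAULT_EPSILON",
    "DEFAULT_K",
    "FICCurve",
    "FICResult",
    "compute_fic",
    "fic_curve",
]
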