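"""Flux estimation from labeling data and per-flux confidence ranges.

The fit minimizes the error-weighted sum of squared deviations between
simulated and observed MDVs over the flux polytope {v : S v = 0, lb <= v <= ub,
measured fluxes fixed}.  Stoichiometry and measured-flux equalities are kept
exact by optimizing over a null-space parameterization v(theta) = v0 + N theta,
so the nonlinear solver only ever sees the free flux directions.

Confidence ranges follow the flux-variability-under-labeling idea: for each
flux, its maximum and minimum are sought subject to the simulated labeling
staying within the elementwise error bounds of the measurements.  These ranges
are the raw material of the flux information content (see ``fic_analysis``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg
import scipy.optimize as opt

from .emu_core import EMU, EMUGraph, emu_decompose, simulate_mdvs
from .errors import InfeasibleError, NonConvergenceError, PepfluxError
from .model_io import MeasurementSet, Network
from .peptide_labeling import DUMMY_RESIDUE, PeptidePanel, peptide_mdv

FluxProfile = dict[str, float]


@dataclass
class FitConfig:
    starts: int = 10
    seed: int = 0
    obj_tol: float = 1e-9
    step_tol: float = 1e-6
    sigma_default: float = 0.01
    maxiter: int = 300
    #: finite stand-in for +inf upper bounds when searching for interior points
    big: float = 1e3


# ---------------------------------------------------------------------------
# null-space parameterization of the flux polytope


class FreeFluxSpace:
    """v(theta) = v0 + N theta with S v = 0 and measured fluxes held exactly.

    ``v0`` is a strictly interior (Chebyshev-like) point of the polytope when
    one exists; ``N`` is an orthonormal null-space basis of the stacked
    stoichiometry + equality system.
    """

    def __init__(self, net: Network, fixed: Mapping[str, float] | None = None, big: float = 1e3):
        self.net = net
        self.flux_ids = net.flux_ids
        nj = len(self.flux_ids)
        S, _ = net.stoichiometric_matrix()
        if fixed is None:
            fixed = {rid: val for rid, (val, _err) in net.measured_fluxes.items()}
        eq_rows, eq_vals = [], []
        col = {rid: j for j, rid in enumerate(self.flux_ids)}
        for rid, val in fixed.items():
            row = np.zeros(nj)
            if rid in col:
                row[col[rid]] = 1.0
            else:  # net flux of a split reversible pair
                fwd, bwd = f"{rid}__f", f"{rid}__b"
                if fwd not in col:
                    raise PepfluxError(f"fixed flux {rid!r} references no reaction")
                row[col[fwd]] = 1.0
                row[col[bwd]] = -1.0
            eq_rows.append(row)
            eq_vals.append(float(val))
        A_eq = np.vstack([S] + eq_rows) if eq_rows else S
        b_eq = np.concatenate([np.zeros(S.shape[0]), eq_vals])
        self.lb = np.array([r.lb for r in net.reactions])
        self.ub = np.array([min(r.ub, big) for r in net.reactions])
        self._find_interior(A_eq, b_eq)
        self.N = scipy.linalg.null_space(A_eq)
        self.dim = self.N.shape[1]

    def _find_interior(self, A_eq, b_eq):
        nj = len(self.flux_ids)
        # maximize slack s with lb + s <= v <= ub - s
        c = np.zeros(nj + 1)
        c[-1] = -1.0
        A_ub = np.vstack(
            [
                np.hstack([-np.eye(nj), np.ones((nj, 1))]),  # lb + s <= v
                np.hstack([np.eye(nj), np.ones((nj, 1))]),  # v + s <= ub
            ]
        )
        b_ub = np.concatenate([-self.lb, self.ub])
        res = opt.linprog(
            c,
            A_ub=A_ub,
            b_ub=b_ub,
            A_eq=np.hstack([A_eq, np.zeros((A_eq.shape[0], 1))]),
            b_eq=b_eq,
            bounds=[(None, None)] * nj + [(0, None)],
            method="highs",
        )
        if not res.success:
            raise InfeasibleError(
                "no flux profile satisfies stoichiometry, bounds and fixed fluxes"
            )
        self.v0 = res.x[:nj]
        self.slack = res.x[-1]

    def v(self, theta: np.ndarray) -> np.ndarray:
        return self.v0 + self.N @ np.atleast_1d(theta)

    def profile(self, theta: np.ndarray) -> FluxProfile:
        vec = self.v(theta)
        return {rid: float(x) for rid, x in zip(self.flux_ids, vec)}

    def project(self, profile: Mapping[str, float]) -> np.ndarray:
        vec = np.array([profile[r] for r in self.flux_ids])
        return self.N.T @ (vec - self.v0)

    def bound_constraints(self):
        """Inequality g(theta) >= 0 covering both flux bounds."""

        def g(theta):
            vec = self.v(theta)
            return np.concatenate([vec - self.lb, self.ub - vec])

        def jac(theta):
            return np.vstack([self.N, -self.N])

        return {"type": "ineq", "fun": g, "jac": jac}

    def contains(self, theta, tol: float = 1e-9) -> bool:
        vec = self.v(theta)
        return bool(np.all(vec >= self.lb - tol) and np.all(vec <= self.ub + tol))

    def sample(self, rng: np.random.Generator, n: int = 1, burn: int = 1000) -> np.ndarray:
        """Coordinate hit-and-run over theta; returns an (n, dim) array."""
        if self.dim == 0:
            return np.zeros((n, 0))
        theta = np.zeros(self.dim)  # v0 is interior
        out = np.empty((n, self.dim))
        total = burn + n
        for it in range(total):
            d = rng.standard_normal(self.dim)
            d /= np.linalg.norm(d)
            Nd = self.N @ d
            vec = self.v(theta)
            lo, hi = -np.inf, np.inf
            for k in range(len(vec)):
                if abs(Nd[k]) < 1e-14:
                    continue
                t1 = (self.lb[k] - vec[k]) / Nd[k]
                t2 = (self.ub[k] - vec[k]) / Nd[k]
                lo = max(lo, min(t1, t2))
                hi = min(hi, max(t1, t2))
            if not np.isfinite(lo) or not np.isfinite(hi) or hi <= lo:
                continue
            theta = theta + rng.uniform(lo, hi) * d
            if it >= burn:
                out[it - burn] = theta
        return out


# ---------------------------------------------------------------------------
# simulated measurements for a flux profile


class LabelingModel:
    """Caches the EMU decomposition needed to predict a measurement set.

    ``residue_map`` maps an amino-acid one-letter code to the network EMU
    whose carbons form that amino acid's backbone (the biosynthetic precursor
    fragment).  Amino-acid measurements target residues directly; peptide
    measurements are convolutions of residue MDVs.
    """

    def __init__(
        self,
        net: Network,
        targets: Sequence[str],
        mode: str,
        residue_map: Mapping[str, EMU],
        corrections=None,
    ):
        self.net = net
        self.mode = mode
        self.targets = list(targets)
        self.residue_map = dict(residue_map)
        self.corrections = corrections
        if mode == "amino_acid":
            residues = [t for t in self.targets]
        else:
            residues = sorted(
                {ch for t in self.targets for ch in t if ch != DUMMY_RESIDUE}
            )
        missing = [r for r in residues if r not in self.residue_map]
        if missing:
            raise PepfluxError(f"residue(s) without EMU mapping: {missing}")
        self.residues = residues
        emus = sorted({self.residue_map[r] for r in residues}, key=str)
        self.graph: EMUGraph = emu_decompose(net, emus)

    def predict(self, v: Mapping[str, float]) -> dict[str, np.ndarray]:
        emu_mdvs = simulate_mdvs(
            self.net, v, self.graph, check_steady=False, on_dead="unlabeled"
        )
        aa_mdvs = {r: emu_mdvs[self.residue_map[r]] for r in self.residues}
        if self.mode == "amino_acid":
            return dict(aa_mdvs)
        return {
            t: peptide_mdv(t, aa_mdvs, corrections=self.corrections)
            for t in self.targets
        }


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitResult:
    profile: FluxProfile
    objective: float
    fitted_mdvs: dict[str, np.ndarray]
    starts_log: list[dict]
    mode: str
    theta: np.ndarray = field(default=None, repr=False)
    space: FreeFluxSpace = field(default=None, repr=False)


def _residual_pairs(meas: MeasurementSet, sim: Mapping[str, np.ndarray], sigma_default: float):
    """Yield (sim, obs, sigma) triplets aligned on overlapping mass indices."""
    for tid, (obs, err) in meas.entries.items():
        s = sim[tid]
        n = min(len(s), len(obs))
        sigma = np.where(err[:n] > 0, err[:n], sigma_default)
        yield s[:n], obs[:n], sigma


def fit_fluxes(
    net: Network,
    meas: MeasurementSet,
    panel: PeptidePanel | None = None,
    residue_map: Mapping[str, EMU] | None = None,
    config: FitConfig = FitConfig(),
    corrections=None,
) -> FitResult:
    """Multi-start weighted least-squares flux fit to amino-acid or peptide MDVs.

    In peptide mode the measurement targets must be sequences of the supplied
    panel.  Returns the best converged start; all starts are logged.
    """
    if residue_map is None:
        raise PepfluxError("a residue -> EMU map is required")
    if meas.mode == "peptide":
        if panel is None:
            raise PepfluxError("peptide-mode fitting requires a PeptidePanel")
        panel_seqs = set(panel.sequences())
        stray = [t for t in meas.targets() if t not in panel_seqs]
        if stray:
            raise PepfluxError(f"measurement target(s) not in panel: {stray}")
    model = LabelingModel(net, meas.targets(), meas.mode, residue_map, corrections)
    space = FreeFluxSpace(net, big=config.big)

    def objective(theta):
        sim = model.predict(space.profile(theta))
        total = 0.0
        for s, o, sig in _residual_pairs(meas, sim, config.sigma_default):
            total += float(np.sum(((s - o) / sig) ** 2))
        return total

    rng = np.random.default_rng(config.seed)
    starts = [np.zeros(space.dim)]
    if space.dim > 0 and config.starts > 1:
        starts.extend(space.sample(rng, config.starts - 1))
    log, best = [], None
    for theta0 in starts:
        if space.dim == 0:
            res_x, res_fun, ok, msg = theta0, objective(theta0), True, "fixed space"
        else:
            res = opt.minimize(
                objective,
                theta0,
                method="SLSQP",
                constraints=[space.bound_constraints()],
                options={"maxiter": config.maxiter, "ftol": config.obj_tol},
            )
            res_x, res_fun, ok, msg = res.x, float(res.fun), bool(res.success), res.message
        log.append({"theta0": np.array(theta0), "objective": res_fun, "success": ok, "message": msg})
        if ok and (best is None or res_fun < best[1]):
            best = (res_x, res_fun)
    if best is None:
        raise NonConvergenceError(
            "no start converged; log: " + "; ".join(e["message"] for e in log)
        )
    theta, fun = best
    return FitResult(
        profile=space.profile(theta),
        objective=fun,
        fitted_mdvs=model.predict(space.profile(theta)),
        starts_log=log,
        mode=meas.mode,
        theta=np.atleast_1d(theta),
        space=space,
    )


# ---------------------------------------------------------------------------
# confidence ranges


@dataclass
class FluxBounds:
    """Per-flux [v_min, v_max] feasible under labeling-within-error constraints."""

    ranges: dict[str, tuple[float, float]]
    failures: dict[str, str] = field(default_factory=dict)

    def widths(self) -> dict[str, float]:
        return {rid: hi - lo for rid, (lo, hi) in self.ranges.items()}

    def to_csv(self, profile: FluxProfile | None = None, path=None) -> str | None:
        lines = ["reaction,v_best,v_min,v_max"]
        for rid, (lo, hi) in self.ranges.items():
            vb = "" if profile is None else repr(float(profile[rid]))
            lines.append(f"{rid},{vb},{float(lo)!r},{float(hi)!r}")
        text = "\n".join(lines) + "\n"
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None


def flux_bounds(
    net: Network,
    meas: MeasurementSet,
    fit: FitResult,
    config: FitConfig = FitConfig(),
    residue_map: Mapping[str, EMU] | None = None,
    corrections=None,
) -> FluxBounds:
    """Min/max of every flux subject to |simulated - observed| <= error bound.

    2 * |J| local NLPs warm-started from the best fit.  A subproblem that
    fails is recorded per flux and the best-fit value stands in for the
    missing extremum.
    """
    if residue_map is None:
        raise PepfluxError("a residue -> EMU map is required")
    model = LabelingModel(net, meas.targets(), meas.mode, residue_map, corrections)
    space = fit.space if fit.space is not None else FreeFluxSpace(net, big=config.big)
    theta_best = fit.theta if fit.theta is not None else space.project(fit.profile)

    def labeling_gap(theta):
        if not meas.entries:  # no labeling data: pure stoichiometric FVA
            return np.array([1.0])
        sim = model.predict(space.profile(theta))
        gaps = []
        for tid, (obs, err) in meas.entries.items():
            s = sim[tid]
            n = min(len(s), len(obs))
            # the error bound is used verbatim: a zero bound is an equality
            # constraint and collapses the range onto the best fit
            gaps.append(obs[:n] + err[:n] - s[:n])
            gaps.append(s[:n] - (obs[:n] - err[:n]))
        return np.concatenate(gaps)

    cons = [space.bound_constraints(), {"type": "ineq", "fun": labeling_gap}]
    ranges: dict[str, tuple[float, float]] = {}
    failures: dict[str, str] = {}
    vbest = np.array([fit.profile[r] for r in space.flux_ids])
    for j, rid in enumerate(space.flux_ids):
        row = space.N[j] if space.dim else np.zeros(0)
        if space.dim == 0 or np.linalg.norm(row) < 1e-12:
            ranges[rid] = (float(vbest[j]), float(vbest[j]))
            continue
        extrema = []
        for sign in (+1.0, -1.0):
            res = opt.minimize(
                lambda th: sign * (space.v0[j] + row @ th),
                theta_best,
                jac=lambda th: sign * row,
                method="SLSQP",
                constraints=cons,
                options={"maxiter": config.maxiter, "ftol": 1e-10},
            )
            if res.success:
                extrema.append(space.v0[j] + row @ res.x)
            else:
                failures[rid] = str(res.message)
                extrema.append(vbest[j])
        hi, lo = float(extrema[0]), float(extrema[1])
        lo, hi = min(lo, hi, vbest[j]), max(lo, hi, vbest[j])
        ranges[rid] = (lo, hi)
    return FluxBounds(ranges=ranges, failures=failures)


__all__ = [
    "FitConfig",
    "FitResult",
    "FluxBounds",
    "FluxProfile",
    "FreeFluxSpace",
    "LabelingModel",
    "fit_fluxes",
    "flux_bounds",
]
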