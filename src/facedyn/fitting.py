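"""Fit dynamical network models to population selectivity dynamics.

Targets are per-region *differential* profiles (typical minus atypical
population response, normalized by the mean response to the whole face) and
*common* profiles (mean across the two image classes, same normalization),
on a 1 ms grid over 50-200 ms.  Fitting follows a two-step multi-start
procedure: many random in-bounds initializations are optimized against the
differential mode alone (the phenomenon of interest, ~20% of the response),
then the top fits are re-optimized against an equally weighted average of
the differential and common objectives.

The optimizer contract is "global-capable constrained minimization plus
local gradient-based polish".  Here the global stage is the seeded
multi-start (uniform in the bounds) supplemented by a fixed-budget
differential-evolution probe of the differential objective; the local stage
is bounded trust-region nonlinear least squares on the residual vector, run
in unit-cube coordinates with scale-like parameters (sigma, tau, sc, and
the connection gains, whose loop time constants go as 1/gain^2) on a log
axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import differential_evolution, least_squares
from sklearn.base import BaseEstimator

from .models import (
    ModelParams,
    ModelSpec,
    SimulationError,
    readout,
    simulate,
)
from .processing import DataError

FIT_GRID = (50.0, 200.0)          # residual grid, 1 ms spacing
NORM_WINDOW = (60, 200)           # whole-face normalization window
_PENALTY = 1e12


@dataclass
class FitTarget:
    """Normalized common- and differential-mode population profiles."""

    time: np.ndarray                  # (nt,) ms
    common: dict                      # region -> (nt,)
    diff: dict                        # region -> (nt,)
    meta: dict = field(default_factory=dict)

    def regions(self) -> list:
        return list(self.diff)


@dataclass
class FitResult:
    spec: ModelSpec
    params: ModelParams
    loss: float
    loss_diff: float
    loss_common: float
    per_start_losses: np.ndarray
    seed: int
    converged: bool


def build_fit_target(
    dataset,
    typical_images,
    atypical_images,
    reference_image: str,
    regions=("pIT", "cIT", "aIT"),
    grid=FIT_GRID,
    smooth_sd_ms: float = 5.0,
) -> FitTarget:
    """Region-averaged, whole-face-normalized common and differential
    profiles from a processed (latency-corrected, baseline-subtracted)
    dataset.

    Profiles are lightly smoothed (Gaussian, default 5 ms) before
    normalization; the normalization reference is each region's mean
    population response to the whole-face image over 60-200 ms.
    """
    t0, t1 = grid
    common, diff = {}, {}
    for region in regions:
        sites = dataset.region_sites(region)
        if not sites:
            continue
        if reference_image not in sites[0].trials:
            raise DataError(f"reference image {reference_image!r} missing")

        def pop_psth(image_ids):
            acc = np.zeros_like(sites[0].time_ms, dtype=float)
            for site in sites:
                acc += np.mean([site.trials[i].mean(axis=0) for i in image_ids], axis=0)
            return acc / len(sites)

        typ = pop_psth(typical_images)
        atyp = pop_psth(atypical_images)
        ref = pop_psth([reference_image])
        if smooth_sd_ms > 0:
            typ, atyp, ref = (gaussian_filter1d(v, smooth_sd_ms) for v in (typ, atyp, ref))
        time = sites[0].time_ms.astype(float)
        norm_mask = (time >= NORM_WINDOW[0]) & (time < NORM_WINDOW[1])
        norm = float(ref[norm_mask].mean())
        if norm <= 0:
            raise DataError(f"{region}: whole-face normalization reference <= 0")
        mask = (time >= t0) & (time <= t1)
        common[region] = ((typ + atyp) / 2.0)[mask] / norm
        diff[region] = (typ - atyp)[mask] / norm
        grid_time = time[mask]
    return FitTarget(time=grid_time, common=common, diff=diff,
                     meta={"reference_image": reference_image})


def target_from_signals(time, signals: dict, meta=None) -> FitTarget:
    """Build a FitTarget from per-region model signals of shape
    (2 conditions, nt): condition 0 is typical, 1 atypical."""
    common = {r: 0.5 * (s[0] + s[1]) for r, s in signals.items()}
    diff = {r: s[0] - s[1] for r, s in signals.items()}
    return FitTarget(time=np.asarray(time, dtype=float), common=common, diff=diff,
                     meta=meta or {})


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def _model_signals_on_grid(spec, params, time, dt):
    horizon = (0.0, float(time[-1]))
    trace = simulate(spec, params, dt=dt, horizon=horizon)
    idx = np.rint((time - trace.time[0]) / dt).astype(int)
    # overflow in extreme parameter corners is handled by the penalty path
    with np.errstate(over="ignore", invalid="ignore"):
        signals = readout(trace, spec, params)
    return {r: s[:, idx] for r, s in signals.items()}


def _mode_norms(target: FitTarget) -> dict:
    """Per-region normalizers: the sum of squares of each target mode (a
    floor keeps degenerate all-zero modes harmless)."""
    norms = {}
    for region in target.regions():
        ss_d = float(np.sum(target.diff[region] ** 2))
        ss_c = float(np.sum(target.common[region] ** 2))
        floor = 1e-12 + 1e-6 * max(ss_d, ss_c)
        norms[region] = (max(ss_d, floor), max(ss_c, floor))
    return norms


def model_loss(spec, params, target: FitTarget, mode: str = "combined",
               dt: float = 0.5) -> float:
    """Sum-of-squares loss of a model against a target.

    Each mode's squared residual is normalized by the target mode's own sum
    of squares (so a perfect fit is 0 and predicting zero gives ~1), and
    regions are weighted equally.  ``mode``: 'diff', 'common' or 'combined'
    (equal weights).
    """
    try:
        signals = _model_signals_on_grid(spec, params, target.time, dt)
    except (SimulationError, FloatingPointError, OverflowError):
        return _PENALTY
    norms = _mode_norms(target)
    missing = [r for r in target.regions() if r not in signals]
    if missing:
        raise ValueError(f"model does not read out region {missing[0]}")
    loss_diff = loss_common = 0.0
    with np.errstate(over="ignore", invalid="ignore"):
        for region in target.regions():
            model_diff = signals[region][0] - signals[region][1]
            model_common = 0.5 * (signals[region][0] + signals[region][1])
            ss_d, ss_c = norms[region]
            loss_diff += float(np.sum((model_diff - target.diff[region]) ** 2)) / ss_d
            loss_common += float(
                np.sum((model_common - target.common[region]) ** 2)) / ss_c
    if not np.isfinite(loss_diff + loss_common):
        return _PENALTY
    if mode == "diff":
        return loss_diff
    if mode == "common":
        return loss_common
    return 0.5 * (loss_diff + loss_common)


def _rescale_output(spec, vec, target: FitTarget, bounds, dt: float,
                    mode: str = "combined") -> np.ndarray:
    """Closed-form rescale of the output gain ``sc`` minimizing the given
    objective (model signals are linear in sc).  Pulls a start's output
    magnitude onto the target's scale before local optimization."""
    names = spec.param_names()
    idx = names.index("sc")
    params = ModelParams.from_vector(spec, vec)
    try:
        signals = _model_signals_on_grid(spec, params, target.time, dt)
    except (SimulationError, FloatingPointError, OverflowError):
        return vec
    norms = _mode_norms(target)
    num = den = 0.0
    with np.errstate(over="ignore", invalid="ignore"):
        for region in target.regions():
            ss_d, ss_c = norms[region]
            m_d = signals[region][0] - signals[region][1]
            m_c = 0.5 * (signals[region][0] + signals[region][1])
            if mode in ("diff", "combined"):
                num += np.dot(m_d, target.diff[region]) / ss_d
                den += np.dot(m_d, m_d) / ss_d
            if mode in ("common", "combined"):
                num += np.dot(m_c, target.common[region]) / ss_c
                den += np.dot(m_c, m_c) / ss_c
    lo_sc = max(bounds[idx][0], 1e-3 * bounds[idx][1])
    if not np.isfinite(den):
        # the start's output overflowed: shrink it to the smallest scale
        out = vec.copy()
        out[idx] = lo_sc
        return out
    if den <= 0 or not np.isfinite(num / den):
        return vec
    norm_t = sum(1.0 for _ in target.regions()) * (2.0 if mode == "combined" else 1.0)
    k = num / den
    if k <= 0:
        # anti-correlated shape: match output magnitude so gradients stay
        # informative rather than parking the start on the zero plateau
        k = math.sqrt(norm_t / den)
    out = vec.copy()
    # keep sc strictly positive: at sc = 0 every gradient vanishes
    out[idx] = float(np.clip(vec[idx] * k, lo_sc, bounds[idx][1]))
    return out


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class DynamicalModelFitter(BaseEstimator):
    """Two-step multi-start constrained fit of one model architecture.

    Parameters
    ----------
    spec : ModelSpec
        Architecture, depth and readout to fit.
    bounds : dict, optional
        Per-parameter ``(low, high)`` overrides of the default bounds table.
    n_starts, n_refine : int
        Random in-bounds initializations for the differential-mode step, and
        the number of top fits carried into the combined-objective step.
    seed : int
        Seeds the start-point stream (starts are a deterministic prefix, so
        the best loss is monotone in ``n_starts``).

    Attributes (after ``fit``)
    --------------------------
    params_ : ModelParams          best-fitting parameters (within bounds)
    loss_ : float                  combined-objective loss of the best fit
    per_start_losses_ : ndarray    differential-mode loss of every start
    result_ : FitResult
    """

    def __init__(self, spec: ModelSpec, bounds: dict | None = None,
                 n_starts: int = 50, n_refine: int = 25, seed: int = 0,
                 dt: float = 0.5, maxiter_coarse: int = 100,
                 maxiter_refine: int = 250, global_probe_iter: int = 40):
        self.spec = spec
        self.bounds = bounds
        self.n_starts = n_starts
        self.n_refine = n_refine
        self.seed = seed
        self.dt = dt
        self.maxiter_coarse = maxiter_coarse
        self.maxiter_refine = maxiter_refine
        self.global_probe_iter = global_probe_iter

    def _bounds_list(self):
        table = self.spec.bounds()
        if self.bounds:
            names = self.spec.param_names()
            table = [
                self.bounds.get("h" if n.startswith("h") else n, bb)
                for n, bb in zip(names, table)
            ]
        return table

    #: scale-like parameters are optimized in log space (their bounds span
    #: orders of magnitude, and a multiplicative step is the natural move;
    #: connection gains set loop time constants ~ 1/gain^2, so slow-feedback
    #: regimes live at small gains)
    _LOG_PARAMS = ("sigma", "tau", "sc", "a", "b", "c", "d")

    def _transforms(self, bounds):
        names = self.spec.param_names()
        lo = np.array([b[0] for b in bounds], dtype=float)
        hi = np.array([b[1] for b in bounds], dtype=float)
        log_mask = np.array([n in self._LOG_PARAMS for n in names])
        # a zero lower bound gets a small positive floor in log space
        lo_eff = np.where(log_mask & (lo <= 0), 1e-3 * hi, lo)
        log_lo = np.where(log_mask, lo_eff, 1.0)
        log_ratio = np.where(log_mask, hi / log_lo, np.e)

        def to_unit(vec):
            v = np.clip(vec, lo_eff, hi)
            lin = (v - lo_eff) / (hi - lo_eff)
            logu = np.log(v / log_lo) / np.log(log_ratio)
            return np.where(log_mask, logu, lin)

        def from_unit(u):
            u = np.clip(u, 0.0, 1.0)
            lin = lo_eff + u * (hi - lo_eff)
            logv = log_lo * log_ratio ** u
            return np.where(log_mask, logv, lin)

        return to_unit, from_unit

    def fit(self, target: FitTarget, y=None):
        spec = self.spec
        bounds = self._bounds_list()
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        rng = np.random.default_rng(self.seed)
        starts = lo + rng.random((self.n_starts, lo.size)) * (hi - lo)
        to_unit, from_unit = self._transforms(bounds)
        unit_bounds = [(0.0, 1.0)] * lo.size

        norms = _mode_norms(target)
        regions = target.regions()

        # the coarse global stage works on the scalar (log-compressed) loss;
        # local polish is trust-region nonlinear least squares on the
        # residual vector, both in (log-aware) unit-cube coordinates
        def obj(mode):
            def _f(u):
                vec = from_unit(u)
                loss = model_loss(spec, ModelParams.from_vector(spec, vec),
                                  target, mode=mode, dt=self.dt)
                return math.log1p(loss)
            return _f

        n_res = len(regions) * target.time.size * 2

        def residuals(mode):
            def _f(u):
                params = ModelParams.from_vector(spec, from_unit(u))
                try:
                    sig = _model_signals_on_grid(spec, params, target.time, self.dt)
                except (SimulationError, FloatingPointError, OverflowError):
                    return np.full(n_res, 1e3)
                # residual weights reproduce the scalar objective exactly:
                # sum(r^2) = L_diff (mode 'diff') or (L_diff + L_common)/2
                w = 2.0 if mode == "combined" else 1.0
                out = []
                with np.errstate(over="ignore", invalid="ignore"):
                    for region in regions:
                        ss_d, ss_c = norms[region]
                        m_d = sig[region][0] - sig[region][1]
                        m_c = 0.5 * (sig[region][0] + sig[region][1])
                        out.append((m_d - target.diff[region]) / np.sqrt(w * ss_d))
                        if mode == "combined":
                            out.append((m_c - target.common[region])
                                       / np.sqrt(w * ss_c))
                        else:
                            out.append(np.zeros_like(m_c))
                res = np.concatenate(out)
                res = np.where(np.isfinite(res), np.clip(res, -1e6, 1e6), 1e3)
                return res
            return _f

        def polish(vec, mode, maxiter):
            vec = _rescale_output(spec, vec, target, bounds, self.dt, mode)
            res = least_squares(
                residuals(mode), to_unit(vec), bounds=(0.0, 1.0), method="trf",
                x_scale="jac", max_nfev=maxiter * (lo.size + 1),
            )
            return float(2.0 * res.cost), from_unit(res.x)

        step1 = [polish(x0, "diff", self.maxiter_coarse) for x0 in starts]
        step1.sort(key=lambda t: t[0])
        self.per_start_losses_ = np.array([l for l, _ in step1])

        # fixed-budget evolutionary probe of the differential objective: a
        # population search finds structured optima (e.g. condition-specific
        # input patterns) that isolated descents miss.  Its budget does not
        # depend on n_starts, so the best loss stays monotone in n_starts.
        pool = step1[: self.n_refine]
        if self.global_probe_iter > 0:
            de = differential_evolution(
                obj("diff"), unit_bounds, maxiter=self.global_probe_iter,
                popsize=24, init="sobol", polish=False, tol=1e-10,
                seed=int(np.random.SeedSequence((self.seed, 1)).generate_state(1)[0]
                         % 2**31),
            )
            pool = pool + [polish(from_unit(de.x), "diff", self.maxiter_coarse)]

        best = (np.inf, None)
        for _, x0 in pool:
            fun, x = polish(x0, "combined", self.maxiter_refine)
            if fun < best[0]:
                best = (fun, x)
        if best[1] is None or not np.isfinite(best[0]) or best[0] >= _PENALTY:
            raise RuntimeError(
                f"all {self.n_starts} starts failed to converge for "
                f"{spec.architecture} ({self.per_start_losses_[:3]} ...)")

        vec = np.clip(best[1], lo, hi)
        self.params_ = ModelParams.from_vector(spec, vec)
        self.loss_ = best[0]
        self.result_ = FitResult(
            spec=spec,
            params=self.params_,
            loss=self.loss_,
            loss_diff=model_loss(spec, self.params_, target, "diff", self.dt),
            loss_common=model_loss(spec, self.params_, target, "common", self.dt),
            per_start_losses=self.per_start_losses_,
            seed=self.seed,
            converged=True,
        )
        self.target_ = target
        return self

    def predict(self, target: FitTarget | None = None) -> dict:
        """Fitted per-region signals, (2 conditions, nt), on the target grid."""
        target = target or self.target_
        return _model_signals_on_grid(self.spec, self.params_, target.time, self.dt)


def fit_model(spec: ModelSpec, target: FitTarget, bounds: dict | None = None,
              n_starts: int = 50, n_refine: int = 25, seed: int = 0,
              **kwargs) -> FitResult:
    """Functional wrapper over :class:`DynamicalModelFitter`."""
    fitter = DynamicalModelFitter(spec, bounds=bounds, n_starts=n_starts,
                                  n_refine=n_refine, seed=seed, **kwargs)
    return fitter.fit(target).result_


def noise_floor(target: FitTarget, bootstrap_targets) -> float:
    """Reliability of the target: mean combined-objective discrepancy of
    site-bootstrap replicate targets from the original."""
    losses = []
    for rep in bootstrap_targets:
        loss = 0.0
        for region in target.regions():
            d = 0.5 * np.sum((rep.diff[region] - target.diff[region]) ** 2)
            c = 0.5 * np.sum((rep.common[region] - target.common[region]) ** 2)
            loss += d + c
        losses.append(loss)
    return float(np.mean(losses))


def compare_models(specs, target: FitTarget, n_starts: int = 50,
                   n_refine: int = 25, seed: int = 0,
                   bootstrap_targets=None, **kwargs):
    """Fit every spec to the same target and rank by combined loss.

    Returns ``(table, results)``: a DataFrame sorted best-first (with the
    bootstrap noise floor attached when replicate targets are supplied), and
    the per-spec FitResults keyed by ``architecture/readout/n_stages``.
    """
    if len(list(specs)) < 2:
        raise ValueError("need at least 2 specs to compare")
    results = {}
    rows = []
    for spec in specs:
        key = f"{spec.architecture}/{spec.readout}/{spec.n_stages}"
        res = fit_model(spec, target, n_starts=n_starts, n_refine=n_refine,
                        seed=seed, **kwargs)
        results[key] = res
        rows.append({
            "model": key,
            "architecture": spec.architecture,
            "readout": spec.readout,
            "n_stages": spec.n_stages,
            "loss": res.loss,
            "loss_diff": res.loss_diff,
            "loss_common": res.loss_common,
        })
    table = pd.DataFrame(rows).sort_values("loss", kind="stable").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    if bootstrap_targets is not None:
        table.attrs["noise_floor"] = noise_floor(target, bootstrap_targets)
    return table, results
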