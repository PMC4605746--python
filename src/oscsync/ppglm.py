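"""Point-process GLM for spike trains: likelihood, penalized back-fitting
IRLS, identifiability constraints, bootstrap confidence bands, and
time-rescaling goodness of fit.

The model is a multiplicative conditional intensity

    log lambda(t | H_t, X_t) = f1(t) + f2(t - t*) + f3(Phi_t)

with f1 the stimulus (PSTH) effect on a B-spline basis over trial time, f2
the auto-history effect of the most recent spike on a B-spline basis over
lags, and f3 the oscillation-phase effect on a circular spline basis.  Any
term can be dropped (the reduced, phase-free model omits f3).  Binning the
trial at a small width D (1 ms default) gives per-bin spike indicators y_k
with p_k = lambda(t_k|.)*D, and the Poisson-approximation log likelihood

    L = sum_k [ y_k log p_k - p_k ].

Fitting minimizes Q = -L + (penalty/2)|Theta|^2 by back-fitting: cyclic
Newton/IRLS updates of the stimulus, history and phase coefficient blocks,
each guarded by step halving so accepted steps never increase Q.

Identifiability: the multiplicative form is invariant to moving constants
between terms, so after fitting the history and phase terms are renormalized
to satisfy mean(exp f2) = 1 over the history span and
(1/2pi) int exp(f3) dphi = 1, with the constants absorbed into f1.  This
leaves the intensity unchanged (exactly, at every bin where the history term
is active).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

from .basis import (BasisSet, default_history_basis, default_phase_basis,
                    default_stimulus_basis, wrap_phase)
from .spikedata import BinnedDesign

__all__ = [
    "ModelSpec",
    "FittedModel",
    "fit",
    "log_likelihood",
    "conditional_intensity",
    "enforce_identifiability",
    "confidence_bands",
    "goodness_of_fit",
    "bin_intensity",
]

_INTEGRAL_GRID = 1000  # trapezoid points for the normalization integrals


@dataclass
class ModelSpec:
    """Which terms are included and on which bases.

    penalty is the ridge weight applied to all coefficient blocks (the
    stimulus intercept direction included, unless unpenalized_intercept).
    """

    include_stimulus: bool = True
    include_history: bool = True
    include_phase: bool = True
    stimulus_basis: BasisSet | None = None
    history_basis: BasisSet | None = None
    phase_basis: BasisSet | None = None
    penalty: float = 1.0
    bin_width: float = 1e-3
    unpenalized_intercept: bool = True

    def __post_init__(self) -> None:
        if not (self.include_stimulus or self.include_history or self.include_phase):
            raise ValueError("at least one model term must be included")
        if not np.isfinite(self.penalty) or self.penalty < 0:
            raise ValueError("penalty must be finite and >= 0")

    def with_defaults(self, trial_length: float) -> "ModelSpec":
        """Fill in default bases for included terms that lack one."""
        s = replace(self)
        if s.include_stimulus and s.stimulus_basis is None:
            s.stimulus_basis = default_stimulus_basis(trial_length)
        if s.include_history and s.history_basis is None:
            s.history_basis = default_history_basis()
        if s.include_phase and s.phase_basis is None:
            s.phase_basis = default_phase_basis()
        return s


@dataclass
class FittedModel:
    """Fitted coefficients Theta = {alpha, beta, gamma} plus diagnostics.

    The phase term is f3(phi) = R(phi) gamma - phase_const; the scalar
    phase_const carries the part of the phase normalization that is not in
    the span of the circular basis (whose columns integrate to zero).
    """

    spec: ModelSpec
    alpha: np.ndarray | None
    beta: np.ndarray | None
    gamma: np.ndarray | None
    phase_const: float = 0.0
    converged: bool = False
    n_iterations: int = 0
    final_objective: float = np.nan
    objective_trace: list = field(default_factory=list)
    confidence_bands: dict | None = None

    # -- term evaluation ---------------------------------------------------
    def f1(self, t) -> np.ndarray:
        if self.alpha is None:
            return np.zeros(np.shape(np.atleast_1d(t)))
        return self.spec.stimulus_basis.evaluate(t) @ self.alpha

    def f2(self, lag) -> np.ndarray:
        """History effect at lag(s); lags are clipped to the basis span
        (constant extrapolation beyond the last knot)."""
        if self.beta is None:
            return np.zeros(np.shape(np.atleast_1d(lag)))
        lo, hi = self.spec.history_basis.span
        lag = np.clip(np.atleast_1d(lag), lo, hi)
        return self.spec.history_basis.evaluate(lag) @ self.beta

    def f3(self, phi) -> np.ndarray:
        if self.gamma is None:
            return np.zeros(np.shape(np.atleast_1d(phi)))
        return self.spec.phase_basis.evaluate(phi) @ self.gamma - self.phase_const

    # -- curves on the rate scale -----------------------------------------
    def stimulus_curve(self, t) -> np.ndarray:
        """exp(f1): the stimulus-driven rate lambda1(t), Hz."""
        return np.exp(self.f1(t))

    def history_curve(self, lag) -> np.ndarray:
        """exp(f2): the auto-history multiplier lambda2(lag)."""
        return np.exp(self.f2(lag))

    def phase_curve(self, phi) -> np.ndarray:
        """exp(f3): the phase-modulation multiplier lambda3(phi)."""
        return np.exp(self.f3(phi))

    def to_dict(self) -> dict:
        d = {
            "phase_const": float(self.phase_const),
            "converged": bool(self.converged),
            "n_iterations": int(self.n_iterations),
            "final_objective": float(self.final_objective),
            "penalty": float(self.spec.penalty),
            "bin_width": float(self.spec.bin_width),
        }
        for name, coef, basis in (
            ("stimulus", self.alpha, self.spec.stimulus_basis),
            ("history", self.beta, self.spec.history_basis),
            ("phase", self.gamma, self.spec.phase_basis),
        ):
            if coef is not None:
                d[name] = {"coefficients": np.asarray(coef).tolist(),
                           "basis": basis.to_dict()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        def block(name):
            if name in d:
                return (np.asarray(d[name]["coefficients"], dtype=float),
                        BasisSet.from_dict(d[name]["basis"]))
            return None, None

        alpha, sb = block("stimulus")
        beta, hb = block("history")
        gamma, pb = block("phase")
        spec = ModelSpec(
            include_stimulus=alpha is not None,
            include_history=beta is not None,
            include_phase=gamma is not None,
            stimulus_basis=sb, history_basis=hb, phase_basis=pb,
            penalty=float(d.get("penalty", 1.0)),
            bin_width=float(d.get("bin_width", 1e-3)),
        )
        return cls(spec, alpha, beta, gamma,
                   phase_const=float(d.get("phase_const", 0.0)),
                   converged=bool(d.get("converged", False)),
                   n_iterations=int(d.get("n_iterations", 0)),
                   final_objective=float(d.get("final_objective", np.nan)))


# ---------------------------------------------------------------------------
# Design-matrix assembly
# ---------------------------------------------------------------------------

def _design_blocks(design: BinnedDesign, spec: ModelSpec):
    """Flattened response and per-term design matrices for a binned design.

    History rows are zeroed where no previous spike exists (multiplier 1);
    lags beyond the basis span are clipped (constant extrapolation).
    """
    n, K = design.counts.shape
    Y = design.counts.reshape(-1).astype(float)
    blocks = {}
    if spec.include_stimulus:
        A1 = spec.stimulus_basis.evaluate(design.bin_times)
        blocks["stimulus"] = np.tile(A1, (n, 1))
    if spec.include_history:
        lo, hi = spec.history_basis.span
        lags = np.clip(design.last_spike_lag.reshape(-1), lo, hi)
        B = spec.history_basis.evaluate(lags)
        B[~design.has_history.reshape(-1)] = 0.0
        blocks["history"] = B
    if spec.include_phase:
        if design.phase_per_bin is None:
            raise ValueError("model includes a phase term but the design has "
                             "no phase covariate")
        blocks["phase"] = spec.phase_basis.evaluate(
            design.phase_per_bin.reshape(-1))
    return Y, blocks


def _eta(blocks, coefs) -> np.ndarray:
    parts = [blocks[k] @ coefs[k] for k in blocks]
    return np.sum(parts, axis=0) if parts else 0.0


def _pen_quad(spec, name, c) -> float:
    """theta' P theta for one block.

    With unpenalized_intercept (default) the constant direction of the
    stimulus and history B-spline blocks is projected out of the ridge
    (P = I - J/p): those constants set the overall firing-rate level and
    the arbitrary gauge split between f1 and f2, which the penalty should
    not shrink toward zero log-rate.  The circular phase basis contains no
    constant, so the gamma block is penalized in full.
    """
    q = float(c @ c)
    if name in ("stimulus", "history") and spec.unpenalized_intercept:
        q -= len(c) * float(np.mean(c)) ** 2
    return q


def _objective(Y, eta, log_dt, spec, coefs):
    logp = eta + log_dt
    p = np.exp(logp)
    L = float(Y @ logp - p.sum())
    pen = sum(_pen_quad(spec, k, c) for k, c in coefs.items())
    return -L + 0.5 * spec.penalty * pen, L


def log_likelihood(design: BinnedDesign, model: FittedModel) -> float:
    """Poisson-approximation log likelihood sum_k [y_k log p_k - p_k]."""
    spec = model.spec
    Y, blocks = _design_blocks(design, spec)
    coefs = _coef_dict(model)
    eta = _eta(blocks, coefs) - (model.phase_const if spec.include_phase else 0.0)
    logp = eta + np.log(design.bin_width)
    if not np.all(np.isfinite(logp)):
        k = int(np.flatnonzero(~np.isfinite(logp))[0])
        raise FloatingPointError(f"non-finite intensity at flat bin index {k}")
    return float(Y @ logp - np.exp(logp).sum())


def _coef_dict(model: FittedModel) -> dict:
    coefs = {}
    if model.spec.include_stimulus:
        coefs["stimulus"] = model.alpha
    if model.spec.include_history:
        coefs["history"] = model.beta
    if model.spec.include_phase:
        coefs["phase"] = model.gamma
    return coefs


# ---------------------------------------------------------------------------
# Fitting: penalized back-fitting IRLS
# ---------------------------------------------------------------------------

def _init_alpha(design: BinnedDesign, basis: BasisSet) -> np.ndarray:
    """Initialize the stimulus block from the log-PSTH (floored at 0.1 Hz)."""
    rate = design.counts.mean(axis=0) / design.bin_width
    # smooth the raw PSTH a little before taking logs
    w = max(3, int(round(0.02 / design.bin_width)))
    kernel = np.ones(w) / w
    rate = np.convolve(rate, kernel, mode="same")
    target = np.log(np.maximum(rate, 0.1))
    A1 = basis.evaluate(design.bin_times)
    coef, *_ = np.linalg.lstsq(A1, target, rcond=None)
    return coef


def _newton_block(V, Y, offset, theta, spec, name, max_steps=3, tol=1e-9):
    """Penalized Newton steps for one coefficient block with step halving.

    Returns (theta, Q) with Q the penalized objective restricted to this
    block's parameterization (other blocks folded into `offset`; their
    penalty contribution is constant and omitted here).
    """
    VtY = V.T @ Y
    penalty = spec.penalty
    p = len(theta)
    P = np.eye(p)
    if name in ("stimulus", "history") and spec.unpenalized_intercept:
        P -= np.full((p, p), 1.0 / p)

    def q_of(th):
        logp = V @ th + offset
        return float(-(Y @ logp) + np.exp(logp).sum()
                     + 0.5 * penalty * (th @ (P @ th)))

    q0 = q_of(theta)
    for _ in range(max_steps):
        mu = np.exp(V @ theta + offset)
        grad = V.T @ mu - VtY + penalty * (P @ theta)
        H = (V * mu[:, None]).T @ V + penalty * P
        try:
            c = cho_factor(H)
            step = cho_solve(c, grad)
        except np.linalg.LinAlgError:
            bump = 1e-6 * np.trace(H) / H.shape[0] + 1e-12
            H[np.diag_indices_from(H)] += bump
            step = np.linalg.solve(H, grad)
        # step halving: accepted steps never increase the objective
        scale = 1.0
        for _half in range(30):
            cand = theta - scale * step
            qc = q_of(cand)
            if np.isfinite(qc) and qc <= q0:
                break
            scale *= 0.5
        else:
            break  # no improving step found; block converged or stuck
        improved = q0 - qc
        theta, q0 = cand, qc
        if improved < tol:
            break
    return theta, q0


def fit(design: BinnedDesign, spec: ModelSpec, *, max_cycles: int = 100,
        tol: float = 1e-6, inner_steps: int = 3, init: FittedModel | None = None,
        drop_no_history: bool = False) -> FittedModel:
    """Fit the penalized point-process GLM by back-fitting IRLS.

    Blocks are updated cyclically (stimulus -> history -> phase), each by
    Newton/IRLS with step halving; the outer loop stops when the change in
    the penalized objective Q across a full cycle is at most `tol`.  The
    identifiability normalization is applied once after convergence (it
    leaves the intensity unchanged wherever the history term is active).

    `init` warm-starts from a previous fit (same spec shapes), which speeds
    up bootstrap refits.  `drop_no_history` excludes bins before each
    trial's first spike from the likelihood instead of fixing their history
    multiplier to 1.
    """
    spec = spec.with_defaults(design.trial_length)
    if design.total_spikes() < 1:
        raise ValueError("cannot fit a model to a design with no spikes")
    Y, blocks = _design_blocks(design, spec)
    keep = None
    if drop_no_history and spec.include_history:
        keep = design.has_history.reshape(-1)
        Y = Y[keep]
        blocks = {k: v[keep] for k, v in blocks.items()}
    log_dt = np.log(design.bin_width)

    coefs = {}
    if spec.include_stimulus:
        coefs["stimulus"] = (np.array(init.alpha, dtype=float)
                             if init is not None and init.alpha is not None
                             else _init_alpha(design, spec.stimulus_basis))
    if spec.include_history:
        coefs["history"] = (np.array(init.beta, dtype=float)
                            if init is not None and init.beta is not None
                            else np.zeros(spec.history_basis.n_basis))
    if spec.include_phase:
        coefs["phase"] = (np.array(init.gamma, dtype=float)
                          if init is not None and init.gamma is not None
                          else np.zeros(spec.phase_basis.n_basis))

    order = [k for k in ("stimulus", "history", "phase") if k in coefs]
    contrib = {k: blocks[k] @ coefs[k] for k in order}

    def total_q():
        eta = np.sum([contrib[k] for k in order], axis=0)
        return _objective(Y, eta, log_dt, spec, coefs)[0]

    q1 = total_q()
    trace = [q1]
    converged = False
    n_cycles = 0
    for cycle in range(max_cycles):
        n_cycles = cycle + 1
        q0 = q1
        # Re-gauge the near-flat direction shared by the stimulus and
        # history blocks (both B-spline bases contain the constant
        # function).  The convention f2 = 0 at the end of the history span
        # keeps the model internally consistent during fitting: bins with
        # no previous spike carry multiplier 1, matching the recovered
        # plateau.  The shift leaves the intensity unchanged at every
        # history-active bin; applying it before the block updates lets
        # the recorded per-cycle objectives stay monotone.
        if "stimulus" in coefs and "history" in coefs:
            c = float(spec.history_basis.evaluate(
                [spec.history_basis.span[1]])[0] @ coefs["history"])
            if c != 0.0:
                coefs["stimulus"] = coefs["stimulus"] + c
                coefs["history"] = coefs["history"] - c
                contrib["stimulus"] = blocks["stimulus"] @ coefs["stimulus"]
                contrib["history"] = blocks["history"] @ coefs["history"]
        for k in order:
            offset = log_dt + np.sum(
                [contrib[j] for j in order if j != k], axis=0)
            theta, _ = _newton_block(blocks[k], Y, offset, coefs[k],
                                     spec, k, max_steps=inner_steps)
            coefs[k] = theta
            contrib[k] = blocks[k] @ theta
        q1 = total_q()
        trace.append(q1)
        if abs(q1 - q0) <= tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"back-fitting did not converge within {max_cycles} cycles "
            f"(last |dQ| = {abs(q1 - q0):.3g})", RuntimeWarning)

    model = FittedModel(
        spec=spec,
        alpha=coefs.get("stimulus"),
        beta=coefs.get("history"),
        gamma=coefs.get("phase"),
        converged=converged,
        n_iterations=n_cycles,
        final_objective=q1,
        objective_trace=trace,
    )
    return enforce_identifiability(model)


# ---------------------------------------------------------------------------
# Identifiability
# ---------------------------------------------------------------------------

def enforce_identifiability(model: FittedModel) -> FittedModel:
    """Renormalize history and phase terms; absorb the constants into f1.

    After enforcement mean(exp f2) = 1 over the history span and
    (1/2pi) int exp(f3) dphi = 1, and the conditional intensity is unchanged
    at every bin whose history term is active (for the phase constant, at
    every bin).  Idempotent.
    """
    m = replace(model, objective_trace=list(model.objective_trace))
    shift = 0.0
    if m.spec.include_history and m.beta is not None:
        lo, hi = m.spec.history_basis.span
        tau = np.linspace(lo, hi, _INTEGRAL_GRID)
        c2 = np.log(np.trapezoid(np.exp(m.f2(tau)), tau) / (hi - lo))
        # B-spline partition of unity: subtracting c2 from every beta
        # subtracts c2 from f2 everywhere on the span (and from the clamped
        # extrapolation beyond it).
        m.beta = m.beta - c2
        shift += c2
    if m.spec.include_phase and m.gamma is not None:
        phi = np.linspace(-np.pi, np.pi, _INTEGRAL_GRID)
        c3 = np.log(np.trapezoid(np.exp(m.f3(phi)), phi) / (2 * np.pi))
        m.phase_const = m.phase_const + c3
        shift += c3
    if m.spec.include_stimulus and m.alpha is not None and shift != 0.0:
        m.alpha = m.alpha + shift  # partition of unity again
    elif shift != 0.0 and not m.spec.include_stimulus:
        # nowhere to absorb the constant: warn and leave terms normalized
        warnings.warn("no stimulus term to absorb normalization constants; "
                      "overall rate level changed", RuntimeWarning)
    return m


# ---------------------------------------------------------------------------
# Intensity evaluation
# ---------------------------------------------------------------------------

def conditional_intensity(model: FittedModel, t, last_spike_lag=None,
                          phase=None) -> np.ndarray:
    """Conditional intensity lambda(t|H_t, X_t) in Hz.

    `last_spike_lag` None (or NaN entries) marks no-history bins, whose
    history multiplier is 1.  Omitted model terms contribute factor 1.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    eta = model.f1(t) if model.spec.include_stimulus else np.zeros_like(t)
    if model.spec.include_history and last_spike_lag is not None:
        lag = np.broadcast_to(np.atleast_1d(
            np.asarray(last_spike_lag, dtype=float)), t.shape).copy()
        ok = np.isfinite(lag)
        if np.any(lag[ok] <= 0):
            raise ValueError("last_spike_lag must be positive")
        f2 = np.zeros_like(t)
        f2[ok] = model.f2(lag[ok])
        eta = eta + f2
    if model.spec.include_phase:
        if phase is None:
            raise ValueError("model includes a phase term: phase is required")
        phi = wrap_phase(np.broadcast_to(
            np.atleast_1d(np.asarray(phase, dtype=float)), t.shape))
        eta = eta + model.f3(phi)
    return np.exp(eta)


def bin_intensity(model: FittedModel, design: BinnedDesign) -> np.ndarray:
    """Per-bin intensity (n_trials, K) in Hz, conditioned on the design's
    own observed spike histories and phases."""
    spec = model.spec
    Y, blocks = _design_blocks(design, spec)
    coefs = _coef_dict(model)
    eta = _eta(blocks, coefs)
    if spec.include_phase:
        eta = eta - model.phase_const
    return np.exp(eta).reshape(design.counts.shape)


# ---------------------------------------------------------------------------
# Goodness of fit: time rescaling
# ---------------------------------------------------------------------------

def goodness_of_fit(model: FittedModel, design: BinnedDesign):
    """Time-rescaling KS check.

    Rescaled inter-spike intervals z_i = 1 - exp(-int lambda dt) are compared
    to Uniform(0,1) with a Kolmogorov-Smirnov test.  Returns (ks_statistic,
    p_value); with fewer than 10 spikes the p value is None.
    """
    lam = bin_intensity(model, design)
    dt = design.bin_width
    z = []
    for i in range(design.n_trials):
        spikes = np.flatnonzero(design.counts[i])
        if spikes.size < 2:
            continue
        cumint = np.cumsum(lam[i] * dt)
        iv = cumint[spikes[1:]] - cumint[spikes[:-1]]
        z.append(1.0 - np.exp(-iv))
    z = np.concatenate(z) if z else np.empty(0)
    if z.size == 0:
        raise ValueError("no inter-spike intervals to rescale")
    ks = stats.kstest(z, "uniform")
    if z.size < 10:
        warnings.warn("fewer than 10 rescaled intervals; KS p unreliable",
                      RuntimeWarning)
        return float(ks.statistic), None
    return float(ks.statistic), float(ks.pvalue)


# ---------------------------------------------------------------------------
# Parametric-bootstrap confidence bands
# ---------------------------------------------------------------------------

def confidence_bands(model: FittedModel, design: BinnedDesign,
                     n_boot: int = 200, seed: int | None = None,
                     level: float = 0.95, n_grid: int = 200) -> FittedModel:
    """Pointwise parametric-bootstrap confidence bands for the fitted curves.

    Simulates `n_boot` datasets from the fitted model (conditioning on the
    design's phase series), refits each, and stores per-curve pointwise
    percentile bands on the model.  Non-convergent refits are dropped with a
    warning; more than 10% dropped is an error.
    """
    if n_boot == 0:
        return model
    from . import simulate  # local import; simulate does not import ppglm

    rng = np.random.default_rng(seed)
    spec = model.spec
    grids = {}
    if spec.include_stimulus:
        lo, hi = spec.stimulus_basis.span
        grids["stimulus"] = np.linspace(lo, hi, n_grid)
    if spec.include_history:
        lo, hi = spec.history_basis.span
        grids["history"] = np.linspace(lo, hi, n_grid)
    if spec.include_phase:
        grids["phase"] = np.linspace(-np.pi, np.pi, n_grid)

    curves = {k: [] for k in grids}
    dropped = 0
    for _ in range(n_boot):
        boot = simulate.simulate_from_model(
            model, design, seed=int(rng.integers(2 ** 31)))
        try:
            refit = fit(boot, spec, init=model)
        except ValueError:
            dropped += 1
            continue
        if not refit.converged:
            dropped += 1
            continue
        if "stimulus" in curves:
            curves["stimulus"].append(refit.stimulus_curve(grids["stimulus"]))
        if "history" in curves:
            curves["history"].append(refit.history_curve(grids["history"]))
        if "phase" in curves:
            curves["phase"].append(refit.phase_curve(grids["phase"]))
    if dropped:
        warnings.warn(f"{dropped}/{n_boot} bootstrap refits dropped",
                      RuntimeWarning)
        if dropped > 0.1 * n_boot:
            raise RuntimeError(
                f"more than 10% of bootstrap refits failed ({dropped}/{n_boot})")
    a = (1.0 - level) / 2.0
    bands = {}
    for k, arrs in curves.items():
        mat = np.vstack(arrs)
        bands[k] = {
            "grid": grids[k],
            "lo": np.quantile(mat, a, axis=0),
            "hi": np.quantile(mat, 1.0 - a, axis=0),
        }
    out = replace(model)
    out.confidence_bands = bands
    return out
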