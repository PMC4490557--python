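"""Per-trace hidden Markov idealization of FRET trajectories.

Each accepted FRET trajectory is fitted with Gaussian-emission HMMs for
K = 1 .. K_max states by expectation-maximization (Baum-Welch) with
multiple seeded restarts; the number of states is selected by BIC; the
idealized trajectory is the Viterbi path. Fitted emission levels are then
mapped onto the canonical FRET classes of the experiment (0.8 / 0.6 /
0.4 / 0.2 for the L11--tRNA pair) so that states are comparable across
traces. Traces that idealize poorly are flagged and excluded downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._hmm_core import forward_backward, viterbi
from .trace_qc import FRETTrace

__all__ = [
    "HMMModel",
    "HMMFitOptions",
    "IdealizedTrace",
    "CanonicalMap",
    "LT_CANONICAL",
    "TT_CANONICAL",
    "fit_hmm",
    "select_model",
    "assess_fit",
    "map_to_canonical",
    "idealize_traces",
]

_MIN_SD = 1e-3


@dataclass
class HMMModel:
    """Gaussian-emission HMM: per-frame transition matrix, one row per state."""

    emission_mean: np.ndarray
    emission_sd: np.ndarray
    transition_prob: np.ndarray
    initial_prob: np.ndarray
    loglik: float = float("nan")
    converged: bool = True
    loglik_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_states(self) -> int:
        return len(self.emission_mean)

    def n_parameters(self) -> int:
        k = self.n_states
        return 2 * k + k * (k - 1) + (k - 1)

    def bic(self, n_obs: int) -> float:
        return -2.0 * self.loglik + self.n_parameters() * np.log(n_obs)


@dataclass(frozen=True)
class HMMFitOptions:
    n_restarts: int = 5
    tol: float = 1e-6          # relative log-likelihood change
    max_iter: int = 500
    min_sd: float = _MIN_SD
    self_prob_init: float = 0.9
    # Stride of the decimated model-validation pass. Three-point
    # smoothing correlates neighboring frames, which lets multi-state
    # models "explain" the slow wander of a single broad state; scoring
    # the winning model against K=1 on every stride-th frame (with the
    # stride-step transition matrix) removes that artifact. 0 disables.
    validation_stride: int = 3


def _log_emission(x: np.ndarray, means: np.ndarray, sds: np.ndarray) -> np.ndarray:
    z = (x[:, None] - means[None, :]) / sds[None, :]
    return -0.5 * z * z - np.log(sds[None, :]) - 0.5 * np.log(2.0 * np.pi)


def _init_params(x: np.ndarray, k: int, rng: np.random.Generator, restart: int,
                 opts: HMMFitOptions):
    # quantile-spaced means; restarts beyond the first are jittered
    q = (np.arange(k) + 0.5) / k
    means = np.quantile(x, q)
    spread = max(np.std(x), 5 * opts.min_sd)
    if restart > 0:
        means = means + rng.normal(0.0, 0.25 * spread, size=k)
    means = np.sort(means)
    sds = np.full(k, max(spread / max(k, 2), opts.min_sd))
    trans = np.full((k, k), (1.0 - opts.self_prob_init) / max(k - 1, 1))
    np.fill_diagonal(trans, opts.self_prob_init if k > 1 else 1.0)
    start = np.full(k, 1.0 / k)
    return means, sds, trans, start


def _em(x: np.ndarray, k: int, rng: np.random.Generator, restart: int,
        opts: HMMFitOptions) -> HMMModel:
    means, sds, trans, start = _init_params(x, k, rng, restart, opts)
    history = []
    prev = -np.inf
    converged = False
    for _ in range(opts.max_iter):
        gamma, xi_sum, loglik = forward_backward(
            _log_emission(x, means, sds), trans, start)
        history.append(loglik)
        if np.isfinite(prev) and abs(loglik - prev) <= opts.tol * abs(prev):
            converged = True
            break
        prev = loglik
        # M step
        w = gamma.sum(axis=0)
        w = np.maximum(w, 1e-12)
        means = gamma.T @ x / w
        var = (gamma * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / w
        sds = np.sqrt(np.maximum(var, opts.min_sd ** 2))
        if k > 1:
            rows = xi_sum.sum(axis=1, keepdims=True)
            trans = np.where(rows > 0, xi_sum / np.maximum(rows, 1e-300),
                             1.0 / k)
            trans = np.maximum(trans, 1e-12)
            trans /= trans.sum(axis=1, keepdims=True)
        start = np.maximum(gamma[0], 1e-12)
        start /= start.sum()
    order = np.argsort(means)
    return HMMModel(means[order], sds[order], trans[np.ix_(order, order)],
                    start[order], loglik=history[-1], converged=converged,
                    loglik_history=np.asarray(history))


def fit_hmm(trace: FRETTrace | np.ndarray, k: int,
            seed: int | np.random.Generator | None = None,
            options: HMMFitOptions | None = None
            ) -> tuple[HMMModel, np.ndarray]:
    """Fit a K-state Gaussian HMM and decode the most probable path.

    EM is run from ``n_restarts`` initializations (quantile-based means,
    jittered for restarts past the first); the restart with the highest
    log-likelihood is kept. Decoding is global (Viterbi). If EM does not
    converge within ``max_iter`` iterations the best model so far is
    returned with ``converged=False``.
    """
    x = trace.efficiency if isinstance(trace, FRETTrace) else np.asarray(trace, float)
    if k < 1:
        raise ValueError("K must be >= 1")
    if len(x) < 10:
        raise ValueError("trace must have >= 10 frames")
    opts = options or HMMFitOptions()
    rng = np.random.default_rng(seed)
    best: HMMModel | None = None
    for restart in range(opts.n_restarts if k > 1 else 1):
        model = _em(x, k, rng, restart, opts)
        if best is None or model.loglik > best.loglik:
            best = model
    path, _ = viterbi(_log_emission(x, best.emission_mean, best.emission_sd),
                      best.transition_prob, best.initial_prob)
    return best, path


def _decimated_loglik(x: np.ndarray, model: HMMModel, stride: int) -> float:
    """Log-likelihood of ``model`` on every stride-th frame only."""
    xd = x[::stride]
    trans = np.linalg.matrix_power(model.transition_prob, stride)
    _, _, ll = forward_backward(
        _log_emission(xd, model.emission_mean, model.emission_sd),
        trans, model.initial_prob)
    return ll


def select_model(trace: FRETTrace | np.ndarray, k_max: int,
                 seed: int | np.random.Generator | None = None,
                 options: HMMFitOptions | None = None
                 ) -> tuple[int, HMMModel, np.ndarray]:
    """Fit K = 1 .. k_max and select the number of states by BIC.

    A winning multi-state model must also beat the one-state model on a
    decimated scoring pass (see :class:`HMMFitOptions`); otherwise its
    apparent extra states only describe smoothing-correlated noise and
    the one-state fit is returned.
    """
    x = trace.efficiency if isinstance(trace, FRETTrace) else np.asarray(trace, float)
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    opts = options or HMMFitOptions()
    rng = np.random.default_rng(seed)
    best = None
    fits = {}
    for k in range(1, k_max + 1):
        model, path = fit_hmm(x, k, rng, opts)
        fits[k] = (model, path)
        score = model.bic(len(x))
        if best is None or score < best[3]:
            best = (k, model, path, score)
    k, model, path, _ = best
    stride = opts.validation_stride
    if k > 1 and stride and stride > 1 and len(x) >= 10 * stride:
        # genuine extra states keep their advantage on decimated frames;
        # states fitted to correlated noise do not (2-nat margin)
        gain = (_decimated_loglik(x, model, stride)
                - _decimated_loglik(x, fits[1][0], stride))
        if gain < 2.0:
            k, (model, path) = 1, fits[1]
    return k, model, path


def assess_fit(trace: FRETTrace | np.ndarray, model: HMMModel,
               path: np.ndarray,
               min_frames_per_state: int = 2,
               max_outlier_fraction: float = 0.01) -> list[str]:
    """Quality flags for one idealized trace (empty list = good).

    Flags a fit when any fitted state holds fewer than two frames of the
    Viterbi path, when more than 1% of frames deviate from their fitted
    level by over three fitted SDs, or when within-state residuals drift
    systematically over the trace (baseline drift masquerading as
    states).
    """
    x = trace.efficiency if isinstance(trace, FRETTrace) else np.asarray(trace, float)
    flags: list[str] = []
    counts = np.bincount(path, minlength=model.n_states)
    if np.any(counts < min_frames_per_state):
        flags.append("underpopulated_state")
    z = np.abs(x - model.emission_mean[path]) / model.emission_sd[path]
    if np.mean(z > 3.0) > max_outlier_fraction:
        flags.append("excess_residuals")
    resid = x - model.emission_mean[path]
    for k in range(model.n_states):
        r = resid[path == k]
        if len(r) < 20:
            continue
        half = len(r) // 2
        a, b = r[:half], r[half:]
        se = np.sqrt(np.var(a) / len(a) + np.var(b) / len(b))
        # threshold of 6 allows for the noise correlation that three-point
        # smoothing introduces while still catching baseline drift
        if se > 0 and abs(a.mean() - b.mean()) > 6.0 * se:
            flags.append("residual_drift")
            break
    return flags


@dataclass(frozen=True)
class CanonicalMap:
    """Assignment of fitted emission levels to named FRET classes."""

    centers: tuple[tuple[str, float], ...]
    tolerance: float = 0.1

    def __post_init__(self) -> None:
        vals = sorted(v for _, v in self.centers)
        if any(b - a < 0.1 for a, b in zip(vals, vals[1:])):
            raise ValueError("canonical centers must be distinct by >= 0.1")

    def assign(self, level: float) -> str | None:
        """Nearest center within +/- tolerance; ties go to the lower center."""
        best_label, best_dist, best_center = None, np.inf, np.inf
        for label, center in self.centers:
            d = abs(level - center)
            if d < best_dist - 1e-12 or (abs(d - best_dist) <= 1e-12
                                         and center < best_center):
                best_label, best_dist, best_center = label, d, center
        return best_label if best_dist <= self.tolerance else None

    def center_of(self, label: str) -> float:
        return dict(self.centers)[label]


#: L11--tRNA (Lt) FRET classes
LT_CANONICAL = CanonicalMap(centers=(("0.8", 0.8), ("0.6", 0.6),
                                     ("0.4", 0.4), ("0.2", 0.2)))
#: tRNA--tRNA (tt) FRET classes
TT_CANONICAL = CanonicalMap(centers=(("0.9", 0.9), ("0.7", 0.7),
                                     ("0.5", 0.5), ("0.0", 0.0)))


@dataclass
class IdealizedTrace:
    """Viterbi-idealized trajectory with canonical class labels."""

    trace_id: str
    state_index: np.ndarray
    level_mean: np.ndarray            # fitted emission mean of occupied state
    model: HMMModel
    score: float                      # BIC of the selected model
    frame_interval: float
    quality_flags: tuple[str, ...] = ()
    canonical_class: tuple[str | None, ...] = ()

    def __len__(self) -> int:
        return len(self.state_index)

    @property
    def flagged(self) -> bool:
        return len(self.quality_flags) > 0


def map_to_canonical(ideal: IdealizedTrace, canonical: CanonicalMap
                     ) -> IdealizedTrace:
    """Label every frame with the canonical class of its fitted level.

    A fitted level farther than the tolerance from every canonical center
    leaves its frames unassigned and flags the trace. A one-state fit
    whose level sits nearly equidistant between two centers (within
    0.04 of the midpoint) is also flagged: such levels are typically
    time-averages of unresolved dynamics, and attributing the whole
    trace to either class would be arbitrary.
    """
    assignment = [canonical.assign(m) for m in ideal.model.emission_mean]
    classes = tuple(assignment[s] for s in ideal.state_index)
    flags = ideal.quality_flags
    if any(a is None for a in assignment):
        if "unassigned_level" not in flags:
            flags = flags + ("unassigned_level",)
    if ideal.model.n_states == 1:
        dists = sorted(abs(ideal.model.emission_mean[0] - c)
                       for _, c in canonical.centers)
        if len(dists) > 1 and dists[1] - dists[0] < 0.08:
            if "ambiguous_level" not in flags:
                flags = flags + ("ambiguous_level",)
    ideal.canonical_class = classes
    ideal.quality_flags = flags
    return ideal


def idealize_traces(traces, k_max: int,
                    canonical: CanonicalMap = LT_CANONICAL,
                    seed: int = 0,
                    options: HMMFitOptions | None = None,
                    ) -> list[IdealizedTrace]:
    """Model-select, decode, quality-check and canonically map many traces.

    Each trace gets an independent, reproducible sub-seed derived from
    ``seed`` so results do not depend on trace order or count.
    """
    import zlib

    out: list[IdealizedTrace] = []
    for trace in traces:
        sub = np.random.default_rng(
            np.random.SeedSequence(
                entropy=seed,
                spawn_key=(zlib.crc32(trace.trace_id.encode()),)))
        k, model, path = select_model(trace, k_max, sub, options)
        flags = assess_fit(trace, model, path)
        if not model.converged:
            flags.append("not_converged")
        ideal = IdealizedTrace(
            trace_id=trace.trace_id,
            state_index=path,
            level_mean=model.emission_mean[path],
            model=model,
            score=model.bic(len(trace)),
            frame_interval=trace.frame_interval,
            quality_flags=tuple(flags),
        )
        out.append(map_to_canonical(ideal, canonical))
    return out
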