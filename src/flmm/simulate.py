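"""Synthetic nested longitudinal functional data with known truth.

The generative model mirrors the structure of trial-level photometry
experiments: per subject i, session l, trial j,

    Y_ijl(s) = beta_0(s) + gamma_0i(s) + x_ijl * (beta_1(s) + gamma_1i(s))
               + ... + eps_ijl(s),

with subject-level random curves ``gamma_ki ~ N(0, Sigma_k)`` drawn once
per subject, and error curves ``eps_ijl ~ N(0, eps_scale * B_{m(i)})``
drawn independently across trials, where ``B_1..B_M`` are per-animal base
covariance matrices and ``eps_scale`` (default 5) inflates them to induce
extra within-trial correlation. The base-matrix index m(i) is drawn
uniformly without replacement when n <= M; for n > M the first M subjects
take indices 1..M and the remainder are drawn without replacement.

Defaults emulate a two-condition (short/long cue-reward delay) design:
15 Hz sampling, 100 trials per session, the condition switching between
sessions, and inter-reward intervals exponential with mean 14 s.

The true covariance surfaces of real recordings are not published, so the
defaults substitute parametric stand-ins (squared-exponential families
with a white-noise nugget) whose magnitudes give single-trial traces with
realistic signal-to-noise; user-supplied matrices are accepted for exact
replication when available.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .data import FunctionalDataset, TimeGrid

__all__ = [
    "SimTruth",
    "EventConfig",
    "default_covariances",
    "generate_functional",
    "generate_trial_events",
    "delay_template",
    "null_template",
    "simpsons_template",
    "bump",
]

DEFAULT_M_BASE = 7
DEFAULT_EPS_SCALE = 5.0
DEFAULT_RATE = 15.0
DEFAULT_TRIALS_PER_SESSION = 100
DEFAULT_IRI_MEAN = 14.0


def bump(t: np.ndarray, amplitude: float, center: float, width: float) -> np.ndarray:
    """Smooth Gaussian bump, the building block of the true coefficient curves."""
    return amplitude * np.exp(-0.5 * ((t - center) / width) ** 2)


def default_covariances(
    grid: TimeGrid,
    family: str = "squared-exponential",
    scale: float = 1.0,
    lengthscale: float = 0.5,
    nugget: float = 0.0,
) -> np.ndarray:
    """Stationary S x S covariance on the grid (PSD by construction).

    ``family`` is ``"squared-exponential"`` or ``"AR1"``; ``scale`` is the
    pointwise variance, ``lengthscale`` the correlation length in seconds,
    and ``nugget`` an optional white-noise variance added to the diagonal.
    """
    if scale <= 0 or lengthscale <= 0:
        raise ValueError("scale and lengthscale must be positive")
    t = grid.points
    d = np.abs(t[:, None] - t[None, :])
    if family == "squared-exponential":
        C = scale * np.exp(-0.5 * (d / lengthscale) ** 2)
    elif family == "AR1":
        C = scale * np.exp(-d / lengthscale)
    else:
        raise ValueError(f"unknown covariance family '{family}'")
    if nugget:
        C = C + nugget * np.eye(t.size)
    return C


@dataclasses.dataclass
class EventConfig:
    """Trial/event timing parameters of the emulated behavioural task."""

    iri_mean: float = DEFAULT_IRI_MEAN        # inter-reward interval, seconds
    delay_short: float = 3.0                  # cue-to-reward delay, short condition
    delay_long: float = 9.0                   # (2 s / 8 s also occur in the source task)
    lick_latency_law: tuple = ("lognormal", -1.0, 0.5)  # (law, mu, sigma) of first-lick latency

    def __post_init__(self):
        if self.iri_mean <= 0:
            raise ValueError("iri_mean must be positive")
        if self.delay_short < 0 or self.delay_long < 0:
            raise ValueError("delays must be nonnegative")


@dataclasses.dataclass
class SimTruth:
    """Generative parameters of a synthetic experiment (the known truth).

    ``beta`` maps covariate names (``"1"`` for the intercept) to true
    S-vector coefficient functions; ``Sigma_gamma`` maps a subset of those
    names to subject-level S x S random-curve covariances.
    """

    grid: TimeGrid
    beta: dict[str, np.ndarray]
    Sigma_gamma: dict[str, np.ndarray]
    Sigma_eps_base: list[np.ndarray]
    eps_scale: float = DEFAULT_EPS_SCALE
    n_subjects: int = 7
    n_sessions: int = 2
    trials_per_session: int = DEFAULT_TRIALS_PER_SESSION
    condition: str | None = "delay"   # binary covariate assigned by session half
    cue_window: tuple = (0.0, 2.0)

    def __post_init__(self):
        S = self.grid.n_points
        for name, b in self.beta.items():
            if np.asarray(b).shape != (S,):
                raise ValueError(f"beta['{name}'] must have length {S}")
        for name, C in list(self.Sigma_gamma.items()) + [
            (f"eps[{i}]", C) for i, C in enumerate(self.Sigma_eps_base)
        ]:
            C = np.asarray(C)
            if C.shape != (S, S):
                raise ValueError(f"covariance '{name}' must be {S}x{S}")
            if not np.allclose(C, C.T):
                raise ValueError(f"covariance '{name}' not symmetric")
            w = np.linalg.eigvalsh(C)
            if w.min() < -1e-8 * max(w.max(), 1.0):
                raise ValueError(f"covariance '{name}' not positive semi-definite")
        if self.eps_scale <= 0:
            raise ValueError("eps_scale must be positive")
        if self.trials_per_session < 1:
            raise ValueError("need at least one trial per session")

    @property
    def n_base(self) -> int:
        return len(self.Sigma_eps_base)

    def eps_covariance(self, base_index: int) -> np.ndarray:
        """Error covariance actually used for a subject: eps_scale x base matrix."""
        return self.eps_scale * self.Sigma_eps_base[base_index]


def assign_base_indices(n: int, M: int, rng: np.random.Generator) -> np.ndarray:
    """Subject -> base-error-matrix assignment (0-based indices).

    For n <= M the indices are drawn uniformly without replacement from
    {0..M-1}; for n > M the first M subjects take 0..M-1 and the remaining
    n - M are drawn without replacement.
    """
    if n <= M:
        return rng.choice(M, size=n, replace=False)
    parts = [np.arange(M)]
    left = n - M
    while left > 0:  # block-fill keeps "without replacement" within each block
        take = min(left, M)
        parts.append(rng.choice(M, size=take, replace=False))
        left -= take
    return np.concatenate(parts)


def _draw_curves(C: np.ndarray, size: int, rng: np.random.Generator) -> np.ndarray:
    w, V = np.linalg.eigh(C)
    w = np.clip(w, 0.0, None)
    root = V * np.sqrt(w)
    return rng.standard_normal((size, C.shape[0])) @ root.T


def generate_functional(truth: SimTruth, seed: int, extra_covariates=None):
    """Draw one synthetic dataset from the truth; returns (dataset, latents).

    The latent record carries every random draw (random-effect curves per
    subject, base-matrix assignment, and error curves) so that moment and
    recovery tests can condition on them.
    """
    rng = np.random.default_rng(seed)
    S = truth.grid.n_points
    n, nses, T = truth.n_subjects, truth.n_sessions, truth.trials_per_session

    subjects = [f"s{i + 1}" for i in range(n)]
    rows = []
    for i, subj in enumerate(subjects):
        for l in range(1, nses + 1):
            for j in range(1, T + 1):
                rows.append((subj, l, j))
    trials = pd.DataFrame(rows, columns=["subject", "session", "trial"])
    trials["session_number"] = trials["session"].astype(float)
    trials["trial_number"] = trials["trial"].astype(float)
    if truth.condition is not None:
        # condition switches halfway through the sessions (e.g. short->long delay)
        trials[truth.condition] = (trials["session"] > nses // 2).astype(float)
    if extra_covariates is not None:
        for name, fn in extra_covariates.items():
            trials[name] = fn(trials, rng)

    base_index = assign_base_indices(n, truth.n_base, rng)
    gammas = {
        name: _draw_curves(C, n, rng) for name, C in truth.Sigma_gamma.items()
    }

    L = len(trials)
    Y = np.zeros((L, S))
    for name, b in truth.beta.items():
        x = np.ones(L) if name == "1" else trials[name].to_numpy(dtype=float)
        Y += x[:, None] * np.asarray(b)[None, :]

    subj_codes = trials["subject"].map({s: i for i, s in enumerate(subjects)}).to_numpy()
    for name, g in gammas.items():
        x = np.ones(L) if name == "1" else trials[name].to_numpy(dtype=float)
        Y += x[:, None] * g[subj_codes]

    eps = np.zeros((L, S))
    for i in range(n):
        mask = subj_codes == i
        C = truth.eps_covariance(base_index[i])
        eps[mask] = _draw_curves(C, int(mask.sum()), rng)
    Y += eps

    dataset = FunctionalDataset(Y=Y, grid=truth.grid, trials=trials)
    latents = {
        "seed": seed,
        "base_index": base_index,
        "gammas": gammas,
        "eps": eps,
        "subjects": subjects,
    }
    return dataset, latents


def generate_trial_events(
    config: EventConfig,
    n_sessions: int,
    trials_per_session: int,
    seed: int,
    subject: str = "s1",
) -> pd.DataFrame:
    """Trial table for one subject with IRI, trial/session/reward counters and lick latency.

    Inter-reward intervals are i.i.d. exponential with mean ``iri_mean``;
    Reward Number is the cumulative trial count pooled across sessions;
    Trial Number resets each session.
    """
    rng = np.random.default_rng(seed)
    total = n_sessions * trials_per_session
    iri = rng.exponential(scale=config.iri_mean, size=total)
    law, mu, sigma = config.lick_latency_law
    if law == "lognormal":
        lick = rng.lognormal(mean=mu, sigma=sigma, size=total)
    elif law == "exponential":
        lick = rng.exponential(scale=mu, size=total)
    else:
        raise ValueError(f"unknown lick latency law '{law}'")
    session = np.repeat(np.arange(1, n_sessions + 1), trials_per_session)
    trial = np.tile(np.arange(1, trials_per_session + 1), n_sessions)
    return pd.DataFrame(
        {
            "subject": subject,
            "session": session,
            "trial": trial,
            "trial_number": trial.astype(float),
            "session_number": session.astype(float),
            "reward_number": np.arange(1, total + 1, dtype=float),
            "iri": iri,
            "lick_latency": lick,
        }
    )


# ---------------------------------------------------------------------------
# Canned truths


def _default_grid() -> TimeGrid:
    # 3 s window around the alignment event at 15 Hz (S = 45)
    return TimeGrid.regular(-1.0, 45, DEFAULT_RATE)


def _default_eps_bases(grid: TimeGrid, scale: float = 0.5) -> list[np.ndarray]:
    """M = 7 per-animal base error covariances with mildly varying SNR/smoothness."""
    scales = scale * np.linspace(0.7, 1.3, DEFAULT_M_BASE)
    lengths = np.linspace(0.15, 0.30, DEFAULT_M_BASE)
    return [
        default_covariances(
            grid, "squared-exponential", s, l, nugget=0.1 * s
        )
        for s, l in zip(scales, lengths)
    ]


def delay_template(
    n_subjects: int = 7,
    n_sessions: int = 2,
    trials_per_session: int = DEFAULT_TRIALS_PER_SESSION,
    effect_scale: float = 1.0,
    grid: TimeGrid | None = None,
) -> SimTruth:
    """Two-condition (short/long delay) truth with a biphasic condition effect.

    The condition coefficient has a positive early lobe and a smaller
    negative late lobe, so a window summary averages over opposing
    effects while the functional fit can resolve them. ``effect_scale``
    multiplies the condition effect (0 gives the null truth).
    """
    grid = grid or _default_grid()
    t = grid.points
    beta0 = bump(t, 1.5, 0.4, 0.35)
    beta1 = effect_scale * (bump(t, 0.8, 0.3, 0.25) - bump(t, 0.3, 1.3, 0.25))
    Sg0 = default_covariances(grid, "squared-exponential", 0.0625, 0.5)
    Sg1 = default_covariances(grid, "squared-exponential", 0.0225, 0.5)
    return SimTruth(
        grid=grid,
        beta={"1": beta0, "delay": beta1},
        Sigma_gamma={"1": Sg0, "delay": Sg1},
        Sigma_eps_base=_default_eps_bases(grid),
        eps_scale=DEFAULT_EPS_SCALE,
        n_subjects=n_subjects,
        n_sessions=n_sessions,
        trials_per_session=trials_per_session,
        condition="delay",
        cue_window=(0.0, 2.0),
    )


def null_template(**kw) -> SimTruth:
    """Delay template with the condition effect identically zero."""
    return delay_template(effect_scale=0.0, **kw)


def simpsons_template(
    n_subjects: int = 5,
    n_sessions: int = 4,
    trials_per_session: int = 20,
    between_slope: float = 0.4,
    within_slope: float = -0.06,
    seed: int = 0,
):
    """Nested-trend fixture: sessions trend up while trials-within-session trend down.

    The session-level intercepts increase across sessions (slope
    ``between_slope`` per session on the response bump) while the signal
    decreases across trials within a session (``within_slope`` per
    trial), so pooling a window summary against cumulative reward number
    yields a positive slope even though the within-session trend is
    negative — the hierarchical-pooling reversal the functional model
    resolves by modelling both covariates.

    Returns ``(dataset, truth)`` for the given seed.
    """
    if between_slope != 0 and within_slope != 0 and between_slope * within_slope >= 0:
        raise ValueError("between_slope and within_slope must have opposite signs")
    grid = _default_grid()
    t = grid.points
    shape = bump(t, 1.0, 0.3, 0.3)
    truth = SimTruth(
        grid=grid,
        beta={
            "1": bump(t, 1.0, 0.4, 0.35),
            "session_number": between_slope * shape,
            "trial_number": within_slope * shape,
        },
        Sigma_gamma={"1": default_covariances(grid, "squared-exponential", 0.04, 0.5)},
        Sigma_eps_base=_default_eps_bases(grid, scale=0.3),
        eps_scale=DEFAULT_EPS_SCALE,
        n_subjects=n_subjects,
        n_sessions=n_sessions,
        trials_per_session=trials_per_session,
        condition=None,
        cue_window=(0.0, 2.0),
    )
    dataset, _ = generate_functional(truth, seed)
    rn = (dataset.trials["session"] - 1) * trials_per_session + dataset.trials["trial"]
    dataset.trials["reward_number"] = rn.astype(float)
    return dataset, truth
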