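"""Global least-squares fitting of the conversion model to time courses.

The four rate constants (k_n, k_n_rev, k_plus, k_off) are fitted
simultaneously to the observed monomer and oligomer series m(t) and x(t)
by Levenberg–Marquardt minimization of a stacked weighted residual.  The
critical nucleus size n_c stays fixed at 2; the average fibril length f_a
is held at its configured value (fit quality is not strongly sensitive to
it) and the average oligomer length x_a is taken from the data (the
count-weighted mean of the detected oligomer sizes over the reaction).

The optimization runs in log10 parameter space, which enforces positivity
and lets the search span decades; a multistart around a heuristic
initialization guards against local minima.  Weights are 1/sd where
per-point standard deviations are supplied, else each series is normalized
by its maximum so monomer and oligomer data contribute comparably.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .conversion_model import (
    IntegrationError,
    KineticState,
    ModelConfig,
    RateConstants,
    Trajectory,
    integrate,
)

logger = logging.getLogger(__name__)

_PENALTY = 1e6
_PARAM_NAMES = ("k_n", "k_n_rev", "k_plus", "k_off")


@dataclass
class KineticDataset:
    """Observed monomer and oligomer time courses for one construct."""

    times: np.ndarray
    m_obs: np.ndarray
    x_obs: np.ndarray
    m_sd: np.ndarray | None = None
    x_sd: np.ndarray | None = None
    label: str = ""
    config: ModelConfig = field(default_factory=ModelConfig)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.m_obs = np.asarray(self.m_obs, dtype=float)
        self.x_obs = np.asarray(self.x_obs, dtype=float)
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.times[0] < 0:
            raise ValueError("times must be non-negative")
        for name in ("m_obs", "x_obs"):
            arr = getattr(self, name)
            if arr.shape != self.times.shape:
                raise ValueError(f"{name} must match times in length")
            if np.any(arr < 0):
                raise ValueError(f"{name} must be >= 0")
        for name in ("m_sd", "x_sd"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != self.times.shape or np.any(arr <= 0):
                    raise ValueError(f"{name} must be positive and match times")
                setattr(self, name, arr)
        if len(self.times) < 4:
            raise ValueError("need at least 4 time points (one per free parameter)")


@dataclass
class FitResult:
    """Fitted rate constants with local uncertainty and diagnostics."""

    params: RateConstants
    stderr: dict[str, float]
    identifiable: dict[str, bool]
    rss: float
    success: bool
    message: str
    trajectory: Trajectory | None = None
    n_starts: int = 1
    seed: int | None = None
    weighting: str = ""

    def to_dict(self) -> dict:
        return {
            "params": {n: float(getattr(self.params, n)) for n in _PARAM_NAMES},
            "n_c": int(self.params.n_c),
            "stderr": {k: float(v) for k, v in self.stderr.items()},
            "identifiable": {k: bool(v) for k, v in self.identifiable.items()},
            "rss": float(self.rss),
            "success": self.success,
            "message": self.message,
            "n_starts": self.n_starts,
            "seed": self.seed,
            "weighting": self.weighting,
        }


def _weights(dataset: KineticDataset) -> tuple[np.ndarray, np.ndarray, str]:
    if dataset.m_sd is not None and dataset.x_sd is not None:
        return 1.0 / dataset.m_sd, 1.0 / dataset.x_sd, "1/sd"
    # floor the normalizer at a small fraction of m0 so an all-zero series
    # cannot produce overflowing weights
    floor = 1e-9 * dataset.config.m0
    w_m = np.full_like(dataset.m_obs, 1.0 / max(dataset.m_obs.max(), floor))
    w_x = np.full_like(dataset.x_obs, 1.0 / max(dataset.x_obs.max(), floor))
    return w_m, w_x, "series-max normalization"


def _simulate(theta: np.ndarray, dataset: KineticDataset, n_c: int) -> Trajectory:
    params = RateConstants(*(10.0**theta), n_c=n_c)
    times = dataset.times
    if times[0] > 0:
        times = np.concatenate([[0.0], times])
        traj = integrate(params, dataset.config, times)
        return Trajectory(
            times=times[1:], m=traj.m[1:], x=traj.x[1:], f=traj.f[1:],
            config=traj.config, params=params,
        )
    return integrate(params, dataset.config, times)


def residual_vector(theta: np.ndarray, dataset: KineticDataset, n_c: int = 2) -> np.ndarray:
    """Stacked weighted residuals of m(t) and x(t) at log10 parameters ``theta``.

    Integration failures return a flat large-penalty vector so the optimizer
    retreats from pathological parameter regions.
    """
    w_m, w_x, _ = _weights(dataset)
    theta = np.asarray(theta, dtype=float)
    if np.any(theta > 12.0) or np.any(theta < -15.0) or not np.all(np.isfinite(theta)):
        # rate constants beyond any physical regime: steer the optimizer back
        return np.full(2 * len(dataset.times), _PENALTY)
    try:
        traj = _simulate(theta, dataset, n_c)
    except (IntegrationError, ValueError, OverflowError) as err:
        logger.warning("integration failed at theta=%s: %s", theta, err)
        return np.full(2 * len(dataset.times), _PENALTY)
    r_m = w_m * (traj.m - dataset.m_obs)
    r_x = w_x * (traj.x - dataset.x_obs)
    return np.concatenate([r_m, r_x])


def auto_init(dataset: KineticDataset, n_c: int = 2) -> RateConstants:
    """Heuristic starting point for the rate constants.

    k_n from the early oligomer slope (x ≈ k_n·m0^n_c·t), k_plus from the
    monomer half-depletion timescale, k_n_rev from quasi-steady oligomers
    at the peak, and k_off from the apparent final-state balance.
    """
    t, m, x = dataset.times, dataset.m_obs, dataset.x_obs
    m0 = dataset.config.m0
    f_a = dataset.config.f_a
    pos = (x > 0) & (t > 0)
    if pos.any():
        i = int(np.argmax(pos))
        k_n = x[i] / (m0**n_c * t[i])
    else:
        k_n = 1e-6
    x_peak = max(x.max(), 1e-9)
    k_n_rev = k_n * m0**n_c / x_peak  # QSS: k_n m^nc ≈ k_n_rev x at the peak
    depleted = m <= 0.5 * (m[0] + m[-1])
    t_half = t[int(np.argmax(depleted))] if depleted.any() and t[int(np.argmax(depleted))] > 0 else max(t[-1] / 2, 1e-3)
    # fibril mass gained ~ f_a k_plus m x t_half
    k_plus = max(m0 - m[-1], 0.1 * m0) / (f_a * m0 * x_peak * t_half)
    f_end = max((m0 - m[-1]) / f_a, 1e-9)
    k_off = k_plus * max(m[-1], 0.1 * m0) * x_peak / f_end
    clip = lambda v: float(np.clip(v, 1e-12, 1e12))
    return RateConstants(clip(k_n), clip(k_n_rev), clip(k_plus), clip(k_off), n_c=n_c)


def fit_rate_constants(
    dataset: KineticDataset,
    init: RateConstants | None = None,
    multistart: int = 16,
    spread_decades: float = 3.0,
    seed: int | None = 0,
    n_c: int = 2,
    unidentifiable_rel_stderr: float = 10.0,
) -> FitResult:
    """Globally fit the four rate constants by multistart Levenberg–Marquardt.

    ``multistart`` log-uniform draws within ±``spread_decades`` decades of
    the (auto- or user-supplied) initialization are each refined by LM in
    log10 space; the best optimum is returned.  Standard errors come from
    the local covariance (JᵀJ)⁻¹·s²; a parameter whose relative standard
    error exceeds ``unidentifiable_rel_stderr`` (or whose covariance is
    singular) is flagged unidentifiable.
    """
    if init is None:
        init = auto_init(dataset, n_c=n_c)
    theta0 = np.log10([init.k_n, init.k_n_rev, init.k_plus, init.k_off])
    rng = np.random.default_rng(seed)
    starts = [theta0]
    for _ in range(max(multistart - 1, 0)):
        starts.append(theta0 + rng.uniform(-spread_decades, spread_decades, 4))

    best = None
    n_ok = 0
    for theta_start in starts:
        try:
            sol = least_squares(
                residual_vector, theta_start, args=(dataset, n_c), method="lm",
                xtol=1e-12, ftol=1e-12, max_nfev=400,
            )
        except Exception as err:  # pragma: no cover - defensive
            logger.warning("start %s failed: %s", theta_start, err)
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        n_ok += 1
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError(
            f"all {len(starts)} optimization starts failed for dataset "
            f"{dataset.label!r}"
        )

    theta = best.x
    params = RateConstants(*(10.0**theta), n_c=n_c)
    rss = float(2 * best.cost)
    n_obs, n_par = 2 * len(dataset.times), 4
    stderr: dict[str, float] = {}
    identifiable: dict[str, bool] = {}
    J = best.jac
    dof = max(n_obs - n_par, 1)
    s2 = rss / dof
    try:
        cov_log = np.linalg.inv(J.T @ J) * s2
        var = np.diag(cov_log)
        singular = np.any(var < 0) or not np.all(np.isfinite(var))
    except np.linalg.LinAlgError:
        singular = True
    for i, name in enumerate(_PARAM_NAMES):
        k = getattr(params, name)
        if singular:
            stderr[name] = float("nan")
            identifiable[name] = False
            continue
        sd_log10 = float(np.sqrt(var[i]))
        sd_k = k * np.log(10.0) * sd_log10  # delta method on 10**theta
        stderr[name] = sd_k
        identifiable[name] = sd_k / k <= unidentifiable_rel_stderr
    _, _, weighting = _weights(dataset)
    traj = _simulate(theta, dataset, n_c)
    return FitResult(
        params=params,
        stderr=stderr,
        identifiable=identifiable,
        rss=rss,
        success=True,
        message=f"{n_ok}/{len(starts)} starts converged; best cost {best.cost:.4g}",
        trajectory=traj,
        n_starts=len(starts),
        seed=seed,
        weighting=weighting,
    )


def average_oligomer_length(sizes, counts=None) -> float:
    """Count-weighted mean apparent oligomer size x_a over pooled events.

    ``sizes`` may be a list of OligomerEvent, an array of per-event sizes,
    or size values paired with ``counts``.
    """
    if counts is None:
        values = np.asarray(
            [getattr(s, "size_app", s) for s in np.atleast_1d(np.asarray(sizes, dtype=object))],
            dtype=float,
        )
        if values.size == 0:
            raise ValueError("no oligomer observations")
        return float(values.mean())
    sizes = np.asarray(sizes, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if sizes.size == 0 or counts.sum() <= 0:
        raise ValueError("no oligomer observations")
    return float((sizes * counts).sum() / counts.sum())


def read_dataset(path, label: str = "", config: ModelConfig | None = None) -> KineticDataset:
    """Read a dataset from CSV columns time_h, m_uM[, m_sd], x_uM[, x_sd]."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"time_h", "m_uM", "x_uM"}
    if not required.issubset(df.columns):
        raise ValueError(f"dataset must have columns {sorted(required)}")
    return KineticDataset(
        times=df["time_h"].to_numpy(),
        m_obs=df["m_uM"].to_numpy(),
        x_obs=df["x_uM"].to_numpy(),
        m_sd=df["m_sd"].to_numpy() if "m_sd" in df else None,
        x_sd=df["x_sd"].to_numpy() if "x_sd" in df else None,
        label=label,
        config=config or ModelConfig(),
    )


def write_dataset(dataset: KineticDataset, path) -> None:
    import pandas as pd

    cols = {"time_h": dataset.times, "m_uM": dataset.m_obs, "x_uM": dataset.x_obs}
    if dataset.m_sd is not None:
        cols["m_sd"] = dataset.m_sd
    if dataset.x_sd is not None:
        cols["x_sd"] = dataset.x_sd
    pd.DataFrame(cols).to_csv(path, index=False)
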