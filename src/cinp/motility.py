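"""Single-cell migration statistics and persistent-random-walk (PRW) model fitting.

A cell tracked every ``dt`` minutes yields a 2D trajectory ``(x(t), y(t))``.
Its mean-squared displacement over a time lag tau,

    MSD(tau) = < (x(t+tau) - x(t))^2 + (y(t+tau) - y(t))^2 >,

is fitted with the persistent-random-walk model

    MSD(tau) = 2 S^2 P (tau - P (1 - exp(-tau/P))) + 4 sigma^2,

where ``S`` is the cell speed (um/min), ``P`` the persistence time (min; the
decay time of directional correlation) and ``sigma`` (um) the static
positional-tracking error, which contributes a constant 4 sigma^2 floor.
Short lags (tau << P) are ballistic, MSD ~ S^2 tau^2; long lags are diffusive,
MSD ~ 2 S^2 P tau.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import lmfit
from scipy import stats

__all__ = [
    "Trajectory",
    "MSDCurve",
    "PRWFit",
    "FitOptions",
    "InsufficientDataError",
    "prw_msd",
    "compute_msd",
    "fit_prw",
    "instantaneous_speeds",
    "net_invasion_distance",
    "split_at_division",
    "summarize_groups",
]


class InsufficientDataError(ValueError):
    """Raised when a trajectory or MSD curve is too short for the requested analysis."""


@dataclass(frozen=True)
class Trajectory:
    """One cell's time-stamped 2D positions (times in minutes, positions in um)."""

    cell_id: str
    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    division_frame: int | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if t.ndim != 1 or t.size < 3:
            raise ValueError(f"trajectory {self.cell_id!r}: need >= 3 time points, got {t.size}")
        if x.shape != t.shape or y.shape != t.shape:
            raise ValueError(f"trajectory {self.cell_id!r}: times/x/y length mismatch")
        if not (np.isfinite(t).all() and np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValueError(f"trajectory {self.cell_id!r}: non-finite coordinates")
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"trajectory {self.cell_id!r}: times must be strictly increasing")
        if self.division_frame is not None and not (0 < self.division_frame < t.size - 1):
            raise ValueError(
                f"trajectory {self.cell_id!r}: division_frame must index an interior frame"
            )
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return self.times.size

    @property
    def dt(self) -> float:
        """Sampling interval in minutes; raises if timestamps are not uniform."""
        steps = np.diff(self.times)
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ValueError(f"trajectory {self.cell_id!r}: non-uniform time stamps")
        return float(steps[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass(frozen=True)
class MSDCurve:
    """Lag-indexed mean-squared displacements (lags min, msd um^2)."""

    lags: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=float)
        msd = np.asarray(self.msd, dtype=float)
        n_pairs = np.asarray(self.n_pairs, dtype=int)
        if not (lags.shape == msd.shape == n_pairs.shape):
            raise ValueError("lags/msd/n_pairs length mismatch")
        if lags.size and (np.any(np.diff(lags) <= 0) or np.any(lags <= 0)):
            raise ValueError("lags must be strictly increasing and positive")
        if np.any(msd < 0) or np.any(n_pairs < 1):
            raise ValueError("msd must be >= 0 and n_pairs >= 1")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "msd", msd)
        object.__setattr__(self, "n_pairs", n_pairs)


@dataclass(frozen=True)
class PRWFit:
    """Fitted PRW parameters: S (um/min), P (min), sigma (um)."""

    S: float
    P: float
    sigma: float
    residual_sse: float
    converged: bool
    stderr: Mapping[str, float | None] = field(default_factory=dict)
    at_bound: tuple[str, ...] = ()
    message: str = ""


@dataclass(frozen=True)
class FitOptions:
    """Options for :func:`fit_prw`.

    weight_by_pairs: weight each lag's squared residual by its pair count.
    s_init / p_init / sigma_init: override the automatic initial guesses.
    p_upper: override the persistence-time upper bound (min).
    """

    weight_by_pairs: bool = True
    relative_residuals: bool = True
    s_init: float | None = None
    p_init: float | None = None
    sigma_init: float = 0.0
    p_upper: float | None = None
    sigma_upper: float = 100.0


def prw_msd(tau: np.ndarray, S: float, P: float, sigma: float) -> np.ndarray:
    """Closed-form PRW MSD: 2 S^2 P (tau - P(1 - e^(-tau/P))) + 4 sigma^2."""
    tau = np.asarray(tau, dtype=float)
    return 2.0 * S**2 * P * (tau - P * (-np.expm1(-tau / P))) + 4.0 * sigma**2


def compute_msd(traj: Trajectory, max_lag_fraction: float = 1.0 / 3.0) -> MSDCurve:
    """Time-averaged MSD over all overlapping start times.

    For every integer lag ``k*dt`` up to ``max_lag_fraction`` of the track
    duration the squared displacement is averaged over the ``n - k``
    overlapping windows; the pair count per lag is recorded so that fits can
    weight lags by how well they are estimated.
    """
    if not 0 < max_lag_fraction <= 1:
        raise ValueError("max_lag_fraction must be in (0, 1]")
    dt = traj.dt
    n = len(traj)
    max_k = int(np.floor(max_lag_fraction * (n - 1)))
    if max_k < 2:
        raise InsufficientDataError(
            f"trajectory {traj.cell_id!r}: fewer than 2 usable lags at "
            f"max_lag_fraction={max_lag_fraction}"
        )
    ks = np.arange(1, max_k + 1)
    msd = np.empty(max_k)
    for i, k in enumerate(ks):
        dx = traj.x[k:] - traj.x[:-k]
        dy = traj.y[k:] - traj.y[:-k]
        msd[i] = np.mean(dx * dx + dy * dy)
    return MSDCurve(lags=ks * dt, msd=msd, n_pairs=n - ks)


def ensemble_msd(trajectories: Sequence[Trajectory], max_lag_fraction: float = 1.0 / 3.0) -> MSDCurve:
    """Pair-count-weighted average of per-track MSD curves (pooled estimator)."""
    curves = [compute_msd(t, max_lag_fraction) for t in trajectories]
    n_lags = max(c.lags.size for c in curves)
    ref = max(curves, key=lambda c: c.lags.size)
    total = np.zeros(n_lags)
    pairs = np.zeros(n_lags, dtype=int)
    for c in curves:
        m = c.lags.size
        if not np.allclose(c.lags, ref.lags[:m]):
            raise ValueError("trajectories have incompatible lag grids")
        total[:m] += c.msd * c.n_pairs
        pairs[:m] += c.n_pairs
    return MSDCurve(lags=ref.lags, msd=total / pairs, n_pairs=pairs)


def fit_prw(msd: MSDCurve, options: FitOptions | None = None) -> PRWFit:
    """Weighted least-squares fit of the PRW model to an MSD curve.

    Initial guesses: S0 from the short-lag ballistic regime sqrt(MSD(tau1))/tau1,
    P0 = 5 lag steps, sigma0 = 0. Bounds keep all parameters positive; a
    parameter landing on a bound is reported in ``at_bound`` (a purely
    ballistic curve, for instance, pegs P at its upper bound because the model
    approaches S^2 tau^2 as P -> infinity).
    """
    opts = options or FitOptions()
    if msd.lags.size < 4:
        raise InsufficientDataError(f"need >= 4 lags to fit, got {msd.lags.size}")
    tau, y = msd.lags, msd.msd
    dt = tau[0]
    s_ball = max(np.sqrt(max(y[0], 1e-12)) / tau[0], 1e-6)
    p_hi = opts.p_upper if opts.p_upper is not None else 30.0 * tau[-1]
    s_hi = 100.0 * (opts.s_init if opts.s_init is not None else s_ball)
    w = np.sqrt(msd.n_pairs / msd.n_pairs.max()) if opts.weight_by_pairs else np.ones_like(y)
    # Fractional residuals keep the fit from being dominated by the huge
    # long-lag MSD values, whose ensemble wiggles are strongly correlated.
    if opts.relative_residuals:
        scale = np.where(y > 0, y, y[y > 0].min() if (y > 0).any() else 1.0)
        w = w / scale

    # Internally the constant term is fitted as the noise floor nf = 4 sigma^2
    # (linear in the model, so sigma = 0 is recovered exactly; d/d sigma of
    # 4 sigma^2 vanishes at 0 and stalls the optimizer otherwise).  The SSE
    # surface also has local minima trading the noise floor against P, so the
    # optimizer is multi-started over a small grid of (P0, sigma0) with S0
    # solved from the last lag.
    starts: list[tuple[float, float, float]] = []
    if opts.s_init is not None or opts.p_init is not None:
        starts.append((
            opts.s_init if opts.s_init is not None else s_ball,
            opts.p_init if opts.p_init is not None else 5.0 * dt,
            opts.sigma_init,
        ))
    else:
        for p0 in (5.0 * dt, tau[-1] / 3.0, tau[-1]):
            for sg0 in (0.0, min(np.sqrt(max(y[0], 0.0)) / 2.0, opts.sigma_upper)):
                tail = y[-1] - 4.0 * sg0**2
                denom = 2.0 * p0 * (tau[-1] - p0 * (-np.expm1(-tau[-1] / p0)))
                s0 = np.sqrt(max(tail, 1e-12) / denom) if denom > 0 else s_ball
                starts.append((min(max(s0, 1e-6), s_hi), p0, sg0))

    def residual(p: lmfit.Parameters) -> np.ndarray:
        model = 2.0 * p["S"].value ** 2 * p["P"].value * (
            tau - p["P"].value * (-np.expm1(-tau / p["P"].value))
        ) + p["nf"].value
        return w * (model - y)

    out = None
    best_sse = np.inf
    for s0, p0, sg0 in starts:
        params = lmfit.Parameters()
        params.add("S", value=s0, min=1e-9, max=s_hi)
        params.add("P", value=min(max(p0, dt / 10.0), p_hi), min=dt / 10.0, max=p_hi)
        params.add("nf", value=4.0 * sg0**2, min=0.0, max=4.0 * opts.sigma_upper**2)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                cand = lmfit.minimize(
                    residual, params, method="least_squares",
                    xtol=1e-15, ftol=1e-15, gtol=1e-15,
                )
        except Exception:  # pragma: no cover - a single start may fail
            continue
        sse = float(np.sum(np.asarray(cand.residual) ** 2))
        if sse < best_sse:
            out, best_sse = cand, sse
    if out is None:  # pragma: no cover - all starts failed
        return PRWFit(
            S=np.nan, P=np.nan, sigma=np.nan, residual_sse=np.inf,
            converged=False, message="optimizer failure on every start",
        )

    pf = out.params
    sigma = float(np.sqrt(pf["nf"].value) / 2.0)
    fitted = prw_msd(tau, pf["S"].value, pf["P"].value, sigma)
    sse = float(np.sum((fitted - y) ** 2))
    at_bound = tuple(
        name
        for name, key in (("S", "S"), ("P", "P"), ("sigma", "nf"))
        if pf[key].value >= pf[key].max * (1 - 1e-6)
        or (pf[key].min > 0 and pf[key].value <= pf[key].min * (1 + 1e-6))
    )
    stderr: dict[str, float | None] = {
        name: (None if pf[name].stderr is None else float(pf[name].stderr))
        for name in ("S", "P")
    }
    # delta method: sigma = sqrt(nf)/2 so se(sigma) = se(nf) / (8 sigma)
    nf_se = pf["nf"].stderr
    stderr["sigma"] = float(nf_se / (8.0 * sigma)) if nf_se is not None and sigma > 0 else None
    return PRWFit(
        S=float(pf["S"].value),
        P=float(pf["P"].value),
        sigma=sigma,
        residual_sse=sse,
        converged=bool(out.success),
        stderr=stderr,
        at_bound=at_bound,
        message=str(out.message),
    )


def instantaneous_speeds(traj: Trajectory) -> np.ndarray:
    """Frame-to-frame displacement magnitude over frame interval (um/min)."""
    if len(traj) < 2:
        raise InsufficientDataError("need >= 2 points for speeds")
    d = np.hypot(np.diff(traj.x), np.diff(traj.y))
    return d / np.diff(traj.times)


def net_invasion_distance(traj: Trajectory) -> float:
    """Euclidean distance between first and last tracked positions (um)."""
    return float(np.hypot(traj.x[-1] - traj.x[0], traj.y[-1] - traj.y[0]))


def split_at_division(traj: Trajectory) -> tuple[Trajectory, Trajectory]:
    """Split a track at its division frame into pre- and post-division segments.

    Both segments include the division frame (the mother is tracked up to
    division, one daughter from it), and both must remain valid trajectories.
    """
    k = traj.division_frame
    if k is None:
        raise ValueError(f"trajectory {traj.cell_id!r}: no division_frame set")
    if k < 2 or k > len(traj) - 3:
        raise InsufficientDataError(
            f"trajectory {traj.cell_id!r}: division at frame {k} leaves a segment "
            "with fewer than 3 points"
        )
    pre = Trajectory(f"{traj.cell_id}:pre", traj.times[: k + 1], traj.x[: k + 1], traj.y[: k + 1])
    post = Trajectory(f"{traj.cell_id}:post", traj.times[k:], traj.x[k:], traj.y[k:])
    return pre, post


def summarize_groups(
    groups: Mapping[str, Sequence[float]],
    method: str = "auto",
) -> pd.DataFrame:
    """Two-group comparison table with a two-sided Mann-Whitney U p-value.

    ``groups`` maps exactly two group labels to samples (e.g. per-cell speeds
    pre vs post division). Returns one row per group with n, median and
    quartiles; the U statistic and p-value are attached to both rows.
    ``method`` is passed to scipy ('auto' uses the exact distribution for
    small tie-free samples, the normal approximation otherwise).
    """
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {len(groups)}")
    labels = list(groups)
    a = np.asarray(groups[labels[0]], dtype=float)
    b = np.asarray(groups[labels[1]], dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs n >= 3")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    rows = []
    for label, sample in ((labels[0], a), (labels[1], b)):
        q1, med, q3 = np.percentile(sample, [25, 50, 75])
        rows.append({"group": label, "n": sample.size, "median": med, "q1": q1, "q3": q3,
                     "U": float(res.statistic), "p_value": float(res.pvalue)})
    return pd.DataFrame(rows).set_index("group")
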