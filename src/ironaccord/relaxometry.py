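"""Mono-exponential T2* fitting with the long-TE truncation method.

The fitting substrate is an :class:`EchoTrain` (magnitude signal at each echo
time). :func:`truncation_scan` drops echoes one at a time from the long-TE end
and fits each level; :func:`select_fit` picks a final fit under a stated
policy (by default: highest occupied R-squared bin, then the most echoes).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "EchoTrain",
    "FitResult",
    "TruncationTrace",
    "ConfigurationError",
    "SelectionError",
    "fit_monoexponential",
    "truncation_scan",
    "select_fit",
    "r2_bin_index",
    "r2_bin_label",
    "R2_BIN_LABELS",
    "R2_BELOW_LABEL",
]

MIN_ECHOES = 3

# R-squared bins: 0.01-wide from 0.95; the top bin is closed above so that
# R^2 == 1 is representable. Values below 0.95 fall into a catch-all bin that
# exists so selection is total; downstream stratification excludes it.
R2_BIN_EDGE = 0.95
R2_BIN_WIDTH = 0.01
R2_N_BINS = 5
R2_BIN_LABELS: Tuple[str, ...] = (
    "[0.95,0.96)",
    "[0.96,0.97)",
    "[0.97,0.98)",
    "[0.98,0.99)",
    "[0.99,1.00]",
)
R2_BELOW_LABEL = "<0.95"

# fixed seed for the single random restart, keeping fits deterministic
_RESTART_SEED = 0x5EED


class ConfigurationError(ValueError):
    """Invalid configuration value (bad bin settings, echo minimum, ...)."""


class SelectionError(RuntimeError):
    """No valid truncation level available for selection."""


def r2_bin_index(r_squared: float) -> int:
    """Bin index of an R^2 value: 0..4 for [0.95, 1.00], -1 below 0.95."""
    if not np.isfinite(r_squared) or r_squared < R2_BIN_EDGE:
        return -1
    idx = int((r_squared - R2_BIN_EDGE) / R2_BIN_WIDTH)
    return min(idx, R2_N_BINS - 1)


def r2_bin_label(r_squared: float) -> str:
    idx = r2_bin_index(r_squared)
    return R2_BELOW_LABEL if idx < 0 else R2_BIN_LABELS[idx]


@dataclass(frozen=True)
class EchoTrain:
    """One patient/ROI's magnitude signal at each echo time.

    Echoes are sorted by TE on construction, so input order is irrelevant.
    """

    te: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        te = np.asarray(self.te, dtype=float)
        sig = np.asarray(self.signal, dtype=float)
        if te.ndim != 1 or sig.ndim != 1 or te.size != sig.size:
            raise ValueError("te and signal must be 1-D and equal length")
        order = np.argsort(te, kind="stable")
        te, sig = te[order], sig[order]
        if np.any(np.diff(te) <= 0):
            raise ValueError("echo times must be distinct")
        if np.any(te <= 0):
            raise ValueError("echo times must be positive")
        if np.any(sig < 0) or not np.all(np.isfinite(sig)):
            raise ValueError("signals must be finite and nonnegative")
        object.__setattr__(self, "te", te)
        object.__setattr__(self, "signal", sig)

    def __len__(self) -> int:
        return int(self.te.size)

    def truncate(self, n_keep: int) -> "EchoTrain":
        """Keep the first (shortest-TE) ``n_keep`` echoes."""
        if not (1 <= n_keep <= len(self)):
            raise ValueError("n_keep out of range")
        return EchoTrain(self.te[:n_keep], self.signal[:n_keep])


@dataclass(frozen=True)
class FitResult:
    """Outcome of one mono-exponential fit."""

    s0_hat: float
    t2star_hat: float
    r_squared: float
    n_echoes: int
    removed_tes: Tuple[float, ...] = ()
    valid: bool = True

    @property
    def r2_bin(self) -> str:
        return r2_bin_label(self.r_squared)


@dataclass(frozen=True)
class TruncationTrace:
    """Ordered fits from the full echo set down to the minimum echo count."""

    levels: Tuple[FitResult, ...]

    def __post_init__(self) -> None:
        if not self.levels:
            raise ValueError("trace must have at least one level")
        counts = [lv.n_echoes for lv in self.levels]
        if any(a - b != 1 for a, b in zip(counts, counts[1:])):
            raise ValueError("levels must decrease by exactly one echo")

    def __len__(self) -> int:
        return len(self.levels)

    def __iter__(self):
        return iter(self.levels)


def _loglinear_init(te: np.ndarray, sig: np.ndarray) -> Tuple[float, float]:
    """OLS line through log(signal) vs TE over positive signals."""
    pos = sig > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(te[pos], np.log(sig[pos]), 1)
        s0 = float(np.exp(intercept))
        t2 = -1.0 / slope if slope < 0 else 10.0 * float(te[-1])
    else:
        s0 = float(max(sig.max(), 1.0))
        t2 = float(te[-1])
    return max(s0, 1e-12), max(t2, 1e-6)


def _r_squared(y: np.ndarray, resid: np.ndarray) -> float:
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else -np.inf
    return 1.0 - ss_res / ss_tot


def fit_monoexponential(train: EchoTrain) -> FitResult:
    """Nonlinear least-squares fit of ``s0 * exp(-TE / t2star)``.

    R^2 is the centered coefficient of determination on the untransformed
    magnitudes of the echoes actually fitted. On failure (all-zero signal or
    optimizer non-convergence after one seeded restart) a result flagged
    invalid is returned instead of raising.
    """
    te, sig = train.te, train.signal
    n = len(train)
    if n < MIN_ECHOES:
        raise ValueError(f"need at least {MIN_ECHOES} echoes, got {n}")
    invalid = FitResult(np.nan, np.nan, -np.inf, n, valid=False)
    if not np.any(sig > 0):
        return invalid

    def resid(p: np.ndarray) -> np.ndarray:
        return p[0] * np.exp(-te / p[1]) - sig

    x0 = np.array(_loglinear_init(te, sig))
    lb, ub = [1e-12, 1e-9], [np.inf, np.inf]
    sol = least_squares(resid, x0, bounds=(lb, ub), method="trf",
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not (sol.success and np.all(np.isfinite(sol.x))):
        rng = np.random.default_rng(_RESTART_SEED)
        x1 = x0 * rng.uniform(0.5, 2.0, size=2)
        sol = least_squares(resid, x1, bounds=(lb, ub), method="trf",
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if not (sol.success and np.all(np.isfinite(sol.x))):
            return invalid
    s0_hat, t2_hat = float(sol.x[0]), float(sol.x[1])
    return FitResult(s0_hat, t2_hat, _r_squared(sig, sol.fun), n)


def truncation_scan(train: EchoTrain, min_echoes: int = MIN_ECHOES) -> TruncationTrace:
    """Fit the train at every truncation level.

    Level k fits the first ``n - k`` echoes, for k = 0 .. n - min_echoes;
    echoes are always removed from the long-TE end, one at a time.
    """
    if min_echoes < MIN_ECHOES:
        raise ConfigurationError(f"min_echoes must be >= {MIN_ECHOES}")
    n = len(train)
    if n < min_echoes:
        raise ValueError(f"train has {n} echoes, need >= {min_echoes}")
    levels = []
    for k in range(n - min_echoes + 1):
        sub = train.truncate(n - k)
        fit = fit_monoexponential(sub)
        removed = tuple(float(t) for t in train.te[n - k:])
        levels.append(replace(fit, removed_tes=removed))
    return TruncationTrace(tuple(levels))


def select_fit(trace: TruncationTrace, policy: str = "binned-max-r2") -> FitResult:
    """Choose the final fit from a truncation trace.

    ``binned-max-r2`` (default): assign each valid level's R^2 to the 0.01
    bins from 0.95 (plus a below-0.95 bin); among levels in the highest
    occupied bin, return the one with the most echoes.
    ``global-max-r2``: return the level with the highest R^2 outright
    (ties broken toward more echoes).
    """
    valid = [lv for lv in trace if lv.valid]
    if not valid:
        raise SelectionError("no valid truncation level")
    if policy == "binned-max-r2":
        best_bin = max(r2_bin_index(lv.r_squared) for lv in valid)
        pool = [lv for lv in valid if r2_bin_index(lv.r_squared) == best_bin]
        return max(pool, key=lambda lv: lv.n_echoes)
    if policy == "global-max-r2":
        return max(valid, key=lambda lv: (lv.r_squared, lv.n_echoes))
    raise ConfigurationError(f"unknown selection policy {policy!r}")
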