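"""Profile-likelihood identifiability analysis.

For a calibrated optimum theta-hat, the profile of parameter i is
``chi2_PL(theta_i) = min over theta_{j != i} of chi2(theta)``: the least
achievable objective with parameter i clamped at each grid value.  The
confidence interval collects the theta_i whose profile exceeds the optimum
by less than the threshold ``Delta_alpha = chi2 quantile(alpha, df)``
(df = 1 for pointwise intervals).  A parameter is identifiable when both CI
ends are finite; a profile that stays below the threshold out to a bound
leaves that side unbounded (practical non-identifiability), and a profile
flat in both directions marks structural non-identifiability.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2 as chi2_dist

__all__ = [
    "ThresholdSpec",
    "ProfileResult",
    "ProfileSurvey",
    "profile_parameter",
    "profile_confidence_interval",
    "classify_identifiability",
    "profile_all",
]

#: Fraction of Delta_alpha below which a profile direction counts as flat.
FLATNESS_FRACTION = 0.05


@dataclass(frozen=True)
class ThresholdSpec:
    """Chi-square threshold for profile CIs."""

    alpha: float = 0.95
    df: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.df < 1:
            raise ValueError("df must be >= 1")

    @property
    def delta(self) -> float:
        """Delta_alpha: the chi-square quantile at (alpha, df)."""
        return float(chi2_dist.ppf(self.alpha, self.df))


@dataclass(frozen=True)
class ProfileResult:
    """Per-parameter profile curve, CI, and identifiability class."""

    name: str
    grid: np.ndarray = field(repr=False)           # parameter values, ascending
    chi2: np.ndarray = field(repr=False)           # profile values on the grid
    chi2_opt: float = 0.0
    theta_opt: float = 0.0
    converged: np.ndarray = field(default=None, repr=False)
    ci_lower: float | None = None                  # None = not yet computed
    ci_upper: float | None = None
    classification: str | None = None
    threshold: float | None = None

    def rise(self) -> tuple[float, float]:
        """Max profile rise above the optimum to the left / right of theta_opt."""
        left = self.grid < self.theta_opt
        right = self.grid > self.theta_opt
        rl = float(np.max(self.chi2[left]) - self.chi2_opt) if left.any() else 0.0
        rr = float(np.max(self.chi2[right]) - self.chi2_opt) if right.any() else 0.0
        return rl, rr

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "theta_opt": self.theta_opt,
            "chi2_opt": self.chi2_opt,
            "grid": [float(g) for g in self.grid],
            "chi2": [float(c) for c in self.chi2],
            "ci": [self.ci_lower, self.ci_upper],
            "classification": self.classification,
            "threshold": self.threshold,
        }


def profile_parameter(
    objective: Callable[[np.ndarray], float],
    theta_hat: np.ndarray,
    names: Sequence[str],
    bounds: Sequence[tuple[float, float]],
    name: str,
    *,
    n_grid: int = 10,
    log_grid: bool = True,
    inner_maxfun: int = 150,
    chi2_opt: float | None = None,
) -> ProfileResult:
    """Profile one parameter of a generic objective.

    ``objective`` maps a full parameter vector to chi2.  The grid spans from
    theta_hat[i] out to each bound (log-spaced by default, ``n_grid`` points
    per direction).  Re-optimisation of the nuisance parameters uses a
    bounded quasi-Newton (L-BFGS-B) warm-started from the previous grid
    point, traversing the grid monotonically outward in each direction.
    Grid points whose inner optimisation fails are flagged, not kept
    silently.
    """
    theta_hat = np.asarray(theta_hat, dtype=float)
    names = list(names)
    i = names.index(name)
    lo, hi = bounds[i]
    center = theta_hat[i]
    if not lo <= center <= hi:
        raise ValueError(f"theta_hat[{name}] = {center} outside bounds ({lo}, {hi})")

    if log_grid:
        if lo <= 0:
            raise ValueError("log grid requires positive lower bounds")
        left = np.geomspace(center, lo, n_grid + 1)[1:]
        right = np.geomspace(center, hi, n_grid + 1)[1:]
    else:
        left = np.linspace(center, lo, n_grid + 1)[1:]
        right = np.linspace(center, hi, n_grid + 1)[1:]

    other = [j for j in range(len(names)) if j != i]
    other_bounds = [bounds[j] for j in other]

    def reopt(theta_i: float, start: np.ndarray) -> tuple[float, np.ndarray, bool]:
        if not other:
            full = theta_hat.copy()
            full[i] = theta_i
            return float(objective(full)), start, True

        def fun(x: np.ndarray) -> float:
            full = theta_hat.copy()
            full[other] = x
            full[i] = theta_i
            return float(objective(full))

        res = minimize(fun, start, method="L-BFGS-B", bounds=other_bounds,
                       options={"maxfun": inner_maxfun, "ftol": 1e-12, "gtol": 1e-10})
        ok = bool(np.isfinite(res.fun))
        return float(res.fun), np.asarray(res.x), ok

    if chi2_opt is None:
        chi2_opt = float(objective(theta_hat))

    grids, vals, flags = [center], [chi2_opt], [True]
    for direction in (left, right):
        start = theta_hat[other].copy() if other else theta_hat.copy()
        for theta_i in direction:
            v, start, ok = reopt(float(theta_i), start)
            grids.append(float(theta_i))
            vals.append(v)
            flags.append(ok)

    order = np.argsort(grids)
    return ProfileResult(
        name=name,
        grid=np.asarray(grids)[order],
        chi2=np.asarray(vals)[order],
        chi2_opt=float(chi2_opt),
        theta_opt=float(center),
        converged=np.asarray(flags)[order],
    )


def profile_confidence_interval(
    profile: ProfileResult, threshold: ThresholdSpec = ThresholdSpec()
) -> ProfileResult:
    """Attach the grid-interpolated CI defined by the chi-square threshold.

    A side is unbounded (recorded as ``-inf`` / ``+inf``) when the profile
    never crosses ``chi2_opt + Delta_alpha`` before the parameter bound.
    """
    if len(profile.grid) == 0:
        raise ValueError("empty profile")
    delta = threshold.delta
    limit = profile.chi2_opt + delta
    g, c = profile.grid, profile.chi2
    ic = int(np.argmin(np.abs(g - profile.theta_opt)))

    def crossing(idx_seq: np.ndarray) -> float | None:
        """First threshold crossing walking outward; None if none."""
        prev = ic
        for idx in idx_seq:
            if c[idx] >= limit:
                # interpolate between prev (inside) and idx (outside)
                x0, x1 = g[prev], g[idx]
                y0, y1 = c[prev], c[idx]
                if y1 == y0:
                    return float(x1)
                frac = (limit - y0) / (y1 - y0)
                return float(x0 + frac * (x1 - x0))
            prev = idx
        return None

    lower = crossing(np.arange(ic - 1, -1, -1))
    upper = crossing(np.arange(ic + 1, len(g)))
    return replace(
        profile,
        ci_lower=float("-inf") if lower is None else lower,
        ci_upper=float("inf") if upper is None else upper,
        threshold=delta,
    )


def classify_identifiability(profile: ProfileResult) -> ProfileResult:
    """Attach the identifiability class.

    Flat in both directions (rise below a small fraction of Delta_alpha)
    -> structurally non-identifiable; any unbounded CI side -> practically
    non-identifiable; both sides finite -> identifiable.
    """
    if profile.ci_lower is None or profile.ci_upper is None:
        raise ValueError("compute the confidence interval first")
    eps = FLATNESS_FRACTION * (profile.threshold or ThresholdSpec().delta)
    rl, rr = profile.rise()
    if rl < eps and rr < eps:
        cls = "structurally_nonidentifiable"
    elif math.isinf(profile.ci_lower) or math.isinf(profile.ci_upper):
        cls = "practically_nonidentifiable"
    else:
        cls = "identifiable"
    return replace(profile, classification=cls)


@dataclass(frozen=True)
class ProfileSurvey:
    """Profiles of all free parameters of one calibrated model."""

    profiles: tuple[ProfileResult, ...]
    variant: int | None = None

    def classes(self) -> dict[str, str]:
        return {p.name: p.classification for p in self.profiles}

    def n_nonidentifiable(self) -> int:
        return sum(
            1 for p in self.profiles
            if p.classification and p.classification.endswith("nonidentifiable")
        )

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "variant": self.variant,
            "n_nonidentifiable": self.n_nonidentifiable(),
            "profiles": [p.to_dict() for p in self.profiles],
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


def plot_profile(profile: ProfileResult, ax=None):
    """Profile curve with the chi-square threshold line (matplotlib axes)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    ax.plot(profile.grid, profile.chi2, "o-", ms=3, lw=1)
    if profile.threshold is not None:
        ax.axhline(profile.chi2_opt + profile.threshold, ls="--", color="k", lw=1,
                   label=f"threshold (+{profile.threshold:.3g})")
        ax.legend(fontsize=8)
    ax.axvline(profile.theta_opt, color="grey", lw=0.8)
    ax.set_xscale("log" if np.all(profile.grid > 0) else "linear")
    ax.set_xlabel(profile.name)
    ax.set_ylabel(r"$\chi^2_{PL}$")
    if profile.classification:
        ax.set_title(profile.classification.replace("_", " "), fontsize=9)
    return ax


def profile_all(
    objective: Callable[[np.ndarray], float],
    theta_hat: np.ndarray,
    names: Sequence[str],
    bounds: Sequence[tuple[float, float]],
    *,
    threshold: ThresholdSpec = ThresholdSpec(),
    variant: int | None = None,
    **kwargs,
) -> ProfileSurvey:
    """Profile every parameter and classify each."""
    chi2_opt = float(objective(np.asarray(theta_hat, dtype=float)))
    profiles = []
    for name in names:
        p = profile_parameter(objective, theta_hat, names, bounds, name,
                              chi2_opt=chi2_opt, **kwargs)
        p = classify_identifiability(profile_confidence_interval(p, threshold))
        profiles.append(p)
    return ProfileSurvey(profiles=tuple(profiles), variant=variant)
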