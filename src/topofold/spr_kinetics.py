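"""SPR multi-cycle kinetics: 1:1 association fitting and linearization.

The association phase of a surface-plasmon-resonance sensorgram under a 1:1
interaction model follows

    Γ(t) = Γ_GG − Γ_GG · e^(−k_obs · t)

where Γ(t) is the surface load (RU), Γ_GG the equilibrium load, and
k_obs = k_a·C + k_d the observed pseudo-first-order rate at analyte
concentration C. Each curve is fit in the re-parameterised form
Γ(t) = c + a·e^(−b·t) by Nelder–Mead minimisation of the reduced
chi-square χ² = Σ(Γ_fit − Γ_obs)² / (n − p) with p = 3 parameters, within
the bounds a ∈ (−700, 0), b ∈ (1e−4, 1e−1), c ∈ (0, 700). The fitted
k_obs = b values are regressed linearly on C (slope k_a, intercept k_d),
K_d = k_d / k_a, and uncertainties come from leave-one-concentration-out
refits: s = sqrt(Σ(x_i − x̄)² / (N − 1)) over the N jackknife estimates.

Only the association window is modelled; dissociation-phase points are the
caller's to discard. Double-referenced (reference-channel and
zero-concentration subtracted) responses are expected as input; a simple
subtraction helper is provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "Sensorgram",
    "AssociationFit",
    "KineticSummary",
    "BOUNDS",
    "simulate_association",
    "fit_association",
    "kobs_regression",
    "dissociation_constant",
    "jackknife_uncertainty",
    "jackknife_dispersion",
    "analyze_titration",
    "subtract_reference",
    "read_titration_csv",
    "write_titration_csv",
    "round_sig",
]

# Open-interval optimisation bounds for (a, b, c); enforced by projecting
# proposals onto the interior with a small margin.
BOUNDS = ((-700.0, 0.0), (1e-4, 1e-1), (0.0, 700.0))
_MARGIN = 1e-9
N_PARAMS = 3


@dataclass
class Sensorgram:
    """One association curve: time (s), response (RU), analyte concentration (M)."""

    time: np.ndarray
    response: np.ndarray
    concentration: float
    label: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.time.shape != self.response.shape or self.time.ndim != 1:
            raise ValueError("time and response must be 1-D arrays of equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.concentration <= 0:
            raise ValueError(f"concentration must be positive, got {self.concentration}")

    @property
    def n(self) -> int:
        return len(self.time)


@dataclass
class AssociationFit:
    a: float
    b: float
    c: float
    chi2: float
    n: int
    p: int = N_PARAMS
    converged: bool = True

    @property
    def k_obs(self) -> float:
        return self.b

    @property
    def gamma_gg(self) -> float:
        """Equilibrium surface load; equals c (and −a at a perfect fit)."""
        return self.c


@dataclass
class KineticSummary:
    k_a: float                      # M^-1 s^-1, slope
    k_d: float                      # s^-1, intercept
    K_d: float                      # M, k_d / k_a
    s_ka: float | None = None       # jackknife standard deviations
    s_kd: float | None = None
    s_Kd: float | None = None
    concentrations: tuple[float, ...] = ()
    k_obs: tuple[float, ...] = ()
    jackknife_estimates: dict = field(default_factory=dict)
    unphysical_intercept: bool = False

    def as_dict(self) -> dict:
        return {
            "k_a_per_M_per_s": self.k_a,
            "k_d_per_s": self.k_d,
            "K_d_M": self.K_d,
            "K_d_M_2sf": round_sig(self.K_d, 2),
            "s_ka": self.s_ka,
            "s_kd": self.s_kd,
            "s_Kd": self.s_Kd,
            "concentrations_M": list(self.concentrations),
            "k_obs_per_s": list(self.k_obs),
            "unphysical_intercept": self.unphysical_intercept,
        }


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0 or not np.isfinite(x):
        return x
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate_association(
    k_a: float,
    k_d: float,
    concentration: float,
    gamma_gg: float = 100.0,
    duration: float = 180.0,
    n: int = 900,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
    label: str = "",
) -> Sensorgram:
    """Simulate a 1:1 association curve Γ(t) = Γ_GG(1 − e^(−k_obs t)).

    ``noise_sd`` adds i.i.d. Gaussian noise (RU), reproducible by ``seed``.
    """
    for name, v in (("k_a", k_a), ("k_d", k_d), ("concentration", concentration),
                    ("gamma_gg", gamma_gg), ("duration", duration)):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    if n < 2:
        raise ValueError(f"need at least 2 points, got {n}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    k_obs = k_a * concentration + k_d
    t = np.linspace(0.0, duration, n)
    response = gamma_gg - gamma_gg * np.exp(-k_obs * t)
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        response = response + rng.normal(0.0, noise_sd, size=n)
    return Sensorgram(time=t, response=response, concentration=concentration, label=label)


def subtract_reference(sample: Sensorgram, reference: Sensorgram) -> Sensorgram:
    """Subtract a reference curve sharing the same time base (simple
    double-referencing step for pre-processed instrument exports)."""
    if sample.n != reference.n or not np.allclose(sample.time, reference.time):
        raise ValueError("sample and reference must share the same time base")
    return Sensorgram(
        time=sample.time,
        response=sample.response - reference.response,
        concentration=sample.concentration,
        label=sample.label,
    )


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _clamp(value: float, lo: float, hi: float) -> float:
    return min(max(value, lo + _MARGIN), hi - _MARGIN)


def _initial_simplex_start(s: Sensorgram) -> np.ndarray:
    # Scale-aware start: c0 = final response, a0 = -c0, b0 = 1 / t63 where
    # t63 is the time to reach 63% of the final response.
    final = float(s.response[-1])
    c0 = _clamp(final if final > 0 else 1.0, *BOUNDS[2])
    a0 = _clamp(-c0, *BOUNDS[0])
    above = np.nonzero(s.response >= 0.632 * final)[0] if final > 0 else []
    if len(above) and s.time[above[0]] > 0:
        b0 = 1.0 / s.time[above[0]]
    else:
        b0 = 3.0 / (s.time[-1] - s.time[0])
    b0 = _clamp(b0, *BOUNDS[1])
    return np.array([a0, b0, c0])


def fit_association(
    s: Sensorgram,
    tol: float = 1e-12,
    max_iter: int = 1_000_000,
) -> AssociationFit:
    """Fit Γ(t) = c + a·e^(−b·t) by bounded Nelder–Mead χ² minimisation.

    Non-convergence within ``max_iter`` iterations returns the best-so-far
    parameters with ``converged=False`` rather than raising.
    """
    if s.n <= N_PARAMS:
        raise ValueError(f"need more than {N_PARAMS} points, got {s.n}")
    t, y = s.time, s.response
    denom = s.n - N_PARAMS

    def chi2(params: np.ndarray) -> float:
        a = _clamp(params[0], *BOUNDS[0])
        b = _clamp(params[1], *BOUNDS[1])
        c = _clamp(params[2], *BOUNDS[2])
        resid = (c + a * np.exp(-b * t)) - y
        return float(np.dot(resid, resid) / denom)

    x0 = _initial_simplex_start(s)
    result = optimize.minimize(
        chi2,
        x0,
        method="Nelder-Mead",
        options={
            "xatol": tol,
            "fatol": tol,
            "maxiter": max_iter,
            "maxfev": max_iter,
        },
    )
    a = _clamp(result.x[0], *BOUNDS[0])
    b = _clamp(result.x[1], *BOUNDS[1])
    c = _clamp(result.x[2], *BOUNDS[2])
    return AssociationFit(
        a=a, b=b, c=c, chi2=chi2(result.x), n=s.n, converged=bool(result.success)
    )


def kobs_regression(points: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Ordinary least-squares line through (C, k_obs): returns (k_a, k_d)."""
    if len(points) < 2:
        raise ValueError("need at least 2 (C, k_obs) points")
    c = np.array([p[0] for p in points], dtype=float)
    k = np.array([p[1] for p in points], dtype=float)
    if np.allclose(c, c[0]):
        raise ValueError("all concentrations are equal; slope is undefined")
    fit = stats.linregress(c, k)
    return float(fit.slope), float(fit.intercept)


def dissociation_constant(k_a: float, k_d: float) -> float:
    """Equilibrium dissociation constant K_d = k_d / k_a."""
    if k_a <= 0:
        raise ValueError(f"k_a must be positive, got {k_a}")
    return k_d / k_a


# ---------------------------------------------------------------------------
# Titration analysis and jackknife
# ---------------------------------------------------------------------------

def _fit_all(sensorgrams: Sequence[Sensorgram]) -> list[AssociationFit]:
    return [fit_association(s) for s in sensorgrams]


def analyze_titration(sensorgrams: Sequence[Sensorgram]) -> KineticSummary:
    """Full pipeline: per-curve association fits, k_obs(C) regression, K_d,
    and leave-one-concentration-out jackknife dispersions.

    A negative regression intercept (unphysical k_d) is flagged via
    ``unphysical_intercept``, never silently clamped.
    """
    summary = jackknife_uncertainty(sensorgrams)
    return summary


def jackknife_dispersion(estimates: Sequence[float]) -> float:
    """Dispersion of leave-one-out estimates: s = sqrt(Σ(x_i − x̄)² / (N − 1))."""
    x = np.asarray(estimates, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 estimates")
    return float(np.sqrt(np.sum((x - x.mean()) ** 2) / (len(x) - 1)))


def jackknife_uncertainty(sensorgrams: Sequence[Sensorgram]) -> KineticSummary:
    """Leave-one-concentration-out dispersion of k_a, k_d and K_d.

    For each of the N concentrations the k_obs(C) line is refit without it;
    s = sqrt(Σ(x_i − x̄)² / (N − 1)) over the N estimates of each quantity.
    """
    concentrations = [s.concentration for s in sensorgrams]
    if len(set(concentrations)) < 3:
        raise ValueError(
            f"need at least 3 distinct concentrations, got {sorted(set(concentrations))}"
        )
    fits = _fit_all(sensorgrams)
    points = [(s.concentration, f.k_obs) for s, f in zip(sensorgrams, fits)]

    k_a, k_d = kobs_regression(points)
    K_d = dissociation_constant(k_a, k_d)

    loo = {"k_a": [], "k_d": [], "K_d": []}
    for i in range(len(points)):
        reduced = points[:i] + points[i + 1:]
        ka_i, kd_i = kobs_regression(reduced)
        loo["k_a"].append(ka_i)
        loo["k_d"].append(kd_i)
        loo["K_d"].append(dissociation_constant(ka_i, kd_i))

    return KineticSummary(
        k_a=k_a,
        k_d=k_d,
        K_d=K_d,
        s_ka=jackknife_dispersion(loo["k_a"]),
        s_kd=jackknife_dispersion(loo["k_d"]),
        s_Kd=jackknife_dispersion(loo["K_d"]),
        concentrations=tuple(concentrations),
        k_obs=tuple(f.k_obs for f in fits),
        jackknife_estimates=loo,
        unphysical_intercept=k_d < 0,
    )


# ---------------------------------------------------------------------------
# CSV I/O (columns: time_s, response_RU, concentration_M, curve_id)
# ---------------------------------------------------------------------------

def read_titration_csv(path: str | Path) -> list[Sensorgram]:
    df = pd.read_csv(path)
    required = {"time_s", "response_RU", "concentration_M", "curve_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for curve_id, group in df.groupby("curve_id", sort=True):
        group = group.sort_values("time_s")
        conc = group["concentration_M"].unique()
        if len(conc) != 1:
            raise ValueError(f"curve {curve_id}: multiple concentrations {conc}")
        out.append(
            Sensorgram(
                time=group["time_s"].to_numpy(),
                response=group["response_RU"].to_numpy(),
                concentration=float(conc[0]),
                label=str(curve_id),
            )
        )
    if not out:
        raise ValueError(f"{path}: no curves")
    return out


def write_titration_csv(sensorgrams: Sequence[Sensorgram], path: str | Path) -> None:
    frames = []
    for i, s in enumerate(sensorgrams):
        frames.append(
            pd.DataFrame(
                {
                    "time_s": s.time,
                    "response_RU": s.response,
                    "concentration_M": s.concentration,
                    "curve_id": s.label or f"curve_{i + 1}",
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
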