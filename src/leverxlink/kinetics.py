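"""Simulation and fitting of fluorescence-proximity binding traces.

Models the standard single-site (1:1 Langmuir) binding readout of a
surface-biosensor experiment: during association at analyte concentration
``c`` the normalized signal rises as

    y(t) = Y_eq * (1 - exp(-k_obs * t)),   k_obs = k_on * c + k_off,
    Y_eq = c / (c + K_D),                  K_D  = k_off / k_on,

and during dissociation it decays as ``y(t) = y_end * exp(-k_off * t)``.
Traces are fitted mono- or biphasically by nonlinear least squares; the
dissociation fit yields ``k_off``, the association fit yields ``k_obs`` from
which ``k_on = (k_obs - k_off) / c`` and ``K_D = k_off / k_on`` follow.
Phase-count selection uses the small-sample-corrected Akaike criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .seeding import spawn_rng

__all__ = [
    "KineticTrace",
    "KineticFitResult",
    "simulate_trace",
    "fit_dissociation",
    "fit_association",
    "select_model",
    "fit_trace_pair",
    "save_traces",
    "load_traces",
]


@dataclass(frozen=True)
class KineticTrace:
    """A normalized binding time-series for one phase of the experiment."""

    time_s: np.ndarray = field(repr=False)
    signal: np.ndarray = field(repr=False)
    phase: str  # "association" | "dissociation"
    analyte_concentration_M: float
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if self.phase not in ("association", "dissociation"):
            raise ValueError("phase must be 'association' or 'dissociation'")
        t = np.asarray(self.time_s, dtype=float)
        if t.ndim != 1 or len(t) != len(self.signal):
            raise ValueError("time and signal must be 1-D and equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time_s)


@dataclass(frozen=True)
class KineticFitResult:
    """Fitted rate constants for one trace (or a dissociation+association pair).

    ``amplitudes`` and ``rates`` are per-phase, rates sorted descending for
    biphasic fits.  ``k_on`` and ``K_D`` are only set once an association fit
    has been combined with a dissociation-derived ``k_off``; ``ok`` is False
    for non-converged or kinetically invalid fits (``k_obs <= k_off``) with
    the reason in ``message``.
    """

    n_phases: int
    amplitudes: tuple[float, ...]
    rates: tuple[float, ...]  # k_i (dissociation) or k_obs_i (association)
    rss: float
    aicc: float
    n_points: int
    k_off: float | None = None
    k_on: float | None = None
    K_D: float | None = None
    offset: float = 0.0
    ok: bool = True
    message: str = ""

    @property
    def k_obs(self) -> float:
        """Dominant-amplitude observed rate."""
        return self.rates[int(np.argmax(self.amplitudes))]


def _aicc(rss: float, n: int, k: int) -> float:
    # Gaussian log-likelihood up to constants; k counts model parameters + sigma
    k = k + 1
    if n - k - 1 <= 0:
        return np.inf
    return n * np.log(max(rss, 1e-300) / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def simulate_trace(
    k_on: float,
    k_off: float,
    c: float,
    t_assoc: float = 300.0,
    t_diss: float = 3600.0,
    n_points: int = 300,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[KineticTrace, KineticTrace]:
    """Generate an association/dissociation trace pair under the 1:1 model.

    Association runs ``n_points`` samples over ``t_assoc`` seconds (default
    5 min), dissociation over ``t_diss`` (default 60 min).  The dissociation
    trace starts from the noiseless association end level.  Gaussian noise of
    sd ``noise_sd`` (signal units; full binding saturation = 1) is added
    point-wise, seeded.
    """
    if k_on <= 0 or k_off < 0 or c <= 0:
        raise ValueError("k_on, c must be positive and k_off non-negative")
    if t_assoc <= 0 or t_diss <= 0 or n_points < 2:
        raise ValueError("durations must be positive and n_points >= 2")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    K_D = k_off / k_on
    k_obs = k_on * c + k_off
    y_eq = c / (c + K_D)
    rng = spawn_rng(seed, "trace_noise")
    t_a = np.linspace(0.0, t_assoc, n_points)
    y_a = y_eq * (1.0 - np.exp(-k_obs * t_a))
    y_end = y_a[-1]
    t_d = np.linspace(0.0, t_diss, n_points)
    y_d = y_end * np.exp(-k_off * t_d)
    if noise_sd > 0:
        y_a = y_a + rng.normal(0.0, noise_sd, n_points)
        y_d = y_d + rng.normal(0.0, noise_sd, n_points)
    assoc = KineticTrace(t_a, y_a, "association", c, noise_sd, seed)
    diss = KineticTrace(t_d, y_d, "dissociation", c, noise_sd, seed)
    return assoc, diss


def _multi_exp_decay(t, *params):
    # params: A_1, k_1, ..., A_p, k_p [, offset]
    p = len(params) // 2
    y = np.zeros_like(t)
    for i in range(p):
        y = y + params[2 * i] * np.exp(-params[2 * i + 1] * t)
    if len(params) % 2:
        y = y + params[-1]
    return y


def _multi_exp_rise(t, *params):
    p = len(params) // 2
    y = np.zeros_like(t)
    for i in range(p):
        y = y + params[2 * i] * (1.0 - np.exp(-params[2 * i + 1] * t))
    if len(params) % 2:
        y = y + params[-1]
    return y


def _initial_decay_guess(t: np.ndarray, y: np.ndarray, n_phases: int) -> list[float]:
    """Log-linearized tail-slope guess for exponential decay."""
    a0 = max(float(y[0] - y.min()), 1e-6)
    pos = y > y.max() * 1e-3
    if pos.sum() >= 3:
        slope = np.polyfit(t[pos], np.log(np.clip(y[pos], 1e-12, None)), 1)[0]
        k0 = max(-slope, 1e-9)
    else:
        k0 = 1.0 / max(t[-1], 1e-9)
    if n_phases == 1:
        return [a0, k0]
    return [a0 / 2, k0 * 10, a0 / 2, k0 / 10]


def _initial_rise_guess(t: np.ndarray, y: np.ndarray, n_phases: int) -> list[float]:
    """63%-rise-time guess for exponential association."""
    a0 = max(float(y[-1]), 1e-6)
    above = np.flatnonzero(y >= 0.63 * a0)
    t63 = float(t[above[0]]) if above.size else t[-1] / 3.0
    t63 = t63 or t[-1] / 3.0
    k0 = 1.0 / max(t63, 1e-9)
    if n_phases == 1:
        return [a0, k0]
    return [a0 / 2, k0 * 5, a0 / 2, k0 / 5]


def _fit_exponential(
    t: np.ndarray,
    y: np.ndarray,
    model,
    p0: list[float],
    with_offset: bool,
    seed: int = 0,
    n_restarts: int = 5,
) -> tuple[np.ndarray | None, float, str]:
    """Least-squares fit with jittered restarts; returns (params, rss, msg)."""
    if with_offset:
        p0 = p0 + [float(np.median(y[-max(3, len(y) // 10):]))]
    n_exp = len(p0) // 2
    lower = [0.0, 1e-12] * n_exp + ([-np.inf] if with_offset else [])
    upper = [np.inf] * len(p0)
    rng = spawn_rng(seed, "fit_restarts")
    best, best_rss = None, np.inf
    msg = ""
    for trial in range(n_restarts + 1):
        trial_p0 = (
            p0
            if trial == 0
            else [max(v * float(rng.lognormal(0, 0.5)), 1e-12) for v in p0]
        )
        trial_p0 = np.clip(trial_p0, lower, upper)
        try:
            popt, _ = curve_fit(
                model, t, y, p0=trial_p0, bounds=(lower, upper), maxfev=20000
            )
        except (RuntimeError, ValueError) as exc:  # non-convergence
            msg = str(exc)
            continue
        rss = float(np.sum((model(t, *popt) - y) ** 2))
        if rss < best_rss:
            best, best_rss = popt, rss
        break  # converged; jittered restarts are for non-convergence only
    return best, best_rss, msg


def _pack_phases(popt: np.ndarray, with_offset: bool) -> tuple[tuple, tuple, float]:
    body = popt[:-1] if with_offset else popt
    offset = float(popt[-1]) if with_offset else 0.0
    amps = tuple(float(a) for a in body[0::2])
    rates = tuple(float(k) for k in body[1::2])
    order = np.argsort(rates)[::-1]  # rates descending
    return tuple(np.array(amps)[order]), tuple(np.array(rates)[order]), offset


def fit_dissociation(
    trace: KineticTrace, n_phases: int = 1, with_offset: bool = False, seed: int = 0
) -> KineticFitResult:
    """Fit ``sum_i A_i exp(-k_i t)`` to a dissociation trace.

    For the monophasic fit ``k_off`` is the single rate; for the biphasic fit
    rates are reported descending and ``k_off`` is the dominant-amplitude
    rate.  Non-convergence returns a flagged result, never a silent NaN.
    """
    if trace.phase != "dissociation":
        raise ValueError("expected a dissociation-phase trace")
    if len(trace) < 10:
        raise ValueError("need at least 10 points to fit")
    if n_phases not in (1, 2):
        raise ValueError("n_phases must be 1 or 2")
    t = np.asarray(trace.time_s, float)
    y = np.asarray(trace.signal, float)
    n_params = 2 * n_phases + (1 if with_offset else 0)
    if np.ptp(y) < 1e-12:  # constant trace: degenerate zero-amplitude phase
        rss = float(np.sum((y - y.mean()) ** 2))
        return KineticFitResult(
            n_phases=n_phases,
            amplitudes=(0.0,) * n_phases,
            rates=(0.0,) * n_phases,
            rss=rss,
            aicc=_aicc(rss, len(y), n_params),
            n_points=len(y),
            k_off=0.0,
            offset=float(y.mean()),
            ok=True,
            message="degenerate: constant trace",
        )
    p0 = _initial_decay_guess(t, y, n_phases)
    popt, rss, msg = _fit_exponential(t, y, _multi_exp_decay, p0, with_offset, seed)
    if popt is None:
        return KineticFitResult(
            n_phases=n_phases,
            amplitudes=(),
            rates=(),
            rss=np.inf,
            aicc=np.inf,
            n_points=len(y),
            ok=False,
            message=f"fit failed to converge: {msg}",
        )
    amps, rates, offset = _pack_phases(popt, with_offset)
    k_off = rates[int(np.argmax(amps))]
    return KineticFitResult(
        n_phases=n_phases,
        amplitudes=amps,
        rates=rates,
        rss=rss,
        aicc=_aicc(rss, len(y), n_params),
        n_points=len(y),
        k_off=k_off,
        offset=offset,
    )


def fit_association(
    trace: KineticTrace,
    k_off: float,
    n_phases: int = 1,
    with_offset: bool = False,
    seed: int = 0,
) -> KineticFitResult:
    """Fit ``sum_i A_i (1 - exp(-k_obs_i t))`` and derive ``k_on`` and ``K_D``.

    ``k_off`` comes from the dissociation fit; the dominant-amplitude
    ``k_obs`` is converted via ``k_on = (k_obs - k_off) / c``.  A fit with
    ``k_obs <= k_off`` is kinetically impossible under the 1:1 model and is
    returned flagged (``ok=False``).
    """
    if trace.phase != "association":
        raise ValueError("expected an association-phase trace")
    if len(trace) < 10:
        raise ValueError("need at least 10 points to fit")
    if n_phases not in (1, 2):
        raise ValueError("n_phases must be 1 or 2")
    t = np.asarray(trace.time_s, float)
    y = np.asarray(trace.signal, float)
    n_params = 2 * n_phases + (1 if with_offset else 0)
    p0 = _initial_rise_guess(t, y, n_phases)
    popt, rss, msg = _fit_exponential(t, y, _multi_exp_rise, p0, with_offset, seed)
    if popt is None:
        return KineticFitResult(
            n_phases=n_phases,
            amplitudes=(),
            rates=(),
            rss=np.inf,
            aicc=np.inf,
            n_points=len(y),
            ok=False,
            message=f"fit failed to converge: {msg}",
        )
    amps, rates, offset = _pack_phases(popt, with_offset)
    k_obs = rates[int(np.argmax(amps))]
    c = trace.analyte_concentration_M
    common = dict(
        n_phases=n_phases,
        amplitudes=amps,
        rates=rates,
        rss=rss,
        aicc=_aicc(rss, len(y), n_params),
        n_points=len(y),
        k_off=k_off,
        offset=offset,
    )
    if k_obs <= k_off:
        return KineticFitResult(
            **common, ok=False, message="invalid kinetics: k_obs <= k_off"
        )
    k_on = (k_obs - k_off) / c
    return KineticFitResult(**common, k_on=k_on, K_D=k_off / k_on)


def select_model(
    mono: KineticFitResult, bi: KineticFitResult, delta: float = 2.0
) -> KineticFitResult:
    """Choose between mono- and biphasic fits of the same trace by AICc.

    The biphasic model is retained only when its AICc improves on the
    monophasic one by more than ``delta`` (default 2); ties and anything less
    go to the parsimonious monophasic fit.  A failed fit always loses.
    """
    if not bi.ok:
        return mono
    if not mono.ok:
        return bi
    return bi if (mono.aicc - bi.aicc) > delta else mono


def fit_trace_pair(
    assoc: KineticTrace,
    diss: KineticTrace,
    phases: str = "auto",
    with_offset: bool = False,
    seed: int = 0,
) -> KineticFitResult:
    """Full pipeline: fit dissociation, then association, deriving k_on/K_D.

    ``phases`` is ``"auto"`` (AICc selection per trace), ``"1"`` or ``"2"``.
    """
    if phases == "auto":
        d = select_model(
            fit_dissociation(diss, 1, with_offset, seed),
            fit_dissociation(diss, 2, with_offset, seed),
        )
    else:
        d = fit_dissociation(diss, int(phases), with_offset, seed)
    if not d.ok or d.k_off is None:
        return d
    if phases == "auto":
        a = select_model(
            fit_association(assoc, d.k_off, 1, with_offset, seed),
            fit_association(assoc, d.k_off, 2, with_offset, seed),
        )
    else:
        a = fit_association(assoc, d.k_off, int(phases), with_offset, seed)
    return a


def save_traces(traces: list[KineticTrace], path: str | Path) -> Path:
    """Write traces in the ``time_s,signal,phase,concentration_M`` dialect."""
    path = Path(path)
    frames = [
        pd.DataFrame(
            {
                "time_s": tr.time_s,
                "signal": tr.signal,
                "phase": tr.phase,
                "concentration_M": tr.analyte_concentration_M,
            }
        )
        for tr in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def load_traces(path: str | Path) -> list[KineticTrace]:
    """Read a trace CSV, returning one KineticTrace per (phase, concentration)."""
    df = pd.read_csv(path)
    required = {"time_s", "signal", "phase", "concentration_M"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV missing columns: {sorted(missing)}")
    out = []
    for (phase, conc), grp in df.groupby(["phase", "concentration_M"], sort=False):
        grp = grp.sort_values("time_s")
        out.append(
            KineticTrace(
                grp["time_s"].to_numpy(float),
                grp["signal"].to_numpy(float),
                str(phase),
                float(conc),
            )
        )
    return out
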