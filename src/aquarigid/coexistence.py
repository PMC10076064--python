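"""NVE three-phase coexistence estimate of the ice melting temperature.

A liquid-ice-liquid slab (with a vacuum gap accommodating the density
change of the phase transition) is run in the microcanonical ensemble
from two bracketing initial temperatures T_L < T_M < T_H.  Above T_M ice
melts and the slab cools; below T_M ice grows and the latent heat warms
the slab — both trajectories relax toward the coexistence temperature
without any thermostat or barostat.  Equilibrium is declared when the
trailing rolling averages of the two temperature traces agree within a
tolerance (0.1 K over a 1 ns window at full scale) and stay within it to
the end of the traces; the temperature is then averaged over a fixed
span and pooled over proton-disorder replicas, with the standard error
of the mean over replicas as the uncertainty.

A pair whose traces never agree signals loss of coexistence (complete
melt or freeze); such replicas are excluded and reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .engine import RunConfig, initialize_velocities, run
from .errors import ConfigError, InsufficientDataError

__all__ = ["CoexistenceResult", "rolling_average", "detect_equilibrium",
           "estimate_tm", "run_coexistence"]


@dataclass
class CoexistenceResult:
    """Pooled melting-temperature estimate over proton-disorder replicas."""

    t_m: float                        # K, pooled mean
    sem: float                        # K, standard error of the mean
    per_pair: List[float]             # per-replica equilibrium temperatures
    onsets: List[Optional[float]]     # equilibrium onset time per pair (fs)
    verdicts: List[str]               # "converged" | "not-converged"
    n_replicas_used: int
    window: float
    avg_span: float
    tol: float
    series: list = field(default_factory=list)  # optional raw (t, T) pairs
    drift_audit: list = field(default_factory=list)  # NVE relative drifts

    def __post_init__(self):
        used = [t for t, v in zip(self.per_pair, self.verdicts)
                if v == "converged"]
        if used and not (min(used) - 1e-9 <= self.t_m <= max(used) + 1e-9):
            raise ValueError("pooled T_M outside the per-pair range")


def rolling_average(times: np.ndarray, values: np.ndarray,
                    window: float) -> Tuple[np.ndarray, np.ndarray]:
    """Causal trailing-window mean of a uniformly sampled series.

    Emits one point per input sample once a full window of history is
    available; a constant series maps to itself.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(times) < 2:
        raise InsufficientDataError("need at least two samples")
    dt = float(np.median(np.diff(times)))
    span = times[-1] - times[0]
    if window > span + 0.5 * dt:
        raise InsufficientDataError(
            f"window {window} exceeds the series span {span}")
    n_win = max(1, int(round(window / dt)))
    csum = np.concatenate([[0.0], np.cumsum(values)])
    out = (csum[n_win:] - csum[:-n_win]) / n_win
    return times[n_win - 1:], out


def detect_equilibrium(series_low, series_high, window: float,
                       tol: float = 0.1) -> Optional[float]:
    """Earliest time after which the two rolling averages stay within tol.

    ``series_low``/``series_high`` are (times, temperatures) pairs from
    the runs started at T_L and T_H.  Returns the onset time, or None
    when the traces never agree to the end (possible complete melt or
    freeze).  The criterion requires agreement *sustained to the end of
    the series*, not a first touch, so single crossings of two traces
    relaxing to different plateaus do not count.
    """
    t_lo, r_lo = rolling_average(*series_low, window)
    t_hi, r_hi = rolling_average(*series_high, window)
    # align on the common grid (both series share cadence by construction;
    # interpolate defensively otherwise)
    t0 = max(t_lo[0], t_hi[0])
    t1 = min(t_lo[-1], t_hi[-1])
    if t1 <= t0:
        raise InsufficientDataError("rolling series do not overlap")
    grid = t_lo[(t_lo >= t0) & (t_lo <= t1)]
    d = np.abs(np.interp(grid, t_lo, r_lo) - np.interp(grid, t_hi, r_hi))
    ok = d <= tol
    if not ok[-1]:
        return None
    # last index where the criterion fails; onset is the next sample
    bad = np.where(~ok)[0]
    onset_idx = int(bad[-1]) + 1 if len(bad) else 0
    return float(grid[onset_idx])


def estimate_tm(pairs: Sequence[Tuple], window: float, avg_span: float,
                tol: float = 0.1) -> CoexistenceResult:
    """Pool the equilibrium temperature over replica pairs.

    Each element of ``pairs`` is ((times_lo, T_lo), (times_hi, T_hi)).
    Per converged pair, both traces are averaged over
    [onset, onset + avg_span] and the two run means averaged; the pooled
    T_M is the mean over replicas with its standard error.  Pairs that
    never converge are excluded and recorded in the verdicts.
    """
    per_pair, onsets, verdicts = [], [], []
    for lo, hi in pairs:
        onset = detect_equilibrium(lo, hi, window, tol)
        onsets.append(onset)
        if onset is None:
            verdicts.append("not-converged")
            per_pair.append(float("nan"))
            continue
        verdicts.append("converged")
        means = []
        for t, v in (lo, hi):
            t = np.asarray(t, dtype=float)
            v = np.asarray(v, dtype=float)
            sel = (t >= onset) & (t <= onset + avg_span)
            if not sel.any():
                raise InsufficientDataError(
                    "no samples in the averaging span after onset")
            means.append(float(v[sel].mean()))
        per_pair.append(0.5 * (means[0] + means[1]))

    used = np.array([x for x in per_pair if np.isfinite(x)])
    if len(used) == 0:
        raise InsufficientDataError(
            "no replica pair reached equilibrium; the slabs may have "
            "fully melted or frozen")
    t_m = float(used.mean())
    sem = float(used.std(ddof=1) / np.sqrt(len(used))) if len(used) > 1 else 0.0
    return CoexistenceResult(t_m=t_m, sem=sem, per_pair=per_pair,
                             onsets=onsets, verdicts=verdicts,
                             n_replicas_used=len(used), window=window,
                             avg_span=avg_span, tol=tol)


def run_coexistence(slabs: Sequence, t_low: float, t_high: float,
                    config: RunConfig, n_steps: int, window: float,
                    avg_span: float, tol: float = 0.1,
                    seed: int = 0) -> CoexistenceResult:
    """Launch paired NVE runs from each slab and pool the results.

    ``slabs`` is a sequence of :class:`~aquarigid.builders.LILSlab`
    (one per proton-disorder replica).  Each slab is run twice with
    initial velocities drawn at ``t_low`` and ``t_high``; a 0.5 fs
    timestep is enforced for the NVE legs regardless of model rigidity.
    Per-run energy-drift audits are collected in the result series
    metadata.
    """
    if config.ensemble != "NVE":
        raise ConfigError("the coexistence method is strictly microcanonical")
    cfg = RunConfig(**{**config.__dict__, "timestep": 0.5,
                       "tail_correction": False})
    pairs = []
    raw = []
    drifts = []
    for rep, slab in enumerate(slabs):
        pair = []
        for leg, T0 in enumerate((t_low, t_high)):
            st = slab.state.copy()
            leg_seed = seed + 1000 * rep + leg
            initialize_velocities(st, slab.topology, T0, seed=leg_seed)
            leg_cfg = RunConfig(**{**cfg.__dict__, "seed": leg_seed})
            traj = run(st, slab.topology, leg_cfg, n_steps)
            times, temps = traj.temperature_series()
            pair.append((times, temps))
            drifts.append(traj.meta.get("drift_relative", 0.0))
        pairs.append(tuple(pair))
        raw.append(pair)
    result = estimate_tm(pairs, window, avg_span, tol)
    result.series = raw
    result.drift_audit = drifts
    return result
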