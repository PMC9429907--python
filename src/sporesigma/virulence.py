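"""Phage virulence index from microplate growth curves.

A dilution series of phage is applied to host cultures across
multiplicities of infection (MOI), and optical density (OD600) is followed
over time.  For each MOI, local virulence is the fractional reduction of
integrated growth relative to the uninfected (MOI = 0) control,

    v(moi) = 1 - A_infected / A_control,

where A is the trapezoidal area under OD(t) on [0, t_end] (default 6 h,
the window from infection to the control's entry into stationary phase).
The virulence index Vp integrates v over the log10-MOI span, normalized by
the maximal theoretical area (v = 1 throughout), giving a scalar in [0, 1]:
Vp = 0 means the phage never suppresses growth, Vp = 1 means instant,
complete lysis at every MOI tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import WelchResult, welch_t_test  # noqa: F401  (re-exported)

__all__ = [
    "VirulenceResult",
    "integrate_od",
    "local_virulence",
    "virulence_index",
    "welch_t_test",
    "WelchResult",
]

PLATE_COLUMNS = ["well", "strain", "moi", "replicate", "time_h", "od600"]


@dataclass(frozen=True)
class VirulenceResult:
    """Virulence index with per-MOI local virulence.

    ``per_moi_local_virulence`` averages replicates per MOI on the local-
    virulence scale; ``per_replicate_vp`` gives one Vp per replicate
    dilution series, the unit used for between-strain Welch comparisons.
    """

    per_moi_local_virulence: dict[float, float]
    vp: float
    t_end: float
    per_replicate_vp: dict[str, float] = field(default_factory=dict)


def integrate_od(time_h: Sequence[float], od600: Sequence[float], t_end: float) -> float:
    """Trapezoidal area (OD x hours) under a growth curve on [0, t_end].

    The boundary value at t_end is linearly interpolated when not sampled.
    """
    t = np.asarray(time_h, dtype=float)
    od = np.asarray(od600, dtype=float)
    if t.size != od.size:
        raise ValueError("time and OD vectors must have equal length")
    if t.size < 2:
        raise ValueError("need >= 2 time points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time points must be strictly increasing")
    if np.any(od < 0):
        raise ValueError("OD values must be non-negative")
    if t_end > t[-1] + 1e-12:
        raise ValueError(f"t_end={t_end} beyond last sampled time {t[-1]}")
    keep = t <= t_end + 1e-12
    if keep.sum() < 2:
        raise ValueError("fewer than 2 usable points at or before t_end")
    tt = t[keep]
    oo = od[keep]
    if tt[-1] < t_end - 1e-12:
        tt = np.append(tt, t_end)
        oo = np.append(oo, np.interp(t_end, t, od))
    return float(np.trapezoid(oo, tt))


def local_virulence(area_infected: float, area_control: float) -> float:
    """1 - infected/control integrated growth, clamped to [0, 1]."""
    if area_control <= 0:
        raise ValueError("control area must be positive")
    return float(min(1.0, max(0.0, 1.0 - area_infected / area_control)))


def virulence_index(curves: pd.DataFrame, t_end: float = 6.0) -> VirulenceResult:
    """Virulence index Vp for one strain's plate of growth curves.

    ``curves`` is long-format with columns well, moi, replicate, time_h,
    od600 (a strain column is tolerated but a single strain is expected).
    Each replicate must carry its own MOI = 0 control well, which
    normalises that replicate's infected wells.  Vp is the trapezoidal area
    of replicate-averaged local virulence over log10(MOI), divided by the
    span (the theoretical maximum with v = 1 everywhere).
    """
    df = curves.copy()
    needed = {"moi", "replicate", "time_h", "od600"}
    if not needed <= set(df.columns):
        raise ValueError(f"plate table needs columns {sorted(needed)}")
    if "well" not in df.columns:
        df["well"] = df["replicate"].astype(str) + "@" + df["moi"].astype(str)
    if "strain" in df.columns and df["strain"].nunique() > 1:
        raise ValueError("virulence_index expects a single strain; group beforehand")

    areas: dict[tuple[str, float], float] = {}
    for (rep, moi), grp in df.groupby(["replicate", "moi"], sort=False):
        grp = grp.sort_values("time_h")
        areas[(str(rep), float(moi))] = integrate_od(grp["time_h"], grp["od600"], t_end)

    mois = sorted({m for _, m in areas})
    nonzero = [m for m in mois if m > 0]
    if 0.0 not in mois:
        raise ValueError("missing MOI=0 uninfected control wells")
    if len(nonzero) < 2:
        raise ValueError("need >= 2 distinct nonzero MOI levels to span the index")

    reps = sorted({r for r, _ in areas})
    per_rep_v: dict[str, dict[float, float]] = {}
    for rep in reps:
        if (rep, 0.0) not in areas:
            raise ValueError(f"replicate {rep!r} lacks an MOI=0 control well")
        control = areas[(rep, 0.0)]
        per_rep_v[rep] = {
            m: local_virulence(areas[(rep, m)], control)
            for m in nonzero
            if (rep, m) in areas
        }

    log_moi = np.log10(nonzero)
    span = log_moi[-1] - log_moi[0]

    def _vp(v_by_moi: Mapping[float, float]) -> float:
        v = np.array([v_by_moi[m] for m in nonzero])
        return float(np.trapezoid(v, log_moi) / span)

    per_replicate_vp = {
        rep: _vp(v) for rep, v in per_rep_v.items() if set(v) == set(nonzero)
    }
    mean_v = {
        m: float(np.mean([v[m] for v in per_rep_v.values() if m in v])) for m in nonzero
    }
    return VirulenceResult(
        per_moi_local_virulence=mean_v,
        vp=_vp(mean_v),
        t_end=t_end,
        per_replicate_vp=per_replicate_vp,
    )
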