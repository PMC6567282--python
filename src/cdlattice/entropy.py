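"""Vibration amplitudes and the independent-oscillator entropy decomposition.

Bodies in a stable superlattice vibrate about fixed sites: the translational
mean-squared displacement <r^2(t)> and the rotational <theta^2(t)> (angle
between a body's center-to-vertex vector at two times) saturate at plateaus.
The saturated amplitudes <u^2> and <phi^2> define effective oscillator
stiffnesses ktrans = 3 kB T / <u^2> and krot = 3 kB T / <phi^2>, and the
relative entropy between systems follows from amplitude ratios:

    dS_trans = 3/2 kB [ ln(<u^2>/<u^2>_ref)_NP + ln(...)_cage ]
    dS_rot   = 3/2 kB [ ln(<phi^2>/<phi^2>_ref)_NP + ln(...)_cage ]

Conventions: <u^2> is site-referenced (variance about the mean position; the
time-lag plateau is twice that and is halved when read off the curve).
<phi^2> is the variance of the body rotation-vector magnitude; the per-vertex
time-lag angle plateau is 4/3 of it for isotropic small rotations and is
rescaled accordingly.  The T d<u^2>/dT term of the entropy derivation drops
for amplitudes linear in T; ``temperature_linearity`` exposes the check.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import BODY_CAGE, BODY_NP, BodyTrajectory, logger

__all__ = [
    "MsdCurves", "EntropyReport", "msd_translational", "msd_rotational",
    "entropy_decomposition", "energy_component", "temperature_linearity",
]

#: <theta^2>_lag-plateau = (4/3) <phi^2> for isotropic small rotations
VERTEX_LAG_TO_PHI2 = 0.75
#: <r^2>_lag-plateau = 2 <u^2> for site-referenced amplitudes
LAG_TO_U2 = 0.5


@dataclass
class MsdCurves:
    t: np.ndarray
    curve: np.ndarray               # time-lag MSD (r^2 or theta^2)
    plateau: float | None           # converted plateau (<u^2> or <phi^2>)
    plateau_raw: float | None       # plateau of the lag curve itself
    plateau_window: tuple | None
    species: int | None
    kind: str = "translational"
    direct: float | None = None     # direct variance estimate (site-referenced)


def _lags(n_frames: int, n_lags: int = 60) -> np.ndarray:
    lags = np.unique(np.round(np.logspace(0, math.log10(n_frames - 1),
                                          n_lags)).astype(int))
    return lags[lags >= 1]


def _plateau(t: np.ndarray, curve: np.ndarray, slope_tol: float = 0.05,
             window=None) -> tuple[float | None, tuple | None]:
    """Average of the saturated tail: the last half of the curve in log time
    where the local log-log slope stays below ``slope_tol``."""
    if window is not None:
        sel = (t >= window[0]) & (t <= window[1])
        return float(curve[sel].mean()), tuple(window)
    if len(t) < 6 or np.any(curve <= 0):
        return None, None
    half = len(t) // 2
    lt, lc = np.log(t[half:]), np.log(curve[half:])
    slope = np.polyfit(lt, lc, 1)[0]
    if slope > slope_tol:
        logger.warning("no MSD plateau: tail log-log slope %.3f "
                       "(drift or diffusion?)", slope)
        return None, None
    return float(curve[half:].mean()), (float(t[half]), float(t[-1]))


def msd_translational(traj: BodyTrajectory, species: int | None = None,
                      n_origins: int = 64, window=None) -> MsdCurves:
    """Multi-origin translational MSD of body centers and its plateau.

    Returns the time-lag curve; ``plateau`` is the site-referenced <u^2>
    (half the lag plateau), and ``direct`` the straight variance of centers
    about their mean positions (the two agree for stationary trajectories).
    """
    sel = np.ones(traj.n_bodies, bool) if species is None \
        else traj.species == species
    pos = traj.centers[:, sel, :]
    f = len(pos)
    if f < 3:
        raise ValueError("need >= 3 frames for an MSD")
    t = traj.times if traj.times is not None else np.arange(f, dtype=float)
    lags = _lags(f)
    stride = max(1, (f - int(lags[-1])) // n_origins) if f > lags[-1] else 1
    curve = np.empty(len(lags))
    for i, lag in enumerate(lags):
        origins = np.arange(0, f - lag, stride)
        if len(origins) < 1:
            origins = np.array([0])
        diff = pos[origins + lag] - pos[origins]
        curve[i] = np.mean(np.sum(diff * diff, axis=-1))
    plateau_raw, win = _plateau(t[lags] - t[0], curve, window=window)
    direct = float(np.mean(np.sum(
        (pos - pos.mean(axis=0, keepdims=True)) ** 2, axis=-1)))
    plateau = LAG_TO_U2 * plateau_raw if plateau_raw is not None else None
    return MsdCurves(t=t[lags] - t[0], curve=curve, plateau=plateau,
                     plateau_raw=plateau_raw, plateau_window=win,
                     species=species, kind="translational", direct=direct)


def msd_rotational(traj: BodyTrajectory, species: int | None = None,
                   n_origins: int = 64, window=None) -> MsdCurves:
    """Per-vertex rotational MSD <theta^2(t)> and the body <phi^2> plateau.

    theta(t) is the angle between the center-to-vertex probe vector at t0
    and t0+t, averaged over probes, origins and bodies; the reported
    <phi^2> rescales the lag plateau by 3/4 (small-rotation geometry).
    """
    if traj.orientations is None:
        raise ValueError("trajectory carries no orientation probes")
    sel = np.ones(traj.n_bodies, bool) if species is None \
        else traj.species == species
    ori = traj.orientations[:, sel, :, :]
    f = len(ori)
    t = traj.times if traj.times is not None else np.arange(f, dtype=float)
    lags = _lags(f)
    stride = max(1, (f - int(lags[-1])) // n_origins) if f > lags[-1] else 1
    curve = np.empty(len(lags))
    for i, lag in enumerate(lags):
        origins = np.arange(0, f - lag, stride)
        if len(origins) < 1:
            origins = np.array([0])
        dots = np.sum(ori[origins + lag] * ori[origins], axis=-1)
        theta = np.arccos(np.clip(dots, -1.0, 1.0))
        curve[i] = np.mean(theta ** 2)
    plateau_raw, win = _plateau(t[lags] - t[0], curve, window=window)
    # direct estimate: angle to the mean orientation, <theta^2> = 2/3 <phi^2>
    mean_ori = ori.mean(axis=0, keepdims=True)
    mean_ori = mean_ori / np.linalg.norm(mean_ori, axis=-1, keepdims=True)
    th0 = np.arccos(np.clip(np.sum(ori * mean_ori, axis=-1), -1.0, 1.0))
    direct = float(1.5 * np.mean(th0 ** 2))
    plateau = (VERTEX_LAG_TO_PHI2 * plateau_raw
               if plateau_raw is not None else None)
    return MsdCurves(t=t[lags] - t[0], curve=curve, plateau=plateau,
                     plateau_raw=plateau_raw, plateau_window=win,
                     species=species, kind="rotational", direct=direct)


# ---------------------------------------------------------------------------
# Entropy decomposition
# ---------------------------------------------------------------------------
@dataclass
class EntropyReport:
    table: pd.DataFrame
    reference: tuple
    shifted: pd.DataFrame | None = None     # per-stiffness re-referenced view

    def row(self, key) -> pd.Series:
        return self.table.loc[self.table["system"].apply(lambda k: k == key)] \
            .iloc[0]


def _ln_ratio(x, ref):
    if x is None or ref is None or x <= 0 or ref <= 0:
        raise ValueError("plateaus must be positive for the entropy ratios")
    return math.log(x / ref)


def entropy_decomposition(plateaus: dict, reference, T: float = 0.09,
                          kB: float = 1.0,
                          shifted_view: bool = True) -> EntropyReport:
    """Independent-oscillator entropy decomposition relative to a reference.

    ``plateaus`` maps a system key (conventionally a (d, ka) tuple) to a dict
    with entries ``u2`` (pooled, or ``u2_np``/``u2_cage``), ``phi2_np``,
    ``phi2_cage`` and optionally ``energy`` (mean potential energy per
    primitive cell).  dS is in units of kB; dF = dE - T dS.
    """
    if reference not in plateaus:
        raise ValueError(f"reference system {reference} missing")

    def u2pair(rec):
        if "u2" in rec:
            return rec["u2"], rec["u2"]
        return rec["u2_np"], rec["u2_cage"]

    ref = plateaus[reference]
    ru_np, ru_cage = u2pair(ref)
    rows = []
    for key, rec in plateaus.items():
        u_np, u_cage = u2pair(rec)
        ds_t = 1.5 * kB * (_ln_ratio(u_np, ru_np) + _ln_ratio(u_cage, ru_cage))
        ds_r_np = 1.5 * kB * _ln_ratio(rec["phi2_np"], ref["phi2_np"])
        ds_r_cage = 1.5 * kB * _ln_ratio(rec["phi2_cage"], ref["phi2_cage"])
        ds_r = ds_r_np + ds_r_cage
        de = (rec.get("energy", 0.0) - ref.get("energy", 0.0))
        rows.append(dict(system=key, dS_trans=ds_t, dS_rot=ds_r,
                         dS_rot_np=ds_r_np, dS_rot_cage=ds_r_cage,
                         minus_TdS_trans=-T * ds_t, minus_TdS_rot=-T * ds_r,
                         dE=de, dF=de - T * (ds_t + ds_r)))
    table = pd.DataFrame(rows)

    shifted = None
    keys = list(plateaus)
    if shifted_view and all(isinstance(k, tuple) and len(k) == 2
                            for k in keys):
        # re-reference each stiffness to its own smallest-NP system
        srows = []
        for ka in sorted({k[1] for k in keys}):
            group = sorted([k for k in keys if k[1] == ka])
            base = min(group)
            sub = entropy_decomposition(
                {k: plateaus[k] for k in group}, base, T=T, kB=kB,
                shifted_view=False)
            for _, r in sub.table.iterrows():
                r = dict(r)
                r["ka"] = ka
                srows.append(r)
        shifted = pd.DataFrame(srows)
    return EntropyReport(table=table, reference=reference, shifted=shifted)


def energy_component(traj: BodyTrajectory, ref: BodyTrajectory) -> float:
    """dE: difference of mean potential energy per primitive cell."""
    for t in (traj, ref):
        if t.energies is None:
            raise ValueError("trajectory carries no energy series")
    cells = traj.n_bodies // 2
    cells_ref = ref.n_bodies // 2
    return float(np.mean(traj.energies) / cells
                 - np.mean(ref.energies) / cells_ref)


def temperature_linearity(u2_by_T: dict) -> float:
    """Logarithmic temperature derivative T d<u^2>/dT / <u^2> from plateaus
    at two (or more) temperatures: 1 for harmonic (linear-in-T) vibrations."""
    items = sorted(u2_by_T.items())
    if len(items) < 2:
        raise ValueError("need plateaus at two temperatures")
    (t1, u1), (t2, u2) = items[0], items[-1]
    return math.log(u2 / u1) / math.log(t2 / t1)
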