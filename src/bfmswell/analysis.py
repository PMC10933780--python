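"""Quantitative post-processing of swelling trajectories.

Covers the full analysis layer of the model:

* per-species 1D vertical density profiles (site coverage per bin),
* moving hydration fronts — penetration (PF), swelling (SF) and erosion (EF)
  — extracted from the profiles by configurable thresholds,
* chain relaxation observables: the normalized end-to-end orientational
  correlation C_EE(t) = <R_EE(t).R_EE(0)> / <R_EE(0).R_EE(0)> and the
  centre-of-mass translational correlation dRcm2(t) = <|Rcm(t) - Rcm(0)|^2>,
  both ensemble-averaged over solvent-activated chains,
* empirical fits C_EE(t) = exp(-t/tau) and dRcm2(t) = alpha * t^beta
  (beta > 1 superdiffusive, beta < 1 subdiffusive),
* first-order swelling kinetics S(t) = S_eq * (1 - exp(-k t)) for
  macroscopic swelling-content series (experimental or simulated proxy),
* the Flory-Huggins polymer-solvent parameter
  chi12 = z * (w12 - (w11 + w22)/2) / kBT with lattice coordination z = 24,
  which for this model's energies reduces to chi12 = 24*eps0*(1 - 1.5*H).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .bfm_core import CHAIN, DRUG, SOLVENT

__all__ = [
    "DensityProfiles",
    "FrontThresholds",
    "FrontTrace",
    "CorrResult",
    "SwellingSeries",
    "SwellingFit",
    "density_profiles",
    "default_front_thresholds",
    "detect_fronts",
    "orientational_correlation",
    "translational_correlation",
    "correlation_analysis",
    "fit_exponential",
    "fit_powerlaw",
    "swelling_kinetics_fit",
    "swelling_content",
    "flory_huggins_chi",
    "flory_huggins_chi_general",
    "summarize_run",
]

#: lattice coordination number of the contact shell
COORDINATION_NUMBER = 24


# ---------------------------------------------------------------------------
# Density profiles
# ---------------------------------------------------------------------------


@dataclass
class DensityProfiles:
    """Per-species vertical density profiles.

    ``rho[species]`` has shape (n_snapshots, n_bins); values are fractional
    site coverage (covered sites / bin area), so summing rho * bin_width * W
    over bins recovers 4 sites per monomer of that species.
    """

    times: np.ndarray
    bin_edges: np.ndarray
    bin_width: int
    box_width: int
    rho: dict

    @property
    def bin_centers(self):
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def density_profiles(trajectory, bin_width=1):
    """Vertical (y) site-coverage density per species, per snapshot."""
    if int(bin_width) < 1:
        raise ValueError("bin width must be >= 1 lattice unit")
    if trajectory.n_snapshots == 0:
        raise ValueError("trajectory is empty")
    bin_width = int(bin_width)
    width, height = trajectory.meta["W"], trajectory.meta["hy"]
    n_bins = int(np.ceil(height / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    rho = {
        s: np.zeros((trajectory.n_snapshots, n_bins)) for s in (CHAIN, DRUG, SOLVENT)
    }
    area = bin_width * width
    for k in range(trajectory.n_snapshots):
        ys = trajectory.pos[k, :, 1].astype(np.int64)
        for s in (CHAIN, DRUG, SOLVENT):
            mask = trajectory.species == s
            if not mask.any():
                continue
            # a plaquette covers rows y and y+1, two sites per row
            rows = np.concatenate([ys[mask], ys[mask] + 1])
            counts = np.bincount(rows // bin_width, minlength=n_bins) * 2
            rho[s][k] = counts[:n_bins] / area
    return DensityProfiles(
        times=trajectory.stamps.copy(),
        bin_edges=edges,
        bin_width=bin_width,
        box_width=width,
        rho=rho,
    )


# ---------------------------------------------------------------------------
# Front detection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FrontThresholds:
    """Absolute density thresholds for the three fronts.

    theta_pf: solvent density marking the deepest solvent reach (PF);
    theta_sf: chain density below which the matrix is rubbery (SF);
    theta_ef: chain density above which polymer is still present (EF).
    """

    theta_pf: float
    theta_sf: float
    theta_ef: float


def default_front_thresholds(profiles, pf_frac=0.05, sf_frac=0.5, ef_frac=0.05):
    """Thresholds derived from the t = 0 profiles: PF at ``pf_frac`` of the
    mean free-solvent density, SF at ``sf_frac`` and EF at ``ef_frac`` of the
    initial bulk chain density."""
    rho_c0 = profiles.rho[CHAIN][0]
    rho_s0 = profiles.rho[SOLVENT][0]
    if rho_c0.max() <= 0:
        raise ValueError("no chain density at t=0; cannot derive thresholds")
    bulk_c = rho_c0[rho_c0 > 0.5 * rho_c0.max()].mean()
    free_s = rho_s0[rho_s0 > 0].mean() if (rho_s0 > 0).any() else 0.0
    return FrontThresholds(
        theta_pf=pf_frac * free_s,
        theta_sf=sf_frac * bulk_c,
        theta_ef=ef_frac * bulk_c,
    )


@dataclass
class FrontTrace:
    """Vertical front positions over time (NaN where undefined).
    Ordering PF <= SF <= EF holds on monotone hydration profiles."""

    times: np.ndarray
    pf: np.ndarray
    sf: np.ndarray
    ef: np.ndarray
    thresholds: FrontThresholds


def _cross_up(y, values, threshold):
    """Lowest y where ``values`` first reaches >= threshold (scan bottom-up),
    linearly interpolated between bin centers; NaN if never."""
    above = values >= threshold
    if not above.any():
        return math.nan
    i = int(np.argmax(above))
    if i == 0:
        return float(y[0])
    v0, v1 = values[i - 1], values[i]
    if v1 == v0:
        return float(y[i])
    return float(y[i - 1] + (threshold - v0) / (v1 - v0) * (y[i] - y[i - 1]))


def _cross_down(y, values, threshold):
    """Lowest y where ``values`` first falls < threshold (scan bottom-up)."""
    below = values < threshold
    if not below.any():
        return math.nan
    i = int(np.argmax(below))
    if i == 0:
        return float(y[0])
    v0, v1 = values[i - 1], values[i]
    if v1 == v0:
        return float(y[i])
    return float(y[i - 1] + (threshold - v0) / (v1 - v0) * (y[i] - y[i - 1]))


def _highest_above(y, values, threshold):
    """Highest y where ``values`` still exceeds >= threshold (scan top-down)."""
    above = values >= threshold
    if not above.any():
        return math.nan
    i = len(values) - 1 - int(np.argmax(above[::-1]))
    if i == len(values) - 1:
        return float(y[-1])
    v0, v1 = values[i], values[i + 1]
    if v1 == v0:
        return float(y[i])
    return float(y[i] + (threshold - v0) / (v1 - v0) * (y[i + 1] - y[i]))


def detect_fronts(profiles, thresholds=None):
    """Extract PF/SF/EF positions from density profiles, per snapshot.

    PF — lowest y where solvent density exceeds theta_pf (deepest solvent
    reach); SF — lowest y where chain density falls below theta_sf (glassy to
    rubbery divide); EF — highest y where chain density still exceeds
    theta_ef (outermost polymer).  All-zero profiles yield NaN fronts.
    """
    if thresholds is None:
        thresholds = default_front_thresholds(profiles)
    y = profiles.bin_centers
    n = profiles.times.size
    pf = np.full(n, math.nan)
    sf = np.full(n, math.nan)
    ef = np.full(n, math.nan)
    for k in range(n):
        rho_s = profiles.rho[SOLVENT][k]
        rho_c = profiles.rho[CHAIN][k]
        if rho_s.any():
            pf[k] = _cross_up(y, rho_s, thresholds.theta_pf)
        if rho_c.any():
            sf[k] = _cross_down(y, rho_c, thresholds.theta_sf)
            ef[k] = _highest_above(y, rho_c, thresholds.theta_ef)
    return FrontTrace(times=profiles.times.copy(), pf=pf, sf=sf, ef=ef, thresholds=thresholds)


# ---------------------------------------------------------------------------
# Chain correlation functions
# ---------------------------------------------------------------------------


def _activated_chain_ids(trajectory):
    """Chains activated at any point during the run (ensemble for averages)."""
    if trajectory.n_chains == 0:
        return np.empty(0, dtype=np.int64)
    return np.flatnonzero(trajectory.chain_active[-1])


def orientational_correlation(trajectory):
    """Normalized end-to-end orientational correlation over activated chains.

    Returns (times, C_EE).  C_EE(0) = 1 exactly; empty arrays when no chain
    was ever activated.
    """
    if trajectory.chain_length < 2:
        raise ValueError("orientational correlation needs chains of >= 2 monomers")
    act = _activated_chain_ids(trajectory)
    if act.size == 0:
        return trajectory.stamps[:0].copy(), np.empty(0)
    n_snap = trajectory.n_snapshots
    ree = np.zeros((n_snap, act.size, 2))
    for k in range(n_snap):
        chains = trajectory.chain_positions(k)[act]
        ree[k] = chains[:, -1] - chains[:, 0]
    denom = np.mean(np.sum(ree[0] * ree[0], axis=1))
    cee = np.mean(np.sum(ree * ree[0], axis=2), axis=1) / denom
    return trajectory.stamps.copy(), cee


def translational_correlation(trajectory):
    """Mean squared centre-of-mass displacement over activated chains.

    Returns (times, dRcm2); dRcm2(0) = 0 exactly.
    """
    if trajectory.chain_length < 1:
        raise ValueError("translational correlation needs chains")
    act = _activated_chain_ids(trajectory)
    if act.size == 0:
        return trajectory.stamps[:0].copy(), np.empty(0)
    n_snap = trajectory.n_snapshots
    com = np.zeros((n_snap, act.size, 2))
    for k in range(n_snap):
        com[k] = trajectory.chain_positions(k)[act].mean(axis=1)
    disp = com - com[0]
    dr2 = np.mean(np.sum(disp * disp, axis=2), axis=1)
    return trajectory.stamps.copy(), dr2


# ---------------------------------------------------------------------------
# Fits
# ---------------------------------------------------------------------------


def fit_exponential(times, values):
    """Orientational correlation time tau from C(t) = exp(-t/tau).

    Non-decaying series are reported as math.inf (not a fit).  Points with
    non-positive values are excluded from the log-space seed.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size < 5:
        raise ValueError("need at least 5 points to fit")
    pos = v > 0
    if np.count_nonzero(pos) < 5:
        raise ValueError("need at least 5 positive values to fit")
    slope = np.polyfit(t[pos], np.log(v[pos]), 1)[0]
    if slope >= 0:
        return math.inf
    tau0 = -1.0 / slope
    popt, _ = curve_fit(
        lambda tt, tau: np.exp(-tt / tau), t[pos], v[pos], p0=[tau0], maxfev=10000
    )
    tau = float(popt[0])
    return tau if tau > 0 else math.inf


def fit_powerlaw(times, values):
    """(alpha, beta) from dRcm2(t) = alpha * t^beta via log-log least squares.

    Points with t <= 0 or value <= 0 are excluded; fewer than 5 usable points
    is an error.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    mask = (t > 0) & (v > 0)
    if np.count_nonzero(mask) < 5:
        raise ValueError("need at least 5 strictly positive points to fit a power law")
    beta, log_alpha = np.polyfit(np.log(t[mask]), np.log(v[mask]), 1)
    return float(np.exp(log_alpha)), float(beta)


@dataclass
class CorrResult:
    """Combined chain-relaxation analysis of one run."""

    times: np.ndarray
    cee: np.ndarray
    dr2: np.ndarray
    tau: float
    alpha: float
    beta: float
    dr2_tf: float


def correlation_analysis(trajectory, fit_tmin=0, fit_tmax=None):
    """Correlation functions plus their empirical fits over a time window
    (attempted-move stamps); the window defaults to the full trajectory."""
    times, cee = orientational_correlation(trajectory)
    _, dr2 = translational_correlation(trajectory)
    if times.size == 0:
        return CorrResult(times, cee, dr2, math.nan, math.nan, math.nan, math.nan)
    if fit_tmax is None:
        fit_tmax = times[-1]
    win = (times >= fit_tmin) & (times <= fit_tmax)
    try:
        tau = fit_exponential(times[win], cee[win])
    except ValueError:
        tau = math.nan
    try:
        alpha, beta = fit_powerlaw(times[win], dr2[win])
    except ValueError:
        alpha, beta = math.nan, math.nan
    return CorrResult(times, cee, dr2, tau, alpha, beta, float(dr2[-1]))


# ---------------------------------------------------------------------------
# Swelling kinetics
# ---------------------------------------------------------------------------


@dataclass
class SwellingSeries:
    """A swelling-content time series S(t) = (w_s - w_0)/w_0.

    ``time_unit`` is hours for experimental series and attempted MC moves for
    the simulated proxy."""

    times: np.ndarray
    values: np.ndarray
    time_unit: str = "hours"


@dataclass
class SwellingFit:
    """First-order swelling kinetics S(t) = S_eq * (1 - exp(-k t))."""

    seq: float
    k: float
    low_confidence: bool = False

    def __iter__(self):  # allows: seq, k = fit
        return iter((self.seq, self.k))


def swelling_kinetics_fit(times, values):
    """Fit the first-order swelling model; S(0) = 0 is built into the form.

    Fits reaching less than ~86% of saturation within the observed window
    (k * t_max < 2) are flagged low-confidence.
    """
    t = np.asarray(times, dtype=float)
    s = np.asarray(values, dtype=float)
    if t.size < 5:
        raise ValueError("need at least 5 time points")
    seq0 = max(float(s.max()), 1e-12)
    k0 = 1.0 / max(float(t.max()) / 3.0, 1e-12)
    popt, _ = curve_fit(
        lambda tt, seq, k: seq * (1.0 - np.exp(-k * tt)),
        t,
        s,
        p0=[seq0, k0],
        maxfev=20000,
    )
    seq, k = float(popt[0]), float(popt[1])
    low_conf = not (k > 0) or k * float(t.max()) < 2.0
    return SwellingFit(seq=seq, k=abs(k), low_confidence=low_conf)


def swelling_content(trajectory):
    """Simulated swelling-content proxy.

    Defines the matrix (gel) extent at time t as the highest lattice row
    covered by any chain plaquette and measures total site coverage of all
    species below it; S(t) is the relative coverage gain over the initial
    matrix coverage.  This is a model-side stand-in for the gravimetric
    S = (w_s - w_0)/w_0 so the first-order kinetic fit applies to runs.
    """
    chain_mask = trajectory.species == CHAIN
    if not chain_mask.any():
        raise ValueError("swelling content proxy requires chains")
    n_snap = trajectory.n_snapshots
    values = np.zeros(n_snap)
    cov0 = None
    for k in range(n_snap):
        ys = trajectory.pos[k, :, 1].astype(np.int64)
        extent = int(ys[chain_mask].max()) + 1
        coverage = 4 * int(np.count_nonzero(ys <= extent))
        if cov0 is None:
            cov0 = coverage
        values[k] = (coverage - cov0) / cov0
    return SwellingSeries(
        times=trajectory.stamps.astype(float), values=values, time_unit="attempted moves"
    )


# ---------------------------------------------------------------------------
# Flory-Huggins mapping
# ---------------------------------------------------------------------------


def flory_huggins_chi_general(z, w11, w22, w12, kbt=1.0):
    """chi12 = z * (w12 - (w11 + w22)/2) / kBT."""
    return z * (w12 - 0.5 * (w11 + w22)) / kbt


def flory_huggins_chi(h, eps0=0.8):
    """chi12 for this model's energies (w11 = 0, w22 = eps0*H,
    w12 = eps0*(1-H), z = 24): chi12 = 24*eps0*(1 - 1.5*H), with kBT = 1."""
    return flory_huggins_chi_general(
        COORDINATION_NUMBER, 0.0, eps0 * h, eps0 * (1.0 - h)
    )


# ---------------------------------------------------------------------------
# Run summary (parameter-sweep layout)
# ---------------------------------------------------------------------------


def summarize_run(trajectory, fit_tmin=0, fit_tmax=None):
    """One tidy summary row per run: (H, Ns, tau, alpha, beta, dRcm2(tf),
    activated chain fraction) — the layout used for H x Ns parameter sweeps."""
    res = correlation_analysis(trajectory, fit_tmin=fit_tmin, fit_tmax=fit_tmax)
    m = trajectory.meta
    return {
        "H": m.get("h"),
        "Ns": m.get("ns"),
        "seed": m.get("seed"),
        "tau": res.tau,
        "alpha": res.alpha,
        "beta": res.beta,
        "dr2_tf": res.dr2_tf,
        "activated_fraction": trajectory.activated_fraction(),
        "chi12": flory_huggins_chi(m.get("h", 0.0), m.get("eps0", 0.8)),
    }
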