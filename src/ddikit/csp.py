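"""Chemical-shift-perturbation quantification and K_d estimation.

Amide peaks in a series of HSQC spectra move as ligand is titrated in;
under fast exchange the observed peak sits at the population-weighted
average of the free and bound positions, so

    ddelta_obs(P, L) = ddelta_max * fb(P, L, K_d)

with the bound fraction given by the root of the 1:1 equilibrium
quadratic in total concentrations,

    fb = ((P + L + K_d) - sqrt((P + L + K_d)^2 - 4 P L)) / (2 P).

Per-residue H and N shift changes are combined as
``sqrt(ddH^2 + (alpha * ddN)^2)`` (alpha defaults to 0.2, the common
convention for amide nitrogen scaling). K_d is estimated per reporter
residue by nonlinear least squares with free (K_d, ddelta_max), both
kept positive through a log-parameterization; the headline output is
the min-max range of converged per-residue estimates, with an optional
global fit sharing one K_d across reporters.

Concentrations are read per titration point, never assumed constant, so
dilution along the titration is handled exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

logger = logging.getLogger("ddikit")


class FitError(RuntimeError):
    """No reporter residue produced a converged fit."""


@dataclass
class TitrationPoint:
    protein_mM: float
    ligand_mM: float
    peaks: dict[str, tuple[float, float]]  # residue -> (dH ppm, dN ppm)


@dataclass
class TitrationSeries:
    """Ordered titration points; the first point is the reference."""

    points: list[TitrationPoint]

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValueError("a titration series needs at least 2 points")
        for i, pt in enumerate(self.points):
            if pt.protein_mM <= 0:
                raise ValueError(f"point {i}: protein concentration must be positive")
            if pt.ligand_mM < 0:
                raise ValueError(f"point {i}: negative ligand concentration")

    @property
    def residues(self) -> set[str]:
        out: set[str] = set()
        for pt in self.points:
            out.update(pt.peaks)
        return out

    @property
    def incomplete_residues(self) -> set[str]:
        return {r for r in self.residues if any(r not in pt.peaks for pt in self.points)}

    @property
    def n_points(self) -> int:
        return len(self.points)


@dataclass
class CSPEntry:
    residue: str
    ddh: float
    ddn: float
    csp: float
    flagged: bool  # not reliably observed at reference or evaluation point


@dataclass
class CSPProfile:
    entries: list[CSPEntry]
    alpha: float
    at_point: int

    def __getitem__(self, residue: str) -> CSPEntry:
        for e in self.entries:
            if e.residue == residue:
                return e
        raise KeyError(residue)

    @property
    def reliable(self) -> list[CSPEntry]:
        return [e for e in self.entries if not e.flagged]


def combined_csp(ddh: float, ddn: float, alpha: float = 0.2) -> float:
    """Combined amide CSP ``sqrt(ddH^2 + (alpha*ddN)^2)``; alpha >= 0.

    With ``alpha=0`` this degenerates to ``|ddH|``.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    return math.hypot(ddh, alpha * ddn)


def csp_profile(series: TitrationSeries, at_point: int = -1, alpha: float = 0.2) -> CSPProfile:
    """Per-residue CSP at one titration point relative to the reference.

    Residues absent at the reference or the evaluation point are flagged
    (NaN components) and excluded from downstream fits.
    """
    ref = series.points[0]
    idx = at_point % len(series.points)
    target = series.points[idx]
    entries = []
    for residue in sorted(series.residues):
        if residue in ref.peaks and residue in target.peaks:
            ddh = target.peaks[residue][0] - ref.peaks[residue][0]
            ddn = target.peaks[residue][1] - ref.peaks[residue][1]
            entries.append(CSPEntry(residue, ddh, ddn, combined_csp(ddh, ddn, alpha), False))
        else:
            entries.append(CSPEntry(residue, float("nan"), float("nan"), float("nan"), True))
    return CSPProfile(entries=entries, alpha=alpha, at_point=idx)


def select_reporters(
    profile: CSPProfile,
    k: float = 1.0,
    explicit: Iterable[str] | None = None,
    top_n: int = 5,
) -> list[str]:
    """Choose reporter residues for K_d fitting.

    Explicit mode returns the given residues that exist in the profile
    (mirroring a hand-picked reporter list). Auto mode selects residues
    with CSP above mean + k*sd of the not-yet-selected reliable residues,
    iterating (selected residues removed from the statistics) until the
    set is stable; if nothing clears the threshold, falls back to the
    top ``top_n`` by CSP with a warning.
    """
    if not profile.entries:
        raise ValueError("empty CSP profile")
    if explicit is not None:
        wanted = list(explicit)
        present = {e.residue for e in profile.entries if not e.flagged}
        return [r for r in wanted if r in present]
    pool = {e.residue: e.csp for e in profile.reliable}
    selected: set[str] = set()
    while True:
        rest = [v for r, v in pool.items() if r not in selected]
        if len(rest) < 2:
            break
        thr = float(np.mean(rest) + k * np.std(rest, ddof=1))
        new = {r for r, v in pool.items() if r not in selected and v > thr}
        if not new:
            break
        selected |= new
    if not selected:
        logger.warning("select_reporters: nothing above mean + %.1f sd; falling back to top %d", k, top_n)
        selected = set(sorted(pool, key=pool.get, reverse=True)[:top_n])
    return sorted(selected, key=pool.get, reverse=True)


def fraction_bound(P, L, kd):
    """Bound fraction of the protein for 1:1 binding at total concentrations.

    Root of ``P*fb^2 - (P+L+kd)*fb + L = 0`` lying in [0, 1); the
    discriminant ``(P+L+kd)^2 - 4PL`` is provably non-negative.
    """
    P = np.asarray(P, dtype=float)
    L = np.asarray(L, dtype=float)
    s = P + L + kd
    disc = s * s - 4.0 * P * L
    assert np.all(disc >= 0), "equilibrium quadratic produced a negative discriminant"
    return (s - np.sqrt(disc)) / (2.0 * P)


def binding_curve(P, L, kd: float, ddelta_max: float):
    """Observed CSP under the 1:1 fast-exchange model:
    ``ddelta_max * fraction_bound(P, L, kd)``."""
    if kd <= 0:
        raise ValueError("kd must be positive")
    return ddelta_max * fraction_bound(P, L, kd)


@dataclass
class KdFitEntry:
    residue: str
    kd_mM: float
    ddelta_max: float
    residual_norm: float
    converged: bool


@dataclass
class KdFit:
    """Per-residue and aggregate dissociation-constant estimates."""

    entries: list[KdFitEntry]
    kd_range: tuple[float, float]  # (min, max) over converged reporters
    global_kd: float | None = None
    bootstrap_interval: tuple[float, float] | None = None
    alpha: float = 0.2

    @property
    def converged_entries(self) -> list[KdFitEntry]:
        return [e for e in self.entries if e.converged]


def _reporter_data(
    series: TitrationSeries, residue: str, alpha: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(P, L, ddelta) arrays over non-reference points where the residue
    is observed; ddelta relative to the reference point."""
    ref = series.points[0]
    if residue not in ref.peaks:
        return np.array([]), np.array([]), np.array([])
    h0, n0 = ref.peaks[residue]
    P, L, y = [], [], []
    for pt in series.points[1:]:
        if residue not in pt.peaks:
            continue
        h, n = pt.peaks[residue]
        P.append(pt.protein_mM)
        L.append(pt.ligand_mM)
        y.append(combined_csp(h - h0, n - n0, alpha))
    return np.asarray(P), np.asarray(L), np.asarray(y)


def _fit_single(P: np.ndarray, L: np.ndarray, y: np.ndarray) -> tuple[float, float, float, bool]:
    kd0 = float(np.median(L[L > 0])) if np.any(L > 0) else 1.0
    dmax0 = 1.2 * float(y[-1]) if y[-1] > 0 else max(float(np.max(y)), 1e-3)

    def resid(theta):
        kd, dmax = np.exp(theta)
        return dmax * fraction_bound(P, L, kd) - y

    res = least_squares(resid, x0=[math.log(kd0), math.log(max(dmax0, 1e-6))], method="lm")
    kd, dmax = np.exp(res.x)
    # estimates collapsing to the edge of identifiability (K_d orders of
    # magnitude outside any measurable concentration) are flagged rather
    # than allowed to pollute the reported range
    converged = bool(
        res.success and np.isfinite(kd) and np.isfinite(dmax) and 1e-4 < kd < 1e4
    )
    return float(kd), float(dmax), float(np.linalg.norm(res.fun)), converged


def fit_kd(
    series: TitrationSeries,
    reporters: Sequence[str],
    alpha: float = 0.2,
    global_fit: bool = True,
) -> KdFit:
    """Fit the 1:1 binding isotherm per reporter residue.

    Requires at least 3 titration points with distinct ligand:protein
    ratios. Per-residue fits give the aggregate (min, max) K_d range;
    ``global_fit`` adds a shared-K_d estimate with per-residue
    ddelta_max.
    """
    if not reporters:
        raise ValueError("reporters must be non-empty")
    ratios = {round(pt.ligand_mM / pt.protein_mM, 9) for pt in series.points}
    if series.n_points < 3 or len(ratios) < 3:
        raise ValueError("need >= 3 titration points with distinct ligand:protein ratios")

    entries: list[KdFitEntry] = []
    data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for residue in reporters:
        P, L, y = _reporter_data(series, residue, alpha)
        if len(y) < 3:
            logger.warning("fit_kd: residue %s observed at <3 points, excluded", residue)
            entries.append(KdFitEntry(residue, float("nan"), float("nan"), float("nan"), False))
            continue
        data[residue] = (P, L, y)
        try:
            kd, dmax, rnorm, ok = _fit_single(P, L, y)
        except Exception:  # numerical failure on a residue is flagged, not fatal
            kd, dmax, rnorm, ok = float("nan"), float("nan"), float("nan"), False
        entries.append(KdFitEntry(residue, kd, dmax, rnorm, ok))

    good = [e for e in entries if e.converged]
    if not good:
        raise FitError("no reporter residue produced a converged fit")
    kd_range = (min(e.kd_mM for e in good), max(e.kd_mM for e in good))

    global_kd = None
    if global_fit:
        global_kd = _fit_global({r: data[r] for r in data if any(e.residue == r and e.converged for e in entries)})
    return KdFit(entries=entries, kd_range=kd_range, global_kd=global_kd, alpha=alpha)


def _fit_global(data: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]) -> float:
    """One shared K_d, per-residue ddelta_max."""
    residues = sorted(data)
    kd0 = float(np.median(np.concatenate([data[r][1] for r in residues])))

    def resid(theta):
        kd = math.exp(theta[0])
        out = []
        for i, r in enumerate(residues):
            P, L, y = data[r]
            dmax = math.exp(theta[1 + i])
            out.append(dmax * fraction_bound(P, L, kd) - y)
        return np.concatenate(out)

    x0 = [math.log(max(kd0, 1e-6))] + [
        math.log(max(1.2 * data[r][2][-1], 1e-6)) for r in residues
    ]
    res = least_squares(resid, x0=x0, method="lm")
    return float(math.exp(res.x[0]))


def bootstrap_kd(
    series: TitrationSeries,
    reporters: Sequence[str],
    n_boot: int = 500,
    seed: int = 0,
    alpha: float = 0.2,
) -> tuple[float, float]:
    """Percentile 95% interval on the global K_d by case-resampling the
    (non-reference) titration points within each reporter."""
    if n_boot < 50:
        logger.warning("bootstrap_kd: n_boot=%d is small; interval will be unstable", n_boot)
    rng = np.random.default_rng(seed)
    data = {}
    for r in reporters:
        P, L, y = _reporter_data(series, r, alpha)
        if len(y) >= 3:
            data[r] = (P, L, y)
    if not data:
        raise FitError("no reporter with enough points to bootstrap")
    estimates = []
    for _ in range(n_boot):
        resampled = {}
        for r, (P, L, y) in data.items():
            idx = rng.integers(0, len(y), size=len(y))
            resampled[r] = (P[idx], L[idx], y[idx])
        try:
            estimates.append(_fit_global(resampled))
        except Exception:
            continue
    if not estimates:
        raise FitError("all bootstrap replicates failed")
    lo, hi = np.percentile(estimates, [2.5, 97.5])
    return float(lo), float(hi)
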