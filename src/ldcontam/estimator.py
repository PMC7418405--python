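"""Contamination estimation from the breakdown of linkage disequilibrium.

Model.  For a panel pair with pseudo-haploid distribution ``q`` and
background distribution ``h~``, a contamination fraction ``a`` mixes the
two: a sequence pair is formed by two uncontaminated or two contaminant
sequences (probability ``(1-a)^2 + a^2``, preserving LD, hence ``q``) or
by one of each (probability ``2a(1-a)``, breaking LD, hence ``h~``)::

    T(a) = (1 - 2a + 2a^2) q + 2a(1-a) h~

The estimate maximises, over a grid of ``a`` from -0.1 to 0.5 in steps of
1e-4, the LOD score: the summed per-pair multinomial log-likelihood of the
observed sequence-pair configurations under ``T(a)`` minus the same at
``a = 0``, in log10 units.  Negative grid values absorb the downward shift
caused by inbreeding.

Bias correction.  Reference-panel mismatch shifts the raw estimate by a
constant ``k``.  In damage mode the three damage classes carry different
effective parameters -- UU: ``a + k``, DU: ``a/2 + k``, DD: ``k`` (damaged
sequences are assumed uncontaminated) -- and the summed likelihood is
maximised jointly over (a, k) on a coarse-to-fine grid; the resulting
``a`` is the contamination rate among undamaged sequences and is rescaled
by (1 - damage rate) to refer to all sequences.  In external mode a
benchmark estimate from an assumed-uncontaminated individual is
subtracted instead.

Standard errors come from a weighted delete-one-chromosome jackknife,
which also absorbs the dependence created by overlapping SNP pairs and by
treating multiple sequences per SNP as independent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .counts import CLASSES, PairObservations, SiteCounts, damage_summary, pair_observations
from .panel import HaplotypePanel, validate_distribution

LN10 = math.log(10.0)
_PROB_FLOOR = 1e-300

#: internal grid unit: all scan parameters are integer multiples of 5e-5,
#: so alpha (step 1e-4), k (step 1e-4) and the class parameters a+k, a/2+k,
#: k all live on one exact integer lattice.
UNIT = 5e-5
_ALPHA_LO, _ALPHA_HI = -2000, 10000      # -0.1 .. 0.5 in units of 5e-5
_K_LO, _K_HI = -2000, 6000               # -0.1 .. 0.3
_STEP = 2                                # alpha/k step 1e-4
_COARSE = 40                             # coarse step 0.002
_REFINE = 80                             # refine radius 0.004

#: admissible mixture parameters: both mixture weights of T written on the
#: (h, h~) basis are non-negative, i.e. 1 + 2a - 2a^2 >= 0.
ALPHA_ADMISSIBLE = ((1 - math.sqrt(3)) / 2, (1 + math.sqrt(3)) / 2)

VERY_HIGH_WARNING = "Very_High_Contamination"
VERY_HIGH_THRESHOLD = 0.15


def very_high_warning(alpha_raw: float) -> str:
    """Warning flag for the *uncorrected* estimate.

    Raw estimates above 15% flag the sample even when the corrected
    estimate is low: a large raw score with a near-zero corrected score
    is the signature of either heavy contamination or cross-contamination
    by another ancient (damaged) sample, which the damage correction
    silently absorbs.
    """
    return VERY_HIGH_WARNING if alpha_raw > VERY_HIGH_THRESHOLD else ""


class FloorCounter:
    """Counts log-probability floor events during a run."""

    def __init__(self):
        self.count = 0

    def reset(self):
        self.count = 0


#: per-run counter of floored log-probability contributions
floor_counter = FloorCounter()


def mixture_distribution(q, h_bg, alpha: float) -> np.ndarray:
    """Contamination-mixture haplotype distribution T(alpha).

    ``T = (1 - 2a + 2a^2) q + 2a(1-a) h~``; symmetric under
    ``a -> 1 - a``.  Errors if ``alpha`` lies outside the admissible
    range where T is guaranteed non-negative.
    """
    q = validate_distribution(q)
    h_bg = validate_distribution(h_bg)
    lo, hi = ALPHA_ADMISSIBLE
    if not (lo <= alpha <= hi):
        raise ValueError(f"alpha={alpha} outside admissible range [{lo:.4f}, {hi:.4f}]")
    w_q = 1.0 - 2.0 * alpha + 2.0 * alpha * alpha
    w_bg = 2.0 * alpha * (1.0 - alpha)
    return w_q * q + w_bg * h_bg


def pair_loglik(obs, T) -> float:
    """Multinomial log-likelihood sum_(a,b) obs(a,b) * log T(a,b).

    Cells where ``T`` is zero but observed contribute with probability
    floored at 1e-300; each such event increments the module-level
    :data:`floor_counter`.
    """
    obs = np.asarray(obs, dtype=float)
    T = np.asarray(T, dtype=float)
    floored = (T <= 0) & (obs > 0)
    if floored.any():
        floor_counter.count += int(floored.sum())
    return float(np.sum(obs * np.log(np.maximum(T, _PROB_FLOOR))))


def _mix_coeffs(t):
    """Coefficients (a, b) with T(t) = a*h + b*h~ when q = h/2 + h~/2."""
    t = np.asarray(t, dtype=float)
    a = 0.5 * (1.0 - 2.0 * t + 2.0 * t * t)
    b = 0.5 * (1.0 + 2.0 * t - 2.0 * t * t)
    return a, b


class _CurveSet:
    """Per-chromosome profile log-likelihood curves for one set of cells.

    Holds the flattened nonzero observation cells (weights ``w``, panel
    values ``h`` and ``h~`` per cell, chromosome index per cell) and
    evaluates, for arbitrary integer lattice points ``t``::

        L_c(t) = sum_{cells on chrom c} w * log(a(t) h + b(t) h~)

    exactly, returning an (n_chrom, n_t) matrix.  Additive constants
    (e.g. ``sum w log h~``) are retained, but every consumer takes
    differences or argmaxes, so they never matter.
    """

    def __init__(self, obs_matrix, h, h_bg, chrom_index, n_chrom):
        w = np.asarray(obs_matrix, dtype=float).ravel()
        nz = w > 0
        self.w = w[nz]
        self.h = np.asarray(h, dtype=float).ravel()[nz]
        self.hbg = np.asarray(h_bg, dtype=float).ravel()[nz]
        self.chrom = np.repeat(np.asarray(chrom_index, dtype=np.int64), 4)[nz]
        self.n_chrom = n_chrom
        self.total = float(self.w.sum())
        self._cache: dict[int, np.ndarray] = {}

    def eval_ints(self, t_ints) -> np.ndarray:
        """Curves at integer lattice points (cached), shape (n_chrom, n_t)."""
        t_ints = np.asarray(t_ints, dtype=np.int64)
        missing = [int(t) for t in t_ints if int(t) not in self._cache]
        if missing and self.w.size:
            buf = np.empty_like(self.h)
            for t in missing:
                a, b = _mix_coeffs(t * UNIT)
                np.multiply(self.h, a, out=buf)
                buf += b * self.hbg
                np.maximum(buf, _PROB_FLOOR, out=buf)
                np.log(buf, out=buf)
                buf *= self.w
                self._cache[t] = np.bincount(self.chrom, weights=buf,
                                             minlength=self.n_chrom)
        elif missing:
            zero = np.zeros(self.n_chrom)
            for t in missing:
                self._cache[t] = zero
        return np.stack([self._cache[int(t)] for t in t_ints], axis=1)


@dataclass
class LODCurve:
    """LOD scores over the alpha grid, relative to alpha = 0."""

    grid: np.ndarray
    lod: np.ndarray

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.lod = np.asarray(self.lod, dtype=float)

    @property
    def alpha_hat(self) -> float:
        """Grid argmax; ties resolve toward the smaller alpha."""
        return float(self.grid[int(np.argmax(self.lod))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"alpha": self.grid, "lod": self.lod})


def _alpha_lattice(grid_lo: float, grid_hi: float, step: float):
    lo = int(round(grid_lo / UNIT))
    hi = int(round(grid_hi / UNIT))
    st = int(round(step / UNIT))
    if st <= 0 or lo % st or hi % st:
        raise ValueError("grid bounds must be multiples of the step")
    return np.arange(lo, hi + 1, st, dtype=np.int64)


class _RawScan:
    """Pooled-class LOD scan with per-chromosome curves for the jackknife."""

    def __init__(self, pairobs: PairObservations, panel: HaplotypePanel,
                 classes=CLASSES, grid_lo=-0.1, grid_hi=0.5, step=1e-4):
        obs = sum(pairobs.class_matrix(c) for c in classes)
        if obs.sum() == 0:
            raise ValueError("no pair observations")
        h = panel.h[pairobs.pair_index]
        hbg = panel.h_bg[pairobs.pair_index]
        self.chroms = np.unique(pairobs.chrom)
        chrom_index = np.searchsorted(self.chroms, pairobs.chrom)
        self.curves = _CurveSet(obs, h, hbg, chrom_index, len(self.chroms))
        self.t_ints = _alpha_lattice(grid_lo, grid_hi, step)
        self.per_chrom = self.curves.eval_ints(self.t_ints)  # (n_chrom, n_t)
        self.zero_col = int(np.searchsorted(self.t_ints, 0))
        if self.t_ints[self.zero_col] != 0:
            raise ValueError("alpha grid must contain 0 (the null hypothesis)")

    def lod_curve(self, exclude_chrom=None) -> LODCurve:
        total = self.per_chrom.sum(axis=0)
        if exclude_chrom is not None:
            row = int(np.searchsorted(self.chroms, exclude_chrom))
            total = total - self.per_chrom[row]
        lod = (total - total[self.zero_col]) / LN10
        return LODCurve(grid=self.t_ints * UNIT, lod=lod)


def lod_scan(pairobs: PairObservations, panel: HaplotypePanel, classes=CLASSES,
             grid_lo: float = -0.1, grid_hi: float = 0.5, step: float = 1e-4):
    """Grid LOD scan of the contamination mixture over pooled classes.

    Returns ``(curve, alpha_hat)`` where ``curve.lod[i]`` is the summed
    per-pair log10 likelihood ratio of ``T(grid[i])`` against ``T(0)``.
    LOD(0) is exactly 0; ties in the argmax break toward smaller alpha.
    """
    scan = _RawScan(pairobs, panel, classes=classes, grid_lo=grid_lo,
                    grid_hi=grid_hi, step=step)
    curve = scan.lod_curve()
    return curve, curve.alpha_hat


class _DamageScan:
    """Joint (alpha, k) likelihood over damage classes, coarse-to-fine.

    The summed likelihood L(a, k) = L_UU(a+k) + L_DU(a/2+k) + L_DD(k)
    decomposes into three 1-D profile curves, so both grid passes are
    exact lattice lookups.  Per-chromosome curves make the delete-one
    jackknife cheap.
    """

    def __init__(self, pairobs: PairObservations, panel: HaplotypePanel,
                 min_dd_obs: int = 1000):
        h = panel.h[pairobs.pair_index]
        hbg = panel.h_bg[pairobs.pair_index]
        self.chroms = np.unique(pairobs.chrom)
        chrom_index = np.searchsorted(self.chroms, pairobs.chrom)
        n_chrom = len(self.chroms)
        self.cs = {c: _CurveSet(pairobs.class_matrix(c), h, hbg, chrom_index, n_chrom)
                   for c in CLASSES}
        if self.cs["UU"].total + self.cs["DU"].total + self.cs["DD"].total == 0:
            raise ValueError("no pair observations")
        if self.cs["DD"].total < min_dd_obs:
            warnings.warn("insufficient damaged data; correction unreliable",
                          RuntimeWarning)
        self.a_coarse = np.arange(_ALPHA_LO, _ALPHA_HI + 1, _COARSE, dtype=np.int64)
        self.k_coarse = np.arange(_K_LO, _K_HI + 1, _COARSE, dtype=np.int64)

    def _objective(self, a_ints, k_ints, exclude_row=None):
        """L(a, k) matrix over the given lattices (a rows, k cols)."""
        t_uu = a_ints[:, None] + k_ints[None, :]
        t_du = a_ints[:, None] // 2 + k_ints[None, :]
        t_dd = k_ints
        L = np.zeros(t_uu.shape)
        for cls, tm in (("UU", t_uu), ("DU", t_du)):
            uniq, inv = np.unique(tm, return_inverse=True)
            cur = self.cs[cls].eval_ints(uniq)
            tot = cur.sum(axis=0) if exclude_row is None else cur.sum(axis=0) - cur[exclude_row]
            L += tot[inv].reshape(tm.shape)
        cur = self.cs["DD"].eval_ints(t_dd)
        tot = cur.sum(axis=0) if exclude_row is None else cur.sum(axis=0) - cur[exclude_row]
        L += tot[None, :]
        return L

    def fit(self, exclude_chrom=None):
        """Maximise L(a, k); returns (alpha, k, at_boundary).

        Coarse pass at step 0.002 on each axis, then a fine pass at step
        1e-4 within +-0.004 of the coarse optimum.  Ties break toward
        smaller alpha, then smaller k (row-major argmax).
        """
        row = None
        if exclude_chrom is not None:
            row = int(np.searchsorted(self.chroms, exclude_chrom))
        L = self._objective(self.a_coarse, self.k_coarse, exclude_row=row)
        ia, ik = np.unravel_index(int(np.argmax(L)), L.shape)
        a0, k0 = int(self.a_coarse[ia]), int(self.k_coarse[ik])
        a_fine = np.arange(max(_ALPHA_LO, a0 - _REFINE),
                           min(_ALPHA_HI, a0 + _REFINE) + 1, _STEP, dtype=np.int64)
        k_fine = np.arange(max(_K_LO, k0 - _REFINE),
                           min(_K_HI, k0 + _REFINE) + 1, _STEP, dtype=np.int64)
        Lf = self._objective(a_fine, k_fine, exclude_row=row)
        ia, ik = np.unravel_index(int(np.argmax(Lf)), Lf.shape)
        a_hat, k_hat = int(a_fine[ia]), int(k_fine[ik])
        at_boundary = a_hat in (_ALPHA_LO, _ALPHA_HI) or k_hat in (_K_LO, _K_HI)
        return a_hat * UNIT, k_hat * UNIT, at_boundary


def damage_corrected_estimate(pairobs: PairObservations, panel: HaplotypePanel,
                              d: float, min_dd_obs: int = 1000):
    """Damage-stratified joint estimate of contamination and panel bias.

    Maximises ``L_UU(a + k) + L_DU(a/2 + k) + L_DD(k)`` over a
    coarse-to-fine grid.  ``a`` is the contamination rate among undamaged
    sequences; ``alpha_all = a * (1 - d)`` refers to all sequences.

    Returns ``(alpha, k, alpha_all)``.  Warns if the DD class has fewer
    than ``min_dd_obs`` observations or if the optimum sits on the grid
    boundary.
    """
    scan = _DamageScan(pairobs, panel, min_dd_obs=min_dd_obs)
    alpha, k, at_boundary = scan.fit()
    if at_boundary:
        warnings.warn("estimate at grid boundary", RuntimeWarning)
    return alpha, k, alpha * (1.0 - d)


def external_corrected_estimate(alpha_raw: float, benchmark_alpha: float) -> float:
    """Subtract the estimate of an assumed-uncontaminated benchmark sample."""
    return alpha_raw - benchmark_alpha


def weighted_jackknife(theta_full: float, theta_del, weights):
    """Weighted delete-one-block jackknife standard error.

    Standard weighted jackknife for unequal block sizes: with ``g``
    blocks of weight ``w_c`` (total ``n``), ``h_c = n / w_c``, delete-one
    estimates ``theta_c`` and pseudovalues
    ``p_c = h_c theta - (h_c - 1) theta_c``,

        theta_J = g theta - sum_c (1 - w_c/n) theta_c
        var     = (1/g) sum_c (p_c - theta_J)^2 / (h_c - 1)

    Reduces to the unweighted delete-one formula for equal weights and to
    ``|theta_1 - theta_2| / 2`` for two equal blocks.
    """
    theta_del = np.asarray(theta_del, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if theta_del.shape != weights.shape or theta_del.ndim != 1:
        raise ValueError("delete-one estimates and weights must be 1-D and aligned")
    g = len(theta_del)
    if g < 2:
        raise ValueError("jackknife requires >=2 blocks")
    if np.any(weights <= 0):
        raise ValueError("block weights must be positive")
    n = weights.sum()
    h = n / weights
    theta_j = g * theta_full - float(((1.0 - weights / n) * theta_del).sum())
    pseudo = h * theta_full - (h - 1.0) * theta_del
    var = float(np.sum((pseudo - theta_j) ** 2 / (h - 1.0)) / g)
    return math.sqrt(max(var, 0.0))


def jackknife_se(pairobs: PairObservations, panel: HaplotypePanel,
                 estimator_config: dict = None):
    """Delete-one-chromosome jackknife SE of the configured estimate.

    ``estimator_config`` keys: ``mode`` ("none", "damage" or "external"),
    ``d`` (damage rate, damage mode), ``benchmark`` (external mode).
    Block weights are the pooled pair-observation counts per chromosome.

    Returns ``(se, per_chrom)`` where ``per_chrom`` maps chromosome to its
    delete-one estimate.
    """
    cfg = dict(estimator_config or {})
    mode = cfg.get("mode", "none")
    chroms = np.unique(pairobs.chrom)
    if len(chroms) < 2:
        raise ValueError("jackknife requires >=2 chromosomes")
    weights = pairobs.per_chrom_totals()

    if mode == "damage":
        scan = _DamageScan(pairobs, panel, min_dd_obs=cfg.get("min_dd_obs", 1000))
        d_full = cfg.get("d", 0.0)
        dsum = cfg.get("damage_summary")
        a, _, _ = scan.fit()
        full = a * (1.0 - d_full)
        per_chrom = {}
        for ch in chroms:
            a_c, _, _ = scan.fit(exclude_chrom=ch)
            d_c = dsum.d_excluding(ch) if dsum is not None else d_full
            per_chrom[int(ch)] = a_c * (1.0 - d_c)
    else:
        scan = _RawScan(pairobs, panel)
        shift = cfg.get("benchmark", 0.0) if mode == "external" else 0.0
        full = scan.lod_curve().alpha_hat - shift
        per_chrom = {int(ch): scan.lod_curve(exclude_chrom=ch).alpha_hat - shift
                     for ch in chroms}
    w = np.array([weights[int(ch)] for ch in chroms])
    th = np.array([per_chrom[int(ch)] for ch in chroms])
    se = weighted_jackknife(full, th, w)
    return se, per_chrom


@dataclass
class ContamEstimate:
    """Full contamination report for one sample."""

    alpha_raw: float
    alpha_corrected: float
    k_hat: float
    se: float
    n_pair_obs: float
    damage_rate: float
    correction_mode: str
    warning: str
    lod_curve: LODCurve
    per_chrom: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    @property
    def alpha_corrected_floor0(self) -> float:
        """Corrected estimate floored at zero (reporting convenience)."""
        return max(self.alpha_corrected, 0.0)

    @property
    def ci95(self):
        return (self.alpha_corrected - 1.96 * self.se,
                self.alpha_corrected + 1.96 * self.se)

    def to_frame(self, sample: str = "sample") -> pd.DataFrame:
        lo, hi = self.ci95
        return pd.DataFrame([{
            "sample": sample, "alpha_raw": self.alpha_raw, "k_hat": self.k_hat,
            "damage_rate": self.damage_rate, "alpha_corrected": self.alpha_corrected,
            "alpha_corrected_floor0": self.alpha_corrected_floor0, "se": self.se,
            "ci95_lo": lo, "ci95_hi": hi, "n_pair_obs": self.n_pair_obs,
            "warning": self.warning,
        }])


class ContaminationEstimator(BaseEstimator):
    """Estimate the contamination fraction of a sequenced sample.

    scikit-learn style estimator: configure with a haplotype reference
    panel and a correction mode, then :meth:`fit` on per-SNP sequence
    counts.  Fitted attributes carry the raw and corrected estimates, the
    LOD curve, the jackknife SE and diagnostics.

    Parameters
    ----------
    panel : HaplotypePanel
    correction : {"damage", "external", "none"}, default "damage"
        Bias-correction mode.  ``damage`` estimates the panel-mismatch
        shift from damaged (presumed uncontaminated) sequences;
        ``external`` subtracts ``benchmark_alpha``.
    benchmark_alpha : float, optional
        Raw estimate of an assumed-uncontaminated individual of the same
        population (required for ``correction="external"``).
    min_dd_obs : int, default 1000
        Minimum DD-class observations before the damage correction is
        considered reliable (warns below).

    Attributes
    ----------
    alpha_raw_ : float
        Uncorrected pooled-class grid-scan estimate (basis of the
        very-high-contamination warning).
    alpha_corrected_ : float
    k_hat_ : float
        Estimated linear panel-mismatch shift (damage mode; NaN otherwise).
    se_ : float
        Weighted delete-one-chromosome jackknife standard error of the
        corrected estimate.
    lod_curve_ : LODCurve
    warning_ : str
        "" or "Very_High_Contamination" (raw estimate above 15%).
    damage_rate_ : float
    per_chrom_ : dict
        Delete-one-chromosome corrected estimates.
    """

    def __init__(self, panel: HaplotypePanel = None, correction: str = "damage",
                 benchmark_alpha: float = None, min_dd_obs: int = 1000,
                 grid_lo: float = -0.1, grid_hi: float = 0.5, grid_step: float = 1e-4):
        self.panel = panel
        self.correction = correction
        self.benchmark_alpha = benchmark_alpha
        self.min_dd_obs = min_dd_obs
        self.grid_lo = grid_lo
        self.grid_hi = grid_hi
        self.grid_step = grid_step

    def fit(self, X: SiteCounts, y=None):
        """Fit the contamination estimate from per-SNP sequence counts."""
        if self.panel is None:
            raise ValueError("a HaplotypePanel is required")
        if self.correction not in ("damage", "external", "none"):
            raise ValueError(f"unknown correction mode {self.correction!r}")
        if self.correction == "external" and self.benchmark_alpha is None:
            raise ValueError("external correction requires benchmark_alpha")
        counts = X if isinstance(X, SiteCounts) else SiteCounts(pd.DataFrame(X))

        pairobs = pair_observations(self.panel, counts)
        dsum = damage_summary(counts, self.panel)
        chroms = np.unique(pairobs.chrom)

        raw = _RawScan(pairobs, self.panel, grid_lo=self.grid_lo,
                       grid_hi=self.grid_hi, step=self.grid_step)
        curve = raw.lod_curve()
        alpha_raw = curve.alpha_hat
        warning = very_high_warning(alpha_raw)

        k_hat = float("nan")
        if self.correction == "damage":
            scan = _DamageScan(pairobs, self.panel, min_dd_obs=self.min_dd_obs)
            a_u, k_hat, at_boundary = scan.fit()
            if at_boundary:
                warnings.warn("estimate at grid boundary", RuntimeWarning)
            alpha_corrected = a_u * (1.0 - dsum.d)
            per_chrom = {}
            for ch in chroms:
                a_c, _, _ = scan.fit(exclude_chrom=ch)
                per_chrom[int(ch)] = a_c * (1.0 - dsum.d_excluding(ch))
        elif self.correction == "external":
            alpha_corrected = external_corrected_estimate(alpha_raw, self.benchmark_alpha)
            per_chrom = {int(ch): raw.lod_curve(exclude_chrom=ch).alpha_hat
                         - self.benchmark_alpha for ch in chroms}
        else:
            alpha_corrected = alpha_raw
            per_chrom = {int(ch): raw.lod_curve(exclude_chrom=ch).alpha_hat
                         for ch in chroms}

        if len(chroms) < 2:
            raise ValueError("jackknife requires >=2 chromosomes")
        wmap = pairobs.per_chrom_totals()
        w = np.array([wmap[int(ch)] for ch in chroms])
        th = np.array([per_chrom[int(ch)] for ch in chroms])
        self.se_ = weighted_jackknife(alpha_corrected, th, w)

        self.alpha_raw_ = alpha_raw
        self.alpha_corrected_ = alpha_corrected
        self.k_hat_ = k_hat
        self.lod_curve_ = curve
        self.warning_ = warning
        self.damage_rate_ = dsum.d
        self.per_chrom_ = per_chrom
        self.n_pair_obs_ = pairobs.total()
        self.diagnostics_ = {
            "n_pairs_covered": int(len(pairobs.pair_index)),
            "n_pairs_skipped": pairobs.n_pairs_skipped,
            "n_sites_mismatched": pairobs.n_sites_mismatched,
            "n_chromosomes": int(len(chroms)),
            "class_totals": {c: pairobs.total([c]) for c in CLASSES},
        }
        return self

    def report_(self) -> ContamEstimate:
        """Fitted results as a :class:`ContamEstimate` record."""
        return ContamEstimate(
            alpha_raw=self.alpha_raw_, alpha_corrected=self.alpha_corrected_,
            k_hat=self.k_hat_, se=self.se_, n_pair_obs=self.n_pair_obs_,
            damage_rate=self.damage_rate_, correction_mode=self.correction,
            warning=self.warning_, lod_curve=self.lod_curve_,
            per_chrom=self.per_chrom_, diagnostics=self.diagnostics_)


def estimate(counts: SiteCounts, panel: HaplotypePanel, mode: str = "damage",
             benchmark: float = None, min_dd_obs: int = 1000) -> ContamEstimate:
    """One-call contamination estimate (functional wrapper).

    Orchestrates pair observation assembly, the pooled raw LOD scan, the
    configured bias correction, the chromosome jackknife and the
    very-high-contamination warning.
    """
    est = ContaminationEstimator(panel=panel, correction=mode,
                                 benchmark_alpha=benchmark, min_dd_obs=min_dd_obs)
    est.fit(counts)
    return est.report_()
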