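"""Two-SNP haplotype reference panels.

A panel is the collection of autosomal SNP pairs in high linkage
disequilibrium (squared genotype correlation above a cutoff, default 0.2)
together with, per pair:

* ``h``   -- the population haplotype distribution over the four joint
  allele configurations ``(a, b)`` of the pair (0 = reference allele,
  1 = alternative), estimated from *unphased* diploid genotype counts by
  an EM algorithm;
* ``h~``  -- the background ("unrelated haplotype") distribution obtained
  by multiplying the two single-SNP allele frequencies;
* ``q = h/2 + h~/2`` -- the distribution expected for pseudo-haploid
  sequence pairs sampled from an uncontaminated diploid individual: the
  two sequences come from the same parental chromosome with probability
  1/2 (true haplotype) and from opposite chromosomes otherwise
  (background haplotype).

Haplotype distributions are plain length-4 numpy vectors indexed by
``2*a + b``, i.e. ``[f00, f01, f10, f11]``.  Diploid pair counts are 3x3
arrays ``c[i, j]`` indexed by alternative-allele dosage at each SNP.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

AUTOSOMES = frozenset(range(1, 23))

#: columns of the tab-separated panel interchange format.  The background
#: and pseudo-haploid distributions are never stored; they are recomputed
#: from (p1, p2, h) on load so the q = h/2 + h~/2 invariant always holds.
PANEL_COLUMNS = [
    "chrom", "pos1", "ref1", "alt1", "pos2", "ref2", "alt2",
    "r2", "p1", "p2", "h00", "h01", "h10", "h11",
]

# Ordered parental haplotype pairs (t1, t2) -> diploid dosage cell (i, j).
# t = 2*a + b; i = a1 + a2, j = b1 + b2.  16 ordered pairs over 9 cells;
# only the double-heterozygote cell (1, 1) is ambiguous.
_ORDERED_PAIRS = tuple(
    (2 * a1 + b1, 2 * a2 + b2, a1 + a2, b1 + b2)
    for a1, b1, a2, b2 in itertools.product((0, 1), repeat=4)
)

_PROB_FLOOR = 1e-300


def validate_distribution(freqs, tol: float = 1e-9) -> np.ndarray:
    """Check that ``freqs`` is a valid haplotype distribution.

    Entries must be non-negative and sum to 1 within ``tol``.  Returns the
    distribution as a float64 array of shape (4,).
    """
    arr = np.asarray(freqs, dtype=float)
    if arr.shape != (4,):
        raise ValueError(f"haplotype distribution must have 4 entries, got shape {arr.shape}")
    if np.any(arr < 0):
        raise ValueError("haplotype distribution has negative entries")
    if abs(arr.sum() - 1.0) > tol:
        raise ValueError(f"haplotype distribution sums to {arr.sum()!r}, not 1")
    return arr


def background_freqs(p1: float, p2: float) -> np.ndarray:
    """Background (no-LD) haplotype distribution from allele frequencies.

    ``h~(a, b) = f(a, p1) * f(b, p2)`` with ``f(1, p) = p`` and
    ``f(0, p) = 1 - p``: the joint distribution of two alleles drawn from
    unrelated chromosomes.
    """
    if not (0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0):
        raise ValueError("allele frequencies must lie in [0, 1]")
    f1 = np.array([1.0 - p1, p1])
    f2 = np.array([1.0 - p2, p2])
    return np.outer(f1, f2).ravel()


# ---------------------------------------------------------------------------
# EM for two-locus haplotype frequencies from unphased diploid counts
# ---------------------------------------------------------------------------

def _em_many(c, init=None, tol: float = 1e-3, max_iter: int = 2000):
    """Vectorised EM over a batch of 3x3 diploid count tables.

    Parameters
    ----------
    c : array (n, 3, 3)
        Non-negative diploid dosage counts, one table per SNP pair.
    init : array (4,) or (n, 4), optional
        Starting haplotype distribution (default uniform 0.25).
    tol : float
        Convergence threshold on the sum of squared elementwise change of
        ``h`` between successive iterations.

    Returns
    -------
    h : array (n, 4)
    n_iter : array (n,) of int
    """
    c = np.asarray(c, dtype=float)
    if c.ndim == 2:
        c = c[None]
    n = c.shape[0]
    totals = c.sum(axis=(1, 2))
    if np.any(totals == 0):
        raise ValueError("empty count table")
    if tol <= 0:
        raise ValueError("tol must be positive")

    if init is None:
        h = np.full((n, 4), 0.25)
    else:
        init = np.asarray(init, dtype=float)
        h = np.broadcast_to(init, (n, 4)).copy()

    n_iter = np.zeros(n, dtype=int)
    active = np.arange(n)
    floored = False
    for _ in range(max_iter):
        ha = h[active]
        ca = c[active]
        P = np.zeros((len(active), 3, 3))
        for t1, t2, i, j in _ORDERED_PAIRS:
            P[:, i, j] += ha[:, t1] * ha[:, t2]
        if np.any((P <= 0) & (ca > 0)):
            floored = True
        Pf = np.maximum(P, _PROB_FLOOR)
        D = np.zeros((len(active), 4))
        for t1, t2, i, j in _ORDERED_PAIRS:
            w = ca[:, i, j] * ha[:, t1] * ha[:, t2] / Pf[:, i, j]
            D[:, t1] += w
            D[:, t2] += w
        hn = D / D.sum(axis=1, keepdims=True)
        delta = ((hn - ha) ** 2).sum(axis=1)
        h[active] = hn
        n_iter[active] += 1
        still = delta >= tol
        active = active[still]
        if active.size == 0:
            break
    if floored:
        warnings.warn("EM encountered a zero-probability cell with observations; "
                      "probability floored at 1e-300", RuntimeWarning)
    return h, n_iter


def _loglik_tables(c, h):
    """Observed-data log-likelihood sum_ij c[i,j] log P(i,j|h) per table."""
    c = np.asarray(c, dtype=float)
    if c.ndim == 2:
        c = c[None]
    h = np.atleast_2d(h)
    P = np.zeros((c.shape[0], 3, 3))
    for t1, t2, i, j in _ORDERED_PAIRS:
        P[:, i, j] += h[:, t1] * h[:, t2]
    return (c * np.log(np.maximum(P, _PROB_FLOOR))).sum(axis=(1, 2))


def em_haplotype_freqs(c, init=None, tol: float = 1e-3, max_iter: int = 2000,
                       return_trajectory: bool = False):
    """Two-locus haplotype frequencies from an unphased 3x3 count table.

    The latent variable is which parental chromosome contributed which
    gamete; every dosage cell except the double heterozygote (1, 1)
    resolves to unambiguous gametes, so with ``c[1][1] == 0`` the result
    equals direct gamete counting.  The observed-data log-likelihood is
    non-decreasing across iterations (an EM guarantee; exposed through
    ``return_trajectory`` for verification).

    Parameters
    ----------
    c : array (3, 3)
        Diploid dosage counts ``c[i, j]``.
    init : array (4,), optional
        Initial distribution, default uniform 0.25.
    tol : float
        Threshold on the squared distance between successive ``h``.
    return_trajectory : bool
        If true, also return the list of per-iteration log-likelihoods.

    Returns
    -------
    h : array (4,), or (h, logliks) if ``return_trajectory``.
    """
    c = np.asarray(c, dtype=float)
    if c.shape != (3, 3):
        raise ValueError("diploid pair counts must be a 3x3 table")
    if np.any(c < 0):
        raise ValueError("diploid pair counts must be non-negative")
    unambiguous = c.sum() - c[1, 1]
    if c[1, 1] > 0 and unambiguous == 0:
        # uniform init is a fixed point: report it deterministically
        warnings.warn("degenerate EM: only double-heterozygote counts observed; "
                      "haplotype phase is unidentifiable", RuntimeWarning)
    if not return_trajectory:
        h, _ = _em_many(c[None], init=init, tol=tol, max_iter=max_iter)
        return h[0]
    # slow path: iterate one step at a time to record the likelihood
    h = np.full(4, 0.25) if init is None else validate_distribution(init)
    logliks = [float(_loglik_tables(c, h)[0])]
    for _ in range(max_iter):
        hn, _ = _em_many(c[None], init=h, tol=np.inf, max_iter=1)
        hn = hn[0]
        logliks.append(float(_loglik_tables(c, hn)[0]))
        delta = ((hn - h) ** 2).sum()
        h = hn
        if delta < tol:
            break
    return h, logliks


# ---------------------------------------------------------------------------
# LD pair selection
# ---------------------------------------------------------------------------

def compute_ld_pairs(genotypes, snps: pd.DataFrame, r2_cutoff: float = 0.2,
                     max_pair_distance: int = 1_000_000):
    """Same-chromosome SNP pairs with squared dosage correlation >= cutoff.

    Parameters
    ----------
    genotypes : array (n_individuals, n_snps)
        Alternative-allele dosages in {0, 1, 2}; NaN marks missing calls.
        r^2 for a pair is the squared Pearson correlation of the two dosage
        columns over individuals non-missing at both SNPs.
    snps : DataFrame
        Per-SNP metadata with at least ``chrom`` and ``pos`` columns,
        aligned to the genotype columns.
    max_pair_distance : int
        Only pairs within this many base pairs are considered (same
        chromosome always required).

    Returns
    -------
    list of ((idx1, idx2), r2) with ``pos[idx1] < pos[idx2]``; pairs with
    fewer than 2 jointly non-missing individuals or an undefined
    correlation (monomorphic SNP) are skipped.
    """
    G = np.asarray(genotypes, dtype=float)
    if G.ndim != 2 or G.shape[1] != len(snps):
        raise ValueError("genotypes must be (n_individuals, n_snps) matching the SNP table")
    chrom = np.asarray(snps["chrom"])
    pos = np.asarray(snps["pos"], dtype=np.int64)
    out = []
    n_skipped = 0
    for ch in pd.unique(chrom):
        sel = np.flatnonzero(chrom == ch)
        order = sel[np.argsort(pos[sel], kind="stable")]
        p = pos[order]
        X = G[:, order]
        V = ~np.isnan(X)
        Xz = np.where(V, X, 0.0)
        m = len(order)
        for k in range(1, m):
            gap = p[k:] - p[:-k]
            ok = gap <= max_pair_distance
            if not ok.any():
                break
            A, B = Xz[:, :-k], Xz[:, k:]
            VA, VB = V[:, :-k], V[:, k:]
            both = VA & VB
            n = both.sum(axis=0)
            Aa = np.where(both, A, 0.0)
            Bb = np.where(both, B, 0.0)
            sx = Aa.sum(axis=0)
            sy = Bb.sum(axis=0)
            sxx = (Aa * Aa).sum(axis=0)
            syy = (Bb * Bb).sum(axis=0)
            sxy = (Aa * Bb).sum(axis=0)
            cov = n * sxy - sx * sy
            vx = n * sxx - sx * sx
            vy = n * syy - sy * sy
            defined = (n >= 2) & (vx > 0) & (vy > 0)
            n_skipped += int((ok & ~defined).sum())
            with np.errstate(divide="ignore", invalid="ignore"):
                r2 = np.where(defined, cov * cov / np.where(defined, vx * vy, 1.0), np.nan)
            hit = ok & defined & (r2 >= r2_cutoff)
            for idx in np.flatnonzero(hit):
                out.append(((int(order[idx]), int(order[idx + k])), float(r2[idx])))
    if n_skipped:
        logger.info("compute_ld_pairs: skipped %d candidate pairs with undefined r^2 "
                    "(monomorphic SNP or <2 jointly non-missing individuals)", n_skipped)
    out.sort(key=lambda t: (snps["chrom"].iloc[t[0][0]], int(snps["pos"].iloc[t[0][0]]),
                            int(snps["pos"].iloc[t[0][1]])))
    return out


# ---------------------------------------------------------------------------
# Panel container
# ---------------------------------------------------------------------------

@dataclass
class HaplotypePanel:
    """Collection of LD SNP pairs with haplotype distributions.

    ``pairs`` holds one row per SNP pair with the columns of
    :data:`PANEL_COLUMNS`.  ``h_bg`` (the background distribution) and
    ``q`` are derived properties, never stored.
    """

    pairs: pd.DataFrame
    population_label: str = ""
    snp_set_label: str = ""
    r2_cutoff: float = 0.2
    maf_cutoff: float = 0.10

    def __post_init__(self):
        missing = [c for c in PANEL_COLUMNS if c not in self.pairs.columns]
        if missing:
            raise ValueError(f"panel table missing columns: {missing}")
        ch = self.pairs["chrom"].astype(int)
        if not ch.isin(AUTOSOMES).all():
            raise ValueError("panel contains non-autosomal chromosomes")
        key = self.pairs[["chrom", "pos1", "pos2"]]
        if key.duplicated().any():
            raise ValueError("panel contains duplicated SNP pairs")
        h = self.h
        if np.any(h < -1e-12) or np.any(np.abs(h.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("panel h columns are not valid distributions")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def h(self) -> np.ndarray:
        """True-haplotype distributions, shape (n_pairs, 4)."""
        return self.pairs[["h00", "h01", "h10", "h11"]].to_numpy(dtype=float)

    @property
    def h_bg(self) -> np.ndarray:
        """Background distributions p1 x p2, shape (n_pairs, 4)."""
        p1 = self.pairs["p1"].to_numpy(dtype=float)
        p2 = self.pairs["p2"].to_numpy(dtype=float)
        cols = [(1 - p1) * (1 - p2), (1 - p1) * p2, p1 * (1 - p2), p1 * p2]
        return np.stack(cols, axis=1)

    @property
    def q(self) -> np.ndarray:
        """Pseudo-haploid pair distributions h/2 + h~/2, shape (n_pairs, 4)."""
        return 0.5 * self.h + 0.5 * self.h_bg

    @property
    def chrom(self) -> np.ndarray:
        return self.pairs["chrom"].to_numpy(dtype=int)

    def snp_table(self) -> pd.DataFrame:
        """Unique SNPs appearing in any pair, with panel allele frequencies."""
        left = self.pairs[["chrom", "pos1", "ref1", "alt1", "p1"]].rename(
            columns={"pos1": "pos", "ref1": "ref", "alt1": "alt", "p1": "alt_freq"})
        right = self.pairs[["chrom", "pos2", "ref2", "alt2", "p2"]].rename(
            columns={"pos2": "pos", "ref2": "ref", "alt2": "alt", "p2": "alt_freq"})
        snps = pd.concat([left, right], ignore_index=True)
        snps = snps.drop_duplicates(subset=["chrom", "pos"]).sort_values(
            ["chrom", "pos"]).reset_index(drop=True)
        return snps

    def to_tsv(self, path) -> None:
        self.pairs[PANEL_COLUMNS].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, population_label: str = "", snp_set_label: str = "",
                 r2_cutoff: float = 0.2, maf_cutoff: float = 0.10) -> "HaplotypePanel":
        pairs = pd.read_csv(path, sep="\t")
        return cls(pairs=pairs, population_label=population_label,
                   snp_set_label=snp_set_label, r2_cutoff=r2_cutoff,
                   maf_cutoff=maf_cutoff)


# ---------------------------------------------------------------------------
# Panel construction
# ---------------------------------------------------------------------------

class PanelBuilder(BaseEstimator):
    """Build a haplotype reference panel from unphased diploid genotypes.

    Filters to autosomal SNPs with minor-allele frequency strictly above
    ``maf_cutoff``, selects same-chromosome SNP pairs within
    ``max_pair_distance`` whose squared dosage correlation is at least
    ``r2_cutoff``, and estimates per-pair haplotype distributions by EM.

    Parameters
    ----------
    maf_cutoff : float, default 0.10
        Minor-allele-frequency filter (strict inequality).
    r2_cutoff : float, default 0.2
        Squared-correlation threshold for retaining a pair.
    max_pair_distance : int, default 1_000_000
        Maximum base-pair separation of a pair.
    exclude : sequence of sample ids, default ()
        Individuals removed before any frequency or LD computation
        (e.g. a test individual also present in the reference cohort).
    em_tol : float, default 1e-8
        Per-pair EM convergence threshold (squared distance between
        iterations).  Tighter than the per-call default of
        :func:`em_haplotype_freqs`: a convergence budget of 1e-3 spread
        over an entire panel leaves each pair far tighter than 1e-3, and
        a loose per-pair threshold leaves h biased toward its uniform
        start, which systematically understates panel LD.

    Attributes
    ----------
    panel_ : HaplotypePanel
    n_snps_in_ : int
        SNPs surviving the MAF/autosome filters.
    n_pairs_ : int
    """

    def __init__(self, maf_cutoff: float = 0.10, r2_cutoff: float = 0.2,
                 max_pair_distance: int = 1_000_000, exclude=(),
                 em_tol: float = 1e-8, population_label: str = "",
                 snp_set_label: str = ""):
        self.maf_cutoff = maf_cutoff
        self.r2_cutoff = r2_cutoff
        self.max_pair_distance = max_pair_distance
        self.exclude = exclude
        self.em_tol = em_tol
        self.population_label = population_label
        self.snp_set_label = snp_set_label

    def fit(self, X, y=None, *, snps: pd.DataFrame = None, sample_ids=None):
        """Fit the panel from a dosage matrix.

        Parameters
        ----------
        X : array (n_individuals, n_snps) or DataFrame
            Dosages in {0, 1, 2}, NaN for missing.  If a DataFrame, its
            index supplies ``sample_ids``.
        snps : DataFrame
            SNP metadata: chrom, pos, ref, alt (aligned to columns of X).
        """
        if snps is None:
            raise ValueError("snps metadata table is required")
        if isinstance(X, pd.DataFrame):
            if sample_ids is None:
                sample_ids = X.index.to_numpy()
            X = X.to_numpy(dtype=float)
        G = np.asarray(X, dtype=float)
        snps = snps.reset_index(drop=True)
        if G.shape[1] != len(snps):
            raise ValueError("genotype matrix and SNP table disagree on SNP count")

        if len(self.exclude) > 0:
            if sample_ids is None:
                raise ValueError("exclude requires sample_ids")
            sample_ids = np.asarray(sample_ids)
            keep = ~np.isin(sample_ids, np.asarray(list(self.exclude)))
            G = G[keep]

        chrom = pd.to_numeric(
            pd.Series(snps["chrom"]).astype(str).str.replace("chr", "", regex=False),
            errors="coerce")
        autosomal = chrom.isin(list(AUTOSOMES)).to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            p = np.nanmean(G, axis=0) / 2.0
        maf = np.minimum(p, 1.0 - p)
        keep_snp = autosomal & np.isfinite(p) & (maf > self.maf_cutoff)
        idx_keep = np.flatnonzero(keep_snp)
        Gk = G[:, idx_keep]
        snps_k = snps.iloc[idx_keep].reset_index(drop=True)
        snps_k = snps_k.assign(chrom=chrom.to_numpy()[idx_keep].astype(int))
        pk = p[idx_keep]

        pair_list = compute_ld_pairs(Gk, snps_k, r2_cutoff=self.r2_cutoff,
                                     max_pair_distance=self.max_pair_distance)
        if not pair_list:
            raise ValueError("empty panel")
        i1 = np.array([a for (a, _), _ in pair_list], dtype=int)
        i2 = np.array([b for (_, b), _ in pair_list], dtype=int)
        r2 = np.array([r for _, r in pair_list], dtype=float)

        # 3x3 dosage count tables per pair, missing excluded pairwise
        n_pairs = len(i1)
        counts = np.zeros((n_pairs, 3, 3), dtype=float)
        chunk = 50_000
        for lo in range(0, n_pairs, chunk):
            hi = min(lo + chunk, n_pairs)
            g1 = Gk[:, i1[lo:hi]]
            g2 = Gk[:, i2[lo:hi]]
            valid = ~np.isnan(g1) & ~np.isnan(g2)
            code = (3 * np.where(valid, g1, 0) + np.where(valid, g2, 0)).astype(np.int64)
            pair_ix = np.broadcast_to(np.arange(hi - lo), g1.shape)
            flat = (pair_ix * 9 + code)[valid]
            counts[lo:hi] = np.bincount(flat, minlength=(hi - lo) * 9).reshape(hi - lo, 3, 3)

        h, _ = _em_many(counts, tol=self.em_tol)

        ref = snps_k["ref"].to_numpy() if "ref" in snps_k else np.full(len(snps_k), "N")
        alt = snps_k["alt"].to_numpy() if "alt" in snps_k else np.full(len(snps_k), "N")
        pairs = pd.DataFrame({
            "chrom": snps_k["chrom"].to_numpy()[i1],
            "pos1": snps_k["pos"].to_numpy()[i1],
            "ref1": ref[i1], "alt1": alt[i1],
            "pos2": snps_k["pos"].to_numpy()[i2],
            "ref2": ref[i2], "alt2": alt[i2],
            "r2": r2,
            "p1": pk[i1], "p2": pk[i2],
            "h00": h[:, 0], "h01": h[:, 1], "h10": h[:, 2], "h11": h[:, 3],
        })
        self.panel_ = HaplotypePanel(
            pairs=pairs, population_label=self.population_label,
            snp_set_label=self.snp_set_label, r2_cutoff=self.r2_cutoff,
            maf_cutoff=self.maf_cutoff)
        self.n_snps_in_ = int(keep_snp.sum())
        self.n_pairs_ = n_pairs
        return self


def build_panel(genotypes, snps: pd.DataFrame, maf_cutoff: float = 0.10,
                r2_cutoff: float = 0.2, max_pair_distance: int = 1_000_000,
                exclude=(), sample_ids=None, em_tol: float = 1e-8,
                population_label: str = "", snp_set_label: str = "") -> HaplotypePanel:
    """Functional wrapper around :class:`PanelBuilder`."""
    builder = PanelBuilder(maf_cutoff=maf_cutoff, r2_cutoff=r2_cutoff,
                           max_pair_distance=max_pair_distance, exclude=exclude,
                           em_tol=em_tol, population_label=population_label,
                           snp_set_label=snp_set_label)
    builder.fit(genotypes, snps=snps, sample_ids=sample_ids)
    return builder.panel_


# ---------------------------------------------------------------------------
# Panel matching (shared-drift statistic)
# ---------------------------------------------------------------------------

def match_panel(sample_counts, panels, outgroup_freqs, min_shared: int = 1000,
                seed: int = 0):
    """Rank candidate panels by shared genetic drift with the sample.

    For each panel the statistic is the mean over shared SNPs of
    ``(x - o) * (p - o)`` where ``x`` is the sample's pseudo-haploid allele
    dosage (one sequence drawn at random per covered SNP), ``p`` the panel
    alternative-allele frequency and ``o`` the outgroup frequency -- an
    outgroup-f3-style measure of shared drift between sample and panel
    population.  The pseudo-haploid draw is made once and reused for every
    panel.

    Parameters
    ----------
    sample_counts : SiteCounts or DataFrame
        Per-SNP sequence counts for the test sample.
    panels : sequence of HaplotypePanel
    outgroup_freqs : DataFrame with chrom, pos, alt_freq columns, or dict
        mapping (chrom, pos) to the outgroup alternative-allele frequency.

    Returns
    -------
    list of (panel, statistic), sorted descending; ties broken by
    population label order.
    """
    from .counts import SiteCounts  # local import to avoid a cycle

    if isinstance(sample_counts, SiteCounts):
        sites = sample_counts.sites
    else:
        sites = pd.DataFrame(sample_counts)
    if len(panels) < 1:
        raise ValueError("at least one candidate panel is required")
    if isinstance(outgroup_freqs, dict):
        og = pd.DataFrame(
            [(c, p, f) for (c, p), f in outgroup_freqs.items()],
            columns=["chrom", "pos", "alt_freq"])
    else:
        og = pd.DataFrame(outgroup_freqs)

    tot_ref = sites["nref_und"] + sites["nref_dam"]
    tot_alt = sites["nalt_und"] + sites["nalt_dam"]
    covered = (tot_ref + tot_alt) > 0
    sample = sites.loc[covered, ["chrom", "pos"]].copy()
    rng = np.random.default_rng(seed)
    p_alt = (tot_alt / (tot_ref + tot_alt))[covered].to_numpy(dtype=float)
    sample["x"] = (rng.random(len(sample)) < p_alt).astype(float)

    merged_og = sample.merge(og, on=["chrom", "pos"], how="inner")
    scored = []
    for panel in panels:
        snps = panel.snp_table()[["chrom", "pos", "alt_freq"]]
        m = merged_og.merge(snps, on=["chrom", "pos"], how="inner")
        if len(m) < min_shared:
            raise ValueError("insufficient overlap for panel matching")
        stat = float(np.mean((m["x"] - m["alt_freq_x"]) * (m["alt_freq_y"] - m["alt_freq_x"])))
        scored.append((panel, stat))
    scored.sort(key=lambda t: (-t[1], t[0].population_label))
    return scored
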