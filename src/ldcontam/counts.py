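"""Per-SNP sequence counts with damage status, and per-pair observations.

The canonical sample input is a tab-separated count table with one row per
SNP giving the number of sequences carrying the reference and alternative
allele, split by damage status (damaged = carrying the C-to-T / G-to-A
deamination signature of authentic ancient DNA, as called by an upstream
tool such as a PMD-score filter).  Coordinates are 1-based and sites are
keyed by (chrom, pos, ref, alt).

For the estimator, sequences at the two SNPs of every panel pair are
cross-classified: each combination of one sequence at SNP1 with one
sequence at SNP2 contributes one observation to the haplotype
configuration (a, b) of damage class UU (both undamaged), DU (exactly one
damaged, either order) or DD (both damaged).  All sequences are used and
treated as independent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import HaplotypePanel

logger = logging.getLogger(__name__)

COUNT_COLUMNS = ["chrom", "pos", "ref", "alt",
                 "nref_und", "nalt_und", "nref_dam", "nalt_dam"]
_COUNT_FIELDS = COUNT_COLUMNS[4:]

CLASSES = ("UU", "DU", "DD")


@dataclass
class SiteCounts:
    """Validated per-SNP sequence counts.

    ``sites`` has the columns of :data:`COUNT_COLUMNS`; all four count
    fields are non-negative integers.  A SNP with all-zero counts is
    treated as uncovered.
    """

    sites: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in COUNT_COLUMNS if c not in self.sites.columns]
        if missing:
            raise ValueError(f"count table missing column: {missing[0]}")
        if self.sites.duplicated(subset=["chrom", "pos"]).any():
            raise ValueError("duplicate chrom+pos in count table")
        for c in _COUNT_FIELDS:
            if (self.sites[c] < 0).any():
                raise ValueError(f"negative counts in column {c}")
        self.sites = self.sites.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def depth_undamaged(self) -> np.ndarray:
        return (self.sites["nref_und"] + self.sites["nalt_und"]).to_numpy()

    @property
    def depth_damaged(self) -> np.ndarray:
        return (self.sites["nref_dam"] + self.sites["nalt_dam"]).to_numpy()

    @property
    def depth_total(self) -> np.ndarray:
        return self.depth_undamaged + self.depth_damaged

    def write(self, path) -> None:
        self.sites[COUNT_COLUMNS].to_csv(path, sep="\t", index=False)


def load_counts(path) -> SiteCounts:
    """Read and validate a tab-separated count table.

    Rows failing integer or allele validation are rejected with a
    ValueError naming the offending (1-based, header-inclusive) line.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in COUNT_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"count table missing column: {col}")
    if len(df) == 0:
        warnings.warn("count table is empty", RuntimeWarning)
        empty = pd.DataFrame({c: pd.Series(dtype=(int if c in _COUNT_FIELDS or c == "pos"
                                                  else object)) for c in COUNT_COLUMNS})
        return SiteCounts(empty.assign(chrom=pd.Series(dtype=int)))
    out = pd.DataFrame()
    for col in ["chrom", "pos"] + _COUNT_FIELDS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != vals.astype("Int64").astype(float))
        if col in _COUNT_FIELDS:
            bad |= vals < 0
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise ValueError(f"invalid value in column {col!r} at line {line}")
        out[col] = vals.astype(int)
    for col in ("ref", "alt"):
        vals = df[col].astype(str).str.upper()
        bad = ~vals.isin(list("ACGT"))
        if bad.any():
            line = int(bad.idxmax()) + 2
            raise ValueError(f"invalid allele in column {col!r} at line {line}")
        out[col] = vals
    return SiteCounts(out[COUNT_COLUMNS])


def write_counts(counts: SiteCounts, path) -> None:
    counts.write(path)


@dataclass
class PairObservations:
    """Cross-classified sequence-pair counts for covered panel pairs.

    Arrays are aligned: row ``k`` refers to panel pair ``pair_index[k]``.
    ``uu``/``du``/``dd`` hold counts over the four haplotype
    configurations (00, 01, 10, 11); their row sums partition the full
    cross product ``(u1 + d1) * (u2 + d2)`` of the two SNPs' depths.
    """

    pair_index: np.ndarray      # (n_cov,) indices into panel.pairs
    chrom: np.ndarray           # (n_cov,)
    uu: np.ndarray              # (n_cov, 4)
    du: np.ndarray              # (n_cov, 4)
    dd: np.ndarray              # (n_cov, 4)
    n_pairs_skipped: int = 0
    n_sites_mismatched: int = 0

    def total(self, classes=CLASSES) -> float:
        return float(sum(getattr(self, c.lower()).sum() for c in classes))

    def class_matrix(self, cls: str) -> np.ndarray:
        return getattr(self, cls.lower())

    def pooled(self) -> np.ndarray:
        return self.uu + self.du + self.dd

    def per_chrom_totals(self) -> dict:
        """Pooled observation counts per chromosome."""
        tot = self.pooled().sum(axis=1)
        out = {}
        for ch in np.unique(self.chrom):
            out[int(ch)] = float(tot[self.chrom == ch].sum())
        return out


def _harmonize(panel: HaplotypePanel, counts: SiteCounts):
    """Align sample counts to panel SNPs by exact chrom+pos+ref+alt match.

    Returns per-SNP count arrays indexed like ``panel.snp_table()`` plus
    the number of sample sites dropped for REF/ALT mismatch.  No strand
    flipping is attempted (A/T and C/G SNPs included); mismatches are
    dropped and reported.
    """
    snps = panel.snp_table()
    merged = snps.merge(counts.sites, on=["chrom", "pos"], how="left",
                        suffixes=("", "_s"))
    have = merged["nref_und"].notna()
    match = have & (merged["ref_s"] == merged["ref"]) & (merged["alt_s"] == merged["alt"])
    n_mismatch = int((have & ~match).sum())
    arr = {}
    for c in _COUNT_FIELDS:
        v = merged[c].where(match, 0.0).fillna(0.0).to_numpy(dtype=float)
        arr[c] = v
    key = pd.MultiIndex.from_frame(snps[["chrom", "pos"]])
    lookup = pd.Series(np.arange(len(snps)), index=key)
    return snps, arr, lookup, n_mismatch


def pair_observations(panel: HaplotypePanel, counts: SiteCounts) -> PairObservations:
    """Cross-classify sequences at each panel pair into UU/DU/DD counts.

    Every combination of one sequence at SNP1 and one at SNP2 is one
    observation; with undamaged/damaged allele counts ``u1, d1`` at SNP1
    and ``u2, d2`` at SNP2 (each a length-2 vector over ref/alt), the
    class counts for configuration (a, b) are the bilinear products::

        UU[a,b] = u1[a] u2[b]
        DU[a,b] = d1[a] u2[b] + u1[a] d2[b]
        DD[a,b] = d1[a] d2[b]

    Pairs with either SNP uncovered contribute nothing (counted in
    ``n_pairs_skipped``).
    """
    snps, arr, lookup, n_mismatch = _harmonize(panel, counts)
    pairs = panel.pairs
    k1 = lookup.loc[list(zip(pairs["chrom"].astype(int), pairs["pos1"]))].to_numpy()
    k2 = lookup.loc[list(zip(pairs["chrom"].astype(int), pairs["pos2"]))].to_numpy()

    u1 = np.stack([arr["nref_und"][k1], arr["nalt_und"][k1]], axis=1)
    d1 = np.stack([arr["nref_dam"][k1], arr["nalt_dam"][k1]], axis=1)
    u2 = np.stack([arr["nref_und"][k2], arr["nalt_und"][k2]], axis=1)
    d2 = np.stack([arr["nref_dam"][k2], arr["nalt_dam"][k2]], axis=1)

    covered = ((u1 + d1).sum(axis=1) > 0) & ((u2 + d2).sum(axis=1) > 0)
    idx = np.flatnonzero(covered)
    u1, d1, u2, d2 = u1[idx], d1[idx], u2[idx], d2[idx]

    def outer(x, y):
        return np.einsum("ka,kb->kab", x, y).reshape(len(idx), 4)

    uu = outer(u1, u2)
    du = outer(d1, u2) + outer(u1, d2)
    dd = outer(d1, d2)
    return PairObservations(
        pair_index=idx,
        chrom=pairs["chrom"].to_numpy(dtype=int)[idx],
        uu=uu, du=du, dd=dd,
        n_pairs_skipped=int(len(pairs) - covered.sum()),
        n_sites_mismatched=n_mismatch,
    )


def subsample_pair_observations(obs: PairObservations, cap: int,
                                seed: int = 0) -> PairObservations:
    """Randomly cap the number of observations per pair (memory control).

    Draws without replacement from each pair's 12-cell count vector when
    its total exceeds ``cap``.  Provided for very deep data; the default
    pipeline applies no cap.
    """
    rng = np.random.default_rng(seed)
    mats = [obs.uu.copy(), obs.du.copy(), obs.dd.copy()]
    tot = obs.pooled().sum(axis=1)
    for k in np.flatnonzero(tot > cap):
        flat = np.concatenate([m[k] for m in mats]).astype(np.int64)
        drawn = rng.multivariate_hypergeometric(flat, cap)
        mats[0][k], mats[1][k], mats[2][k] = drawn[:4], drawn[4:8], drawn[8:]
    return PairObservations(pair_index=obs.pair_index, chrom=obs.chrom,
                            uu=mats[0], du=mats[1], dd=mats[2],
                            n_pairs_skipped=obs.n_pairs_skipped,
                            n_sites_mismatched=obs.n_sites_mismatched)


@dataclass
class DamageSummary:
    """Damage rate over sequences at panel SNPs."""

    d: float
    n_total: int
    n_damaged: int
    per_chrom: dict = field(default_factory=dict)  # chrom -> (n_total, n_damaged)

    def d_excluding(self, chrom: int) -> float:
        """Damage rate with one chromosome removed (for the jackknife)."""
        nt, nd = self.per_chrom.get(int(chrom), (0, 0))
        rest_t = self.n_total - nt
        rest_d = self.n_damaged - nd
        return rest_d / rest_t if rest_t > 0 else 0.0


def damage_summary(counts: SiteCounts, panel: HaplotypePanel) -> DamageSummary:
    """Fraction of damaged sequences over SNPs appearing in >= 1 panel pair."""
    snps = panel.snp_table()
    merged = snps.merge(counts.sites, on=["chrom", "pos"], how="inner")
    match = (merged["ref_x"] == merged["ref_y"]) & (merged["alt_x"] == merged["alt_y"])
    merged = merged[match]
    n_dam = merged["nref_dam"] + merged["nalt_dam"]
    n_und = merged["nref_und"] + merged["nalt_und"]
    n_tot = n_dam + n_und
    total = int(n_tot.sum())
    if total == 0:
        raise ValueError("no coverage on panel SNPs")
    per_chrom = {}
    for ch, grp in merged.groupby("chrom"):
        per_chrom[int(ch)] = (int((grp["nref_dam"] + grp["nalt_dam"]
                                   + grp["nref_und"] + grp["nalt_und"]).sum()),
                              int((grp["nref_dam"] + grp["nalt_dam"]).sum()))
    damaged = int(n_dam.sum())
    return DamageSummary(d=damaged / total, n_total=total, n_damaged=damaged,
                         per_chrom=per_chrom)


# ---------------------------------------------------------------------------
# Pileup reader (convenience plumbing)
# ---------------------------------------------------------------------------

def counts_from_alignments(alignments_path, snps: pd.DataFrame,
                           damage_mode: str = "flag", damage_tag: str = "XD",
                           terminal_bases: int = 3, fasta: str = None,
                           min_base_quality: int = 20,
                           min_mapping_quality: int = 20) -> SiteCounts:
    """Pull per-SNP allele counts from a SAM/BAM/CRAM file.

    This is convenience plumbing around :mod:`pysam`; calling PMD-style
    damage scores is an upstream responsibility.  Two damage modes:

    ``flag``
        A sequence is damaged iff it carries integer aux tag
        ``damage_tag`` (default ``XD``) with a nonzero value.
    ``terminal-ct``
        Heuristic: a sequence is damaged iff it shows a C-to-T mismatch
        to the reference within ``terminal_bases`` of either read end
        (G-to-A on reverse-strand alignments).  Requires MD tags or a
        reference FASTA.

    Only positions present in ``snps`` (chrom, pos, ref, alt; 1-based)
    are pulled down; other sites are ignored.
    """
    import pysam

    if damage_mode not in ("flag", "terminal-ct"):
        raise ValueError("damage_mode must be 'flag' or 'terminal-ct'")
    mode = "r" if str(alignments_path).endswith(".sam") else "rb"
    snps = snps.reset_index(drop=True)
    lookup = {(str(c).replace("chr", ""), int(p) - 1): k
              for k, (c, p) in enumerate(zip(snps["chrom"], snps["pos"]))}
    tallies = np.zeros((len(snps), 4), dtype=np.int64)  # ru, au, rd, ad
    with pysam.AlignmentFile(alignments_path, mode) as af:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_duplicate:
                continue
            if read.mapping_quality < min_mapping_quality:
                continue
            chrom = read.reference_name.replace("chr", "")
            damaged = None
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                k = lookup.get((chrom, rpos))
                if k is None:
                    continue
                if read.query_qualities is not None and \
                        read.query_qualities[qpos] < min_base_quality:
                    continue
                base = read.query_sequence[qpos].upper()
                if base == snps["ref"].iloc[k]:
                    allele = 0
                elif base == snps["alt"].iloc[k]:
                    allele = 1
                else:
                    continue
                if damaged is None:
                    if damage_mode == "flag":
                        damaged = bool(read.has_tag(damage_tag)
                                       and read.get_tag(damage_tag))
                    else:
                        damaged = _has_terminal_ct(read, terminal_bases)
                tallies[k, 2 * damaged + allele] += 1
    df = snps[["chrom", "pos", "ref", "alt"]].copy()
    df["nref_und"] = tallies[:, 0]
    df["nalt_und"] = tallies[:, 1]
    df["nref_dam"] = tallies[:, 2]
    df["nalt_dam"] = tallies[:, 3]
    if df["chrom"].dtype == object:
        try:
            df["chrom"] = df["chrom"].astype(str).str.replace(
                "chr", "", regex=False).astype(int)
        except ValueError:
            pass
    return SiteCounts(df.reset_index(drop=True))


def _has_terminal_ct(read, k: int) -> bool:
    """C-to-T mismatch within k bases of a read end (strand-aware)."""
    try:
        pairs = read.get_aligned_pairs(matches_only=True, with_seq=True)
    except ValueError:  # no MD tag
        raise ValueError("terminal-ct damage calling requires MD tags "
                         "(run samtools calmd) or a reference FASTA")
    n = read.query_length
    for q, _, refbase in pairs:
        if refbase is None:
            continue
        if q >= k and q < n - k:
            continue
        qbase = read.query_sequence[q].upper()
        refbase = refbase.upper()
        if read.is_reverse:
            if refbase == "G" and qbase == "A":
                return True
        else:
            if refbase == "C" and qbase == "T":
                return True
    return False
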