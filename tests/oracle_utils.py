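"""Independent brute-force oracles used by the test suite.

Everything here is written directly from the model definitions and never
calls into :mod:`ldcontam` internals, so it can serve as an independent
check of the package's EM, likelihood and panel code.
"""

import itertools

import numpy as np
import pandas as pd


def diploid_cell_probs(h):
    """P(i, j | h) by explicit enumeration of ordered parental gametes."""
    h = np.asarray(h, dtype=float).reshape(2, 2)  # h[a, b]
    P = np.zeros((3, 3))
    for a1, b1, a2, b2 in itertools.product((0, 1), repeat=4):
        P[a1 + a2, b1 + b2] += h[a1, b1] * h[a2, b2]
    return P


def table_loglik(c, h):
    """sum_ij c[i,j] log P(i,j|h), brute force."""
    P = diploid_cell_probs(h)
    with np.errstate(divide="ignore", invalid="ignore"):
        logP = np.where(P > 0, np.log(np.maximum(P, 1e-300)), -1e308)
    mask = np.asarray(c) > 0
    return float(np.sum(np.asarray(c)[mask] * logP[mask]))


def simplex_grid_argmax(c, resolution):
    """Maximiser of the table likelihood over the 3-simplex grid.

    Enumerates all h = (i, j, k, n-i-j-k) / n with n = 1/resolution,
    evaluating the likelihood vectorised in chunks.
    """
    n = int(round(1.0 / resolution))
    c = np.asarray(c, dtype=float)
    best_ll, best_h = -np.inf, None
    jk = np.array([(j, k) for j in range(n + 1) for k in range(n + 1 - j)])
    for i in range(n + 1):
        sel = jk[jk.sum(axis=1) <= n - i]
        if len(sel) == 0:
            continue
        h = np.empty((len(sel), 4))
        h[:, 0] = i / n
        h[:, 1] = sel[:, 0] / n
        h[:, 2] = sel[:, 1] / n
        h[:, 3] = (n - i - sel.sum(axis=1)) / n
        # vectorised enumeration of P(i,j|h)
        P = np.zeros((len(sel), 3, 3))
        for a1, b1, a2, b2 in itertools.product((0, 1), repeat=4):
            P[:, a1 + a2, b1 + b2] += h[:, 2 * a1 + b1] * h[:, 2 * a2 + b2]
        ll = np.sum(np.where(c > 0, c * np.log(np.maximum(P, 1e-300)), 0.0),
                    axis=(1, 2))
        k = int(np.argmax(ll))
        if ll[k] > best_ll:
            best_ll, best_h = float(ll[k]), h[k].copy()
    return best_h, best_ll


def gamete_count_freqs(c):
    """Direct gamete counting; exact MLE when c[1][1] == 0.

    Cell (i, j) with (i, j) != (1, 1) decomposes into unambiguous
    gametes: dosage 0 -> two reference alleles, 1 -> one of each,
    2 -> two alternative alleles.
    """
    c = np.asarray(c, dtype=float)
    assert c[1, 1] == 0
    D = np.zeros(4)
    for i in range(3):
        for j in range(3):
            if c[i, j] == 0:
                continue
            a_alleles = {0: (0, 0), 1: (0, 1), 2: (1, 1)}[i]
            b_alleles = {0: (0, 0), 1: (0, 1), 2: (1, 1)}[j]
            # the two gametes pair the k-th allele at each SNP (order
            # within a heterozygote is arbitrary but consistent: each
            # pairing appears once, matching phase-known decomposition
            # except the double heterozygote, which is excluded)
            for k in range(2):
                D[2 * a_alleles[k] + b_alleles[k]] += c[i, j]
    return D / D.sum()


def mixture_T(q, h_bg, alpha):
    """The two-component contamination mixture, written out directly."""
    return ((1 - 2 * alpha + 2 * alpha ** 2) * np.asarray(q)
            + 2 * alpha * (1 - alpha) * np.asarray(h_bg))


def random_consistent_panel(n_pairs, seed, n_chrom=22):
    """A synthetic panel table with self-consistent (h, p1, p2).

    h is Dirichlet with a boost on the diagonal (so pairs carry LD);
    allele frequencies are the marginals of h, making q = h/2 + h~/2
    hold by construction.  Returns a pandas DataFrame in the panel
    interchange layout.
    """
    rng = np.random.default_rng(seed)
    h = rng.dirichlet((2.0, 0.5, 0.5, 2.0), size=n_pairs)
    p1 = h[:, 2] + h[:, 3]
    p2 = h[:, 1] + h[:, 3]
    chrom = (np.arange(n_pairs) % n_chrom) + 1
    pos1 = 1000 * (np.arange(n_pairs) + 1)
    return pd.DataFrame({
        "chrom": chrom, "pos1": pos1, "ref1": "A", "alt1": "G",
        "pos2": pos1 + 100, "ref2": "C", "alt2": "T",
        "r2": 0.5, "p1": p1, "p2": p2,
        "h00": h[:, 0], "h01": h[:, 1], "h10": h[:, 2], "h11": h[:, 3],
    })


def expected_pair_observations(panel, alpha_uu, alpha_du=None, alpha_dd=None,
                               n_per_pair=100.0):
    """Noise-free PairObservations: expected counts N * T(alpha) per class.

    With ``alpha_du``/``alpha_dd`` omitted the DU and DD classes are
    empty (pooled-scan inputs).
    """
    from ldcontam.counts import PairObservations

    n = len(panel.pairs)
    h, hbg = panel.h, panel.h_bg
    q = 0.5 * h + 0.5 * hbg

    def tmat(a):
        return n_per_pair * ((1 - 2 * a + 2 * a * a) * q + 2 * a * (1 - a) * hbg)

    zero = np.zeros((n, 4))
    return PairObservations(
        pair_index=np.arange(n),
        chrom=panel.pairs["chrom"].to_numpy(dtype=int),
        uu=tmat(alpha_uu),
        du=tmat(alpha_du) if alpha_du is not None else zero.copy(),
        dd=tmat(alpha_dd) if alpha_dd is not None else zero.copy(),
    )
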