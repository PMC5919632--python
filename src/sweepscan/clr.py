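"""Composite likelihood ratio test for completed selective sweeps.

The test contrasts, at each 10 kb grid point, the derived-allele counts of
nearby SNPs under two models: the genome-wide background site frequency
spectrum, and a sweep-deformed spectrum in the star-like approximation.
A lineage at distance ``d`` from the sweep escapes the sweep via
recombination with probability

    p_e(d) = 1 - exp(-alpha * d)

where ``alpha >= 0`` is the sweep intensity per bp.  The number of escaping
lineages is Binomial(n, p_e); the escapees plus one founder lineage are a
hypergeometric subsample of the background spectrum, and the founder's
allele is copied into the n - e swept lineages.  The composite likelihood
is maximized over ``alpha`` on a log lattice with golden-section
refinement;

    CLR(g) = 2 [ max_alpha sum_i ln P(k_i | alpha, d_i) - sum_i ln phi(k_i) ]

is non-negative by construction because the alpha -> infinity limit
recovers the background.

Array data carry no invariant sites, so counts 0 and n are excluded from
the background; the sweep model can generate them, and the likelihood of
an observed (polymorphic) site uses the model vector renormalized over
1..n-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from scipy.special import gammaln

from .types import VariantTable, window_index

__all__ = [
    "BackgroundSFS",
    "background_sfs",
    "sweep_spectrum",
    "SweepLikelihoodTable",
    "clr_at_grid",
    "clr_scan",
]

#: default flanking span (bp, each side) of sites contributing to a grid point
FLANK = 100_000
#: alpha lattice size; endpoints chosen so that p_e at 10 kb spans 0.001..0.999
N_ALPHA = 64


@dataclass
class BackgroundSFS:
    """Genome-wide spectrum: phi[k-1] = P(derived count = k), k = 1..n-1."""

    n: int
    phi: np.ndarray

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.size != self.n - 1:
            raise ValueError("phi must have length n - 1")
        if not np.isclose(self.phi.sum(), 1.0):
            raise ValueError("phi must sum to 1")


def background_sfs(hm: np.ndarray) -> BackgroundSFS:
    """Empirical unfolded spectrum of the polymorphic sites of *hm*."""
    n = hm.shape[0]
    counts = hm.sum(axis=0)
    poly = (counts > 0) & (counts < n)
    if not poly.any():
        raise ValueError("no polymorphic sites")
    hist = np.bincount(counts[poly], minlength=n)[1:n]
    return BackgroundSFS(n=n, phi=hist / hist.sum())


def fold(bg: BackgroundSFS) -> BackgroundSFS:
    """Folded copy of the spectrum (minor-allele counts), for use when the
    ancestral coding is distrusted; stored on the same 1..n-1 support."""
    n = bg.n
    phi = bg.phi.copy()
    folded = phi + phi[::-1]
    half = (n - 1) // 2
    out = np.zeros_like(phi)
    out[:half] = folded[:half]
    if (n - 1) % 2:
        out[half] = phi[half]
    return BackgroundSFS(n=n, phi=out / out.sum())


def _escape_kernel(bg: BackgroundSFS) -> np.ndarray:
    """Q[e, k]: distribution of the post-sweep derived count (k = 0..n) given
    e escaping lineages, marginalized over the background spectrum."""
    n = bg.n
    ks = np.arange(1, n)
    Q = np.zeros((n + 1, n + 1))
    for e in range(n):
        size = e + 1
        m = np.arange(0, size + 1)
        # P(m derived in a subsample of size e+1 | site count k) summed over phi
        pm = hypergeom.pmf(m[:, None], n, ks[None, :], size) @ bg.phi
        founder_derived = m / size
        for mi, pmi in zip(m, pm):
            if pmi == 0.0:
                continue
            Q[e, (mi - 1) + (n - e)] += pmi * founder_derived[mi]
            Q[e, mi] += pmi * (1.0 - founder_derived[mi])
    Q[n, 1:n] = bg.phi  # every lineage escapes: background unchanged
    return Q


def sweep_spectrum(bg: BackgroundSFS, alpha: float, d: float) -> np.ndarray:
    """Probability vector over derived counts 0..n under the sweep model."""
    if alpha < 0 or d < 0:
        raise ValueError("alpha and d must be non-negative")
    n = bg.n
    pe = -np.expm1(-alpha * d)
    e = np.arange(n + 1)
    logw = (
        gammaln(n + 1) - gammaln(e + 1) - gammaln(n - e + 1)
        + np.where(e > 0, e * np.log(max(pe, 1e-300)), 0.0)
        + np.where(e < n, (n - e) * np.log(max(1.0 - pe, 1e-300)), 0.0)
    )
    if pe == 0.0:
        w = np.zeros(n + 1)
        w[0] = 1.0
    elif pe == 1.0:
        w = np.zeros(n + 1)
        w[n] = 1.0
    else:
        w = np.exp(logw)
    return w @ _escape_kernel(bg)


@dataclass
class SweepLikelihoodTable:
    """Tabulated per-count log-likelihood as a function of escape probability.

    ``loglik[r, k-1]`` is ``ln P(count = k | p_e = pe_grid[r])`` with the
    model renormalized over the polymorphic counts 1..n-1.
    """

    bg: BackgroundSFS
    pe_grid: np.ndarray
    loglik: np.ndarray

    @classmethod
    def build(cls, bg: BackgroundSFS, n_grid: int = 2048) -> "SweepLikelihoodTable":
        n = bg.n
        Q = _escape_kernel(bg)
        # dense near both endpoints where the model changes fastest
        t = np.linspace(0.0, 1.0, n_grid)
        pe = 0.5 * (1.0 - np.cos(np.pi * t))  # Chebyshev-like spacing in [0,1]
        e = np.arange(n + 1)
        logc = gammaln(n + 1) - gammaln(e + 1) - gammaln(n - e + 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            logw = (logc[None, :]
                    + e[None, :] * np.log(pe[:, None])
                    + (n - e)[None, :] * np.log1p(-pe[:, None]))
        logw[pe == 0.0] = -np.inf
        logw[pe == 0.0, 0] = 0.0
        logw[pe == 1.0] = -np.inf
        logw[pe == 1.0, n] = 0.0
        probs = np.exp(logw) @ Q  # (n_grid, n+1)
        poly = probs[:, 1:n]
        norm = poly.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = np.log(np.where(norm > 0, poly / norm, 0.0))
        ll[~np.isfinite(ll)] = -745.0  # ln of smallest positive double
        return cls(bg=bg, pe_grid=pe, loglik=ll)

    def loglik_at(self, pe: np.ndarray, k: np.ndarray) -> np.ndarray:
        """Linear interpolation of ln P(k | pe); *pe* broadcast against *k*."""
        pe = np.asarray(pe, dtype=float)
        idx = np.clip(np.searchsorted(self.pe_grid, pe) - 1, 0, self.pe_grid.size - 2)
        x0 = self.pe_grid[idx]
        x1 = self.pe_grid[idx + 1]
        frac = np.where(x1 > x0, (pe - x0) / (x1 - x0), 0.0)
        col = np.asarray(k) - 1
        y0 = self.loglik[idx, col]
        y1 = self.loglik[idx + 1, col]
        return y0 + frac * (y1 - y0)


def default_alpha_grid(n_alpha: int = N_ALPHA, scale_bp: float = 10_000.0) -> np.ndarray:
    """Log-spaced alpha lattice spanning p_e(scale_bp) from 0.001 to 0.999."""
    a_lo = -np.log1p(-0.001) / scale_bp
    a_hi = -np.log1p(-0.999) / scale_bp
    return np.geomspace(a_lo, a_hi, n_alpha)


def _composite_loglik(table: SweepLikelihoodTable, alpha: float,
                      d: np.ndarray, k: np.ndarray) -> float:
    pe = -np.expm1(-alpha * d)
    return float(table.loglik_at(pe, k).sum())


def clr_at_grid(table: SweepLikelihoodTable, distances: np.ndarray,
                counts: np.ndarray, alpha_grid: np.ndarray | None = None,
                refine: bool = True):
    """(CLR, alpha_hat) at one grid point from site distances and derived counts.

    Maximizes the composite log-likelihood over the alpha lattice, optionally
    refined by golden-section search on log(alpha); ties resolve toward the
    smaller alpha.  CLR is clipped at 0 (the alpha -> infinity limit is the
    background model).
    """
    if alpha_grid is None:
        alpha_grid = default_alpha_grid()
    d = np.asarray(distances, dtype=float)
    k = np.asarray(counts, dtype=np.int64)
    if d.size == 0:
        return None
    ll0 = float(np.log(table.bg.phi[k - 1]).sum())
    lls = np.array([_composite_loglik(table, a, d, k) for a in alpha_grid])
    best = int(np.argmax(lls))  # argmax takes the first (smallest alpha) on ties
    best_ll, best_alpha = lls[best], alpha_grid[best]
    if refine and 0 < best < alpha_grid.size - 1:
        gr = (np.sqrt(5.0) - 1.0) / 2.0
        lo, hi = np.log(alpha_grid[best - 1]), np.log(alpha_grid[best + 1])
        x1 = hi - gr * (hi - lo)
        x2 = lo + gr * (hi - lo)
        f1 = _composite_loglik(table, np.exp(x1), d, k)
        f2 = _composite_loglik(table, np.exp(x2), d, k)
        for _ in range(24):
            if f1 >= f2:  # prefer the left (smaller alpha) branch on ties
                hi, x2, f2 = x2, x1, f1
                x1 = hi - gr * (hi - lo)
                f1 = _composite_loglik(table, np.exp(x1), d, k)
            else:
                lo, x1, f1 = x1, x2, f2
                x2 = lo + gr * (hi - lo)
                f2 = _composite_loglik(table, np.exp(x2), d, k)
        x_best = x1 if f1 >= f2 else x2
        f_best = max(f1, f2)
        if f_best > best_ll:
            best_ll, best_alpha = f_best, np.exp(x_best)
    clr = max(2.0 * (best_ll - ll0), 0.0)
    return clr, float(best_alpha)


def clr_scan(hm: np.ndarray, vt: VariantTable, grid: int = 10_000,
             flank: int = FLANK, bg: BackgroundSFS | None = None,
             folded: bool = False, alpha_grid: np.ndarray | None = None,
             counts: np.ndarray | None = None, refine: bool = True,
             table: SweepLikelihoodTable | None = None) -> pd.DataFrame:
    """CLR at every 10 kb window midpoint; returns a window track.

    Columns: ``chrom, start, end, grid_pos, n_snps, alpha_hat, value``.
    Grid points with no site within *flank* carry no row.  *counts* may
    supply externally permuted derived counts (same length as *vt*).
    """
    if table is not None:
        bg = table.bg
    else:
        if bg is None:
            bg = background_sfs(hm)
        if folded:
            bg = fold(bg)
        table = SweepLikelihoodTable.build(bg)
    if counts is None:
        counts = hm.sum(axis=0)
    counts = np.asarray(counts, dtype=np.int64)
    n = bg.n
    rows = []
    for c in vt.chromosomes():
        sl = vt.chrom_slice(c)
        pos = vt.pos[sl]
        kc = counts[sl]
        poly = (kc > 0) & (kc < n)
        pos, kc = pos[poly], kc[poly]
        if pos.size == 0:
            continue
        last_win = int(window_index(pos[-1:], grid)[0])
        for w in range(last_win + 1):
            g = w * grid + grid // 2  # midpoint, 1-based convention
            lo = np.searchsorted(pos, g - flank)
            hi = np.searchsorted(pos, g + flank, side="right")
            if hi <= lo:
                continue
            d = np.abs(pos[lo:hi].astype(float) - g)
            res = clr_at_grid(table, d, kc[lo:hi], alpha_grid, refine=refine)
            if res is None:
                continue
            clr, alpha_hat = res
            rows.append((c, w * grid, (w + 1) * grid, g, hi - lo, alpha_hat, clr))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "grid_pos",
                                       "n_snps", "alpha_hat", "value"])
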