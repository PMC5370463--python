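"""Per-window population-genetic statistics.

Computes, on non-overlapping genomic windows (default 5 kb):

* nucleotide diversity π per population (unbiased per-site estimator),
* absolute divergence d_XY per population pair,
* Patterson's D from frequency-weighted ABBA/BABA sums, and
* the dynamic admixture-proportion estimator f_d, whose denominator is
  recomputed per site with the donor role P_D chosen as whichever of
  {P2, P3} carries the higher derived-allele frequency, which bounds the
  estimate at 1.

Frequency weighting generalizes the binary ABBA/BABA counts: with all
populations fixed at a site the weights reduce to 0/1 pattern counts.

Accessible length
-----------------
π and d_XY are per accessible site.  Upstream filtering keeps only positions
covered in every accession, so positions absent from the variant matrix are
treated as covered and monomorphic: the default accessible length of a
window is its span minus the sites unusable for the statistic at hand
(``accessible="span"``); ``accessible="variant"`` normalizes by the usable
variant-site count only.  π and d_XY are invariant under allele
relabelling and therefore use unpolarized frequencies over every site with
enough calls (π needs ≥ 2 allele calls in the population, d_XY ≥ 1 in
each); D and f_d use only sites with an unambiguous outgroup-derived
polarization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, PolarizedFrequencies, PopulationAssignment, polarize

logger = logging.getLogger("triadscan")

DEFAULT_WIDTH = 5_000
DEFAULT_MIN_SNPS = 10

ROLE_ORDER = ("P1", "P2", "P3", "O")
PAIRS = (("P1", "P2"), ("P1", "P3"), ("P2", "P3"),
         ("P1", "O"), ("P2", "O"), ("P3", "O"))


@dataclass(frozen=True)
class Window:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    @property
    def span(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# single-window operations
# ---------------------------------------------------------------------------

def _window_mask(freqs: PolarizedFrequencies, w: Window) -> np.ndarray:
    return (freqs.chrom == w.chrom) & (freqs.pos >= w.start) & (freqs.pos < w.end)


def _length(span: int, usable_in_window: np.ndarray, n_in_window: int,
            accessible: str) -> int:
    """Accessible length: window span minus unusable sites, or the usable
    variant-site count."""
    n_usable = int(usable_in_window.sum())
    if accessible == "span":
        return span - (n_in_window - n_usable)
    if accessible == "variant":
        return n_usable
    raise ValueError(f"unknown accessible mode {accessible!r}")


def nucleotide_diversity(freqs: PolarizedFrequencies, w: Window, pop: str,
                         accessible: str = "span") -> float:
    """π: unbiased mean per-site heterozygosity, Σ n/(n−1)·2p(1−p) / L.

    Uses unpolarized allele frequencies (π does not depend on which allele
    is ancestral).  Sites with fewer than 2 allele calls in ``pop`` are
    excluded from both numerator and denominator.
    """
    k = freqs.pop_col(pop)
    m = _window_mask(freqs, w)
    n = freqs.ncalls[m, k].astype(float)
    p = freqs.freq_raw[m, k]
    ok = n >= 2
    L = _length(w.span, ok, int(m.sum()), accessible)
    if L <= 0:
        return np.nan
    return float(np.sum(n[ok] / (n[ok] - 1) * 2 * p[ok] * (1 - p[ok])) / L)


def absolute_divergence(freqs: PolarizedFrequencies, w: Window,
                        pop_a: str, pop_b: str,
                        accessible: str = "span") -> float:
    """d_XY: mean per-site probability that alleles drawn one from each
    population differ, Σ p_A(1−p_B) + p_B(1−p_A) / L.

    Unpolarized (the expression is invariant under a joint allele flip);
    sites lacking calls in either population are excluded from numerator
    and denominator.
    """
    ka, kb = freqs.pop_col(pop_a), freqs.pop_col(pop_b)
    m = _window_mask(freqs, w)
    pa, pb = freqs.freq_raw[m, ka], freqs.freq_raw[m, kb]
    ok = (freqs.ncalls[m, ka] >= 1) & (freqs.ncalls[m, kb] >= 1)
    L = _length(w.span, ok, int(m.sum()), accessible)
    if L <= 0:
        return np.nan
    return float(np.sum(pa[ok] * (1 - pb[ok]) + pb[ok] * (1 - pa[ok])) / L)


def _pattern_weights(p1, p2, p3, po):
    abba = (1 - p1) * p2 * p3 * (1 - po)
    baba = p1 * (1 - p2) * p3 * (1 - po)
    return abba, baba


def _triad_freqs(freqs: PolarizedFrequencies, pops: PopulationAssignment, mask):
    t = pops.triad
    cols = [freqs.pop_col(lab) for lab in (t.p1, t.p2, t.p3, t.outgroup)]
    return [freqs.freq[mask, c] for c in cols]


def patterson_D(freqs: PolarizedFrequencies, w: Window,
                pops: PopulationAssignment):
    """Frequency-weighted ABBA/BABA sums and Patterson's D for one window.

    Returns ``(abba_sum, baba_sum, D)``; D is NaN when both sums are 0.
    """
    m = _window_mask(freqs, w) & freqs.retained
    p1, p2, p3, po = _triad_freqs(freqs, pops, m)
    abba, baba = _pattern_weights(p1, p2, p3, po)
    a, b = float(abba.sum()), float(baba.sum())
    d = (a - b) / (a + b) if (a + b) > 0 else np.nan
    return a, b, d


def dynamic_fd(freqs: PolarizedFrequencies, w: Window,
               pops: PopulationAssignment, require_positive_D: bool = True):
    """Dynamic admixture-fraction estimator for one window.

    The numerator is S(P1,P2,P3,O) = Σ(ABBA−BABA); the denominator repeats
    the sum substituting, per site, the role P_D = argmax(p2, p3) for both
    P2 and P3.  Returns ``(S_num, S_den, fd)``; fd is NaN when the window's
    D is negative (outside the estimator's validity domain, configurable)
    or the denominator is ≤ 0.
    """
    m = _window_mask(freqs, w) & freqs.retained
    p1, p2, p3, po = _triad_freqs(freqs, pops, m)
    abba, baba = _pattern_weights(p1, p2, p3, po)
    pd_ = np.maximum(p2, p3)
    abba_d, baba_d = _pattern_weights(p1, pd_, pd_, po)
    s_num = float((abba - baba).sum())
    s_den = float((abba_d - baba_d).sum())
    a, b = float(abba.sum()), float(baba.sum())
    d = (a - b) / (a + b) if (a + b) > 0 else np.nan
    fd = np.nan
    if s_den > 0 and not (require_positive_D and (np.isnan(d) or d < 0)):
        fd = s_num / s_den
    return s_num, s_den, fd


# ---------------------------------------------------------------------------
# whole-genome scan
# ---------------------------------------------------------------------------

def tile_windows(chrom_lengths: dict, width: int = DEFAULT_WIDTH) -> pd.DataFrame:
    """Tile each chromosome with non-overlapping windows; the terminal
    window may be short and is retained."""
    rows = []
    for chrom, length in chrom_lengths.items():
        starts = np.arange(0, length, width)
        for s in starts:
            rows.append((chrom, int(s), int(min(s + width, length))))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def infer_chrom_lengths(g: GenotypeMatrix) -> dict:
    out: dict = {}
    for chrom in dict.fromkeys(g.chrom.tolist()):
        out[chrom] = int(g.pos[g.chrom == chrom].max()) + 1
    return out


def scan_windows(g: GenotypeMatrix, pops: PopulationAssignment,
                 width: int = DEFAULT_WIDTH, min_snps: int = DEFAULT_MIN_SNPS,
                 min_calls: int = 2, chrom_lengths: dict | None = None,
                 accessible: str = "span",
                 require_positive_D: bool = True) -> pd.DataFrame:
    """Compute all window statistics along the genome.

    Returns one row per window (empty windows included) with columns
    ``chrom, start, end, n_accessible, n_sites, n_snps``, per-role π
    (``pi_P1``…), per-pair d_XY (``dxy_P1_P2``…), ``abba_sum, baba_sum, D,
    S_num, S_den, fd``.  Windows with fewer than ``min_snps`` informative
    SNPs have every statistic set to missing but are still emitted.
    """
    t = pops.triad
    role_pop = dict(zip(ROLE_ORDER, (t.p1, t.p2, t.p3, t.outgroup)))
    freqs = polarize(g, pops, min_calls=min_calls)

    if chrom_lengths is None:
        chrom_lengths = infer_chrom_lengths(g)
    wins = tile_windows(chrom_lengths, width)

    # map each site to its window row index
    chrom_offset: dict = {}
    off = 0
    for chrom, length in chrom_lengths.items():
        chrom_offset[chrom] = off
        off += int(np.ceil(length / width)) if length > 0 else 0
    n_win = len(wins)

    known = np.isin(freqs.chrom, list(chrom_lengths))
    if not known.all():
        raise ValueError(
            f"sites on chromosomes absent from chrom_lengths: "
            f"{sorted(set(freqs.chrom[~known]))}")
    site_win = np.array([chrom_offset[c] for c in freqs.chrom]) + freqs.pos // width

    if accessible not in ("span", "variant"):
        raise ValueError(f"unknown accessible mode {accessible!r}")
    ret = freqs.retained
    bc = lambda mask, w=None: np.bincount(  # noqa: E731
        site_win[mask], weights=None if w is None else w[mask], minlength=n_win)

    all_sites = np.ones(freqs.n_sites, dtype=bool)
    n_total = bc(all_sites)
    n_sites = bc(ret)
    span = (wins.end - wins.start).to_numpy()

    def length(ok):
        if accessible == "span":
            return span - (n_total - bc(ok))
        return bc(ok).astype(float)

    cols = {r: freqs.pop_col(role_pop[r]) for r in ROLE_ORDER}
    p = {r: np.nan_to_num(freqs.freq[:, cols[r]]) for r in ROLE_ORDER}
    praw = {r: np.nan_to_num(freqs.freq_raw[:, cols[r]]) for r in ROLE_ORDER}
    n = {r: freqs.ncalls[:, cols[r]].astype(float) for r in ROLE_ORDER}

    # informative SNPs: derived allele present in the ingroup
    snp = ret & ((p["P1"] > 0) | (p["P2"] > 0) | (p["P3"] > 0))
    n_snps = bc(snp)

    out = wins.copy()
    out["n_accessible"] = span - (n_total - n_sites)
    out["n_sites"] = n_sites.astype(int)
    out["n_snps"] = n_snps.astype(int)

    with np.errstate(invalid="ignore", divide="ignore"):
        for r in ROLE_ORDER:
            ok = n[r] >= 2
            term = np.where(ok, n[r] / np.maximum(n[r] - 1, 1)
                            * 2 * praw[r] * (1 - praw[r]), 0.0)
            L_pop = length(ok)
            out[f"pi_{r}"] = np.where(L_pop > 0, bc(ok, term) / np.maximum(L_pop, 1), np.nan)
        for ra, rb in PAIRS:
            ok = (n[ra] >= 1) & (n[rb] >= 1)
            term = np.where(ok, praw[ra] * (1 - praw[rb])
                            + praw[rb] * (1 - praw[ra]), 0.0)
            L_pair = length(ok)
            out[f"dxy_{ra}_{rb}"] = np.where(L_pair > 0, bc(ok, term) / np.maximum(L_pair, 1), np.nan)

        abba, baba = _pattern_weights(p["P1"], p["P2"], p["P3"], p["O"])
        pd_ = np.maximum(p["P2"], p["P3"])
        abba_d, baba_d = _pattern_weights(p["P1"], pd_, pd_, p["O"])
        zero = np.zeros(freqs.n_sites)
        A = bc(ret, np.where(ret, abba, zero))
        B = bc(ret, np.where(ret, baba, zero))
        s_num = A - B
        s_den = bc(ret, np.where(ret, abba_d - baba_d, zero))
        D = np.where(A + B > 0, (A - B) / np.where(A + B > 0, A + B, 1), np.nan)
        fd = np.where(s_den > 0, s_num / np.where(s_den > 0, s_den, 1), np.nan)
        if require_positive_D:
            fd = np.where(np.isnan(D) | (D < 0), np.nan, fd)

    out["abba_sum"], out["baba_sum"], out["D"] = A, B, D
    out["S_num"], out["S_den"], out["fd"] = s_num, s_den, fd

    thin = out["n_snps"] < min_snps
    stat_cols = ([f"pi_{r}" for r in ROLE_ORDER]
                 + [f"dxy_{a}_{b}" for a, b in PAIRS]
                 + ["abba_sum", "baba_sum", "D", "S_num", "S_den", "fd"])
    out.loc[thin, stat_cols] = np.nan
    logger.info("scan_windows: %d windows (%d below min_snps=%d)",
                len(out), int(thin.sum()), min_snps)
    return out


def genome_wide_D(stats: pd.DataFrame, block_size: int = 1_000_000,
                  min_blocks: int = 20):
    """Genome-wide Patterson's D with a block-jackknife standard error.

    Blocks default to 1 Mb of consecutive windows; on short (simulated)
    genomes the block size shrinks so that at least ``min_blocks`` blocks
    exist, keeping the jackknife variance estimate usable.

    Returns ``(D, se, n_blocks)``.
    """
    ok = stats["abba_sum"].notna() & stats["baba_sum"].notna()
    sub = stats.loc[ok]
    a, b = sub["abba_sum"].to_numpy(), sub["baba_sum"].to_numpy()
    tot_a, tot_b = a.sum(), b.sum()
    if tot_a + tot_b <= 0:
        return np.nan, np.nan, 0
    d_hat = (tot_a - tot_b) / (tot_a + tot_b)

    total_span = float((sub["end"] - sub["start"]).sum())
    bs = block_size
    if total_span / bs < min_blocks:
        bs = max(int((sub["end"] - sub["start"]).max()), int(total_span // min_blocks))
    key = sub["chrom"].astype(str) + ":" + (sub["start"] // bs).astype(str)
    codes = pd.factorize(key)[0]
    n_blocks = codes.max() + 1
    if n_blocks < 2:
        return d_hat, np.nan, int(n_blocks)

    a_blk = np.bincount(codes, weights=a, minlength=n_blocks)
    b_blk = np.bincount(codes, weights=b, minlength=n_blocks)
    loo = (tot_a - a_blk - (tot_b - b_blk)) / (tot_a - a_blk + tot_b - b_blk)
    se = float(np.sqrt((n_blocks - 1) / n_blocks * np.sum((loo - loo.mean()) ** 2)))
    return float(d_hat), se, int(n_blocks)
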