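"""Case-control scan for domestication-associated haplotypes.

Domesticated accessions are labeled cases, wild ones controls.  Two log10
Bayes factors are computed at every polymorphic marker:

* ``bf1`` — single-marker association: Beta-binomial marginal likelihood of
  the case and control allele counts under separate frequencies versus a
  pooled frequency, in closed form via Beta functions.
* ``bf2`` — local-haplotype association: pseudo-haplotypes in a window of
  ``flank`` markers each side of the core marker are clustered by Hamming
  distance (k-medoids, deterministic farthest-point initialization); the
  Bayes factor contrasts per-cluster case/control rates (Beta-Bernoulli,
  product over clusters) against a pooled rate.  This is a deterministic
  local-haplotype-sharing statistic: samples descending from the same
  recent haplotype fall in the same cluster, so a sweep shared by the
  cases yields a case-loaded cluster and a large bf2.

Significance is calibrated by permuting case-control labels (group sizes
preserved) and recomputing both statistics, treating the permuted values
as draws from the null.  Markers passing both thresholds are classified
against gene models (UTR / synonymous / nonsynonymous / splice / stop
categories, codon recomputed from the reference honoring strand and
phase); genes with at least two passing markers in qualifying categories
are reported as domestication candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import betaln

from .io import MISSING, Gene, GenotypeMatrix, Transcript

logger = logging.getLogger("triadscan")

LN10 = np.log(10.0)

CATEGORIES = ("five_prime_utr", "three_prime_utr", "nonsynonymous", "synonymous",
              "splice_site", "stop_gained", "stop_lost", "intron", "intergenic")
#: categories that can support a candidate gene
QUALIFYING = frozenset({"five_prime_utr", "three_prime_utr", "nonsynonymous",
                        "splice_site", "stop_gained", "stop_lost"})
#: multiple-transcript conflicts resolved by decreasing severity
SEVERITY = ("stop_gained", "stop_lost", "splice_site", "nonsynonymous",
            "five_prime_utr", "three_prime_utr", "synonymous", "intron",
            "intergenic")
_SEV_RANK = {c: i for i, c in enumerate(SEVERITY)}

#: fixed Bayes-factor cutoffs used in the published scans
DEFAULT_THRESHOLDS = {"2COD": {"bf1": 3.0, "bf2": 3.5},
                      "DMA": {"bf1": 3.3, "bf2": 3.0}}


@dataclass
class PhenotypeDesign:
    """Case/control sample sets for one domestication phenotype."""

    cases: list
    controls: list
    label: str = "design"

    def __post_init__(self) -> None:
        if not self.cases or not self.controls:
            raise ValueError("cases and controls must be non-empty")
        if set(self.cases) & set(self.controls):
            raise ValueError("cases and controls overlap")

    @property
    def samples(self) -> list:
        return list(self.cases) + list(self.controls)


# ---------------------------------------------------------------------------
# Bayes factors
# ---------------------------------------------------------------------------

def _ln_marginal(k, n, a, b):
    """ln Beta-binomial marginal likelihood of an ordered allele sequence."""
    return betaln(k + a, n - k + b) - betaln(a, b)


def single_marker_bf(g: GenotypeMatrix, design: PhenotypeDesign,
                     prior=(1.0, 1.0)) -> np.ndarray:
    """log10 Bayes factor per marker for separate vs pooled allele frequency.

    bf1 = log10[ m(cases)·m(controls) / m(pooled) ] with m the Beta(a,b)
    binomial marginal of the allele counts.  Markers monomorphic across
    cases+controls return 0 by convention.
    """
    a, b = prior
    ci = g.sample_index(design.cases)
    wi = g.sample_index(design.controls)

    def counts(idx):
        d = g.dosage[:, idx]
        m = d == MISSING
        return np.where(m, 0, d).sum(axis=1), 2 * (~m).sum(axis=1)

    k1, n1 = counts(ci)
    k0, n0 = counts(wi)
    kt, nt = k1 + k0, n1 + n0
    lnbf = (_ln_marginal(k1, n1, a, b) + _ln_marginal(k0, n0, a, b)
            - _ln_marginal(kt, nt, a, b))
    bf1 = lnbf / LN10
    mono = (kt == 0) | (kt == nt)
    bf1[mono] = 0.0
    return bf1


def pseudo_haplotypes(g: GenotypeMatrix, samples, seed: int = 0) -> np.ndarray:
    """Expand diploid dosages to two pseudo-haplotypes per sample.

    Homozygous calls split deterministically; unphased heterozygotes are
    assigned a random phase from the seeded generator.  Missing calls are
    treated as ancestral (logged).
    """
    rng = np.random.default_rng(seed)
    idx = g.sample_index(samples)
    d = g.dosage[:, idx]
    n_missing = int((d == MISSING).sum())
    if n_missing:
        logger.info("pseudo_haplotypes: %d missing calls treated as ancestral", n_missing)
    d = np.where(d == MISSING, 0, d)
    n_sites, n_samp = d.shape
    h = np.zeros((2 * n_samp, n_sites), dtype=np.int8)
    h[0::2] = (d.T >= 1)
    h[1::2] = (d.T == 2)
    het = d.T == 1
    flip = rng.random(het.shape) < 0.5
    swap = het & flip
    h0, h1 = h[0::2].copy(), h[1::2].copy()
    h[0::2] = np.where(swap, h1, h0)
    h[1::2] = np.where(swap, h0, h1)
    return h


def _kmedoids(dist: np.ndarray, k: int, max_iter: int = 20) -> np.ndarray:
    """Deterministic k-medoids on a precomputed distance matrix.

    Farthest-point initialization: the first medoid is the point with the
    largest summed distance to all others; each further medoid maximizes
    the minimum distance to those already chosen.  All ties break to the
    lowest index.  Returns cluster assignments (may use < k clusters when
    fewer distinct points exist).
    """
    n = dist.shape[0]
    medoids = [int(np.argmax(dist.sum(axis=1)))]
    while len(medoids) < k:
        mind = dist[:, medoids].min(axis=1)
        cand = int(np.argmax(mind))
        if mind[cand] == 0:
            break  # no more distinct points
        medoids.append(cand)
    for _ in range(max_iter):
        assign = np.argmin(dist[:, medoids], axis=1)
        new = []
        for c in range(len(medoids)):
            members = np.flatnonzero(assign == c)
            within = dist[np.ix_(members, members)].sum(axis=1)
            new.append(int(members[np.argmin(within)]))
        if new == medoids:
            break
        medoids = new
    return np.argmin(dist[:, medoids], axis=1)


def _bf_from_clusters(assign: np.ndarray, y: np.ndarray, a: float, b: float) -> float:
    """log10 BF: per-cluster vs pooled Beta-Bernoulli case rate."""
    n1, n = int(y.sum()), y.size
    ln = -_ln_marginal(n1, n, a, b)
    for c in np.unique(assign):
        m = assign == c
        ln += _ln_marginal(int(y[m].sum()), int(m.sum()), a, b)
    return float(ln / LN10)


def local_haplotype_bf(g: GenotypeMatrix, design: PhenotypeDesign,
                       flank: int = 10, k: int = 2, prior=(1.0, 1.0),
                       seed: int = 0, return_clusters: bool = False):
    """log10 local-haplotype Bayes factor at every marker.

    Windows never span chromosome boundaries and are clipped at ends.
    Windows containing fewer than 2 distinct pseudo-haplotypes give bf2 = 0.
    When ``return_clusters`` is set, also returns the per-marker cluster
    assignment matrix (−1 where degenerate), which permits recomputing the
    Bayes factor under permuted labels without re-clustering.
    """
    a, b = prior
    h = pseudo_haplotypes(g, design.samples, seed=seed)
    y = np.array([1] * (2 * len(design.cases)) + [0] * (2 * len(design.controls)),
                 dtype=np.int8)
    n_hap, n_sites = h.shape
    bf2 = np.zeros(n_sites)
    clusters = np.full((n_sites, n_hap), -1, dtype=np.int8)

    for chrom in dict.fromkeys(g.chrom.tolist()):
        cols = np.flatnonzero(g.chrom == chrom)
        hc = h[:, cols]
        # cumulative pairwise mismatches -> O(1) windowed Hamming distances
        mism = (hc[:, None, :] != hc[None, :, :]).astype(np.int32)
        cum = np.concatenate(
            [np.zeros((n_hap, n_hap, 1), np.int32), mism.cumsum(axis=2)], axis=2)
        for j, site in enumerate(cols):
            lo, hi = max(0, j - flank), min(len(cols), j + flank + 1)
            dist = cum[:, :, hi] - cum[:, :, lo]
            if dist.max() == 0:
                continue  # identical haplotypes in all samples
            assign = _kmedoids(dist, k)
            clusters[site] = assign
            bf2[site] = _bf_from_clusters(assign, y, a, b)
    if return_clusters:
        return bf2, clusters
    return bf2


def bf2_from_clusters(clusters: np.ndarray, y: np.ndarray, prior=(1.0, 1.0)) -> np.ndarray:
    """Recompute bf2 for every marker from stored cluster assignments."""
    a, b = prior
    out = np.zeros(clusters.shape[0])
    for i in range(clusters.shape[0]):
        assign = clusters[i]
        if assign[0] < 0:
            continue
        out[i] = _bf_from_clusters(assign, y, a, b)
    return out


def permutation_null(g: GenotypeMatrix, design: PhenotypeDesign,
                     n_perm: int = 1, seed: int = 0, flank: int = 10,
                     k: int = 2, prior=(1.0, 1.0), threshold_quantile=None):
    """Permute case-control labels and recompute bf1/bf2 as null draws.

    Group sizes are preserved.  Clustering depends only on genotypes, so
    stored cluster assignments are reused across permutations.  Suggested
    thresholds are the maxima of the null distributions (default) or the
    given quantile.  Returns a dict with observed and null tables plus
    thresholds; fixed seed gives identical output on rerun.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    n_case = len(design.cases)
    samples = design.samples
    if n_case == len(samples) or n_case == 0:
        raise ValueError("cannot permute: one group is empty")

    bf1 = single_marker_bf(g, design, prior)
    bf2, clusters = local_haplotype_bf(g, design, flank=flank, k=k, prior=prior,
                                       seed=seed, return_clusters=True)

    null1 = np.empty((n_perm, g.n_sites))
    null2 = np.empty((n_perm, g.n_sites))
    for i in range(n_perm):
        perm = rng.permutation(len(samples))
        cases_p = [samples[j] for j in perm[:n_case]]
        ctrl_p = [samples[j] for j in perm[n_case:]]
        d_p = PhenotypeDesign(cases_p, ctrl_p, design.label + "_perm")
        null1[i] = single_marker_bf(g, d_p, prior)
        # haplotype order is fixed by `samples`; permute labels over samples
        y = np.zeros(len(samples), dtype=np.int8)
        y[perm[:n_case]] = 1
        null2[i] = bf2_from_clusters(clusters, np.repeat(y, 2), prior)
    if threshold_quantile is None:
        thr1, thr2 = float(null1.max()), float(null2.max())
    else:
        thr1 = float(np.quantile(null1, threshold_quantile))
        thr2 = float(np.quantile(null2, threshold_quantile))
    logger.info("permutation_null: %d permutation(s); thresholds bf1>=%.3g bf2>=%.3g",
                n_perm, thr1, thr2)
    return {"bf1": bf1, "bf2": bf2, "null_bf1": null1, "null_bf2": null2,
            "bf1_threshold": thr1, "bf2_threshold": thr2}


# ---------------------------------------------------------------------------
# variant-effect classification
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGT", "TGCA")


def _translate(codon: str) -> str:
    from Bio.Seq import Seq
    return str(Seq(codon).translate())


def _chrom_seq(reference, chrom: str) -> str:
    if isinstance(reference, dict):
        return reference[chrom]
    return str(reference[chrom][:])  # pyfaidx.Fasta


def _cds_positions(tx: Transcript) -> np.ndarray:
    """Genomic positions of CDS bases in translation order."""
    segs = sorted((s, e) for s, e, _ in tx.cds)
    pos = np.concatenate([np.arange(s, e) for s, e in segs])
    return pos[::-1] if tx.strand == "-" else pos


def _first_phase(tx: Transcript) -> int:
    segs = sorted(tx.cds, key=lambda c: c[0], reverse=(tx.strand == "-"))
    return segs[0][2] if segs else 0


def _in_any(pos: int, intervals) -> bool:
    return any(s <= pos < e for s, e in intervals)


def _classify_in_transcript(pos: int, ref: str, alt: str, tx: Transcript,
                            seq: str):
    """Effect category of a marker within one transcript, or None if the
    marker is outside every exon and intron of the transcript."""
    exons = sorted(tx.exons)
    if not exons:
        return None
    # intron / splice site
    for (s0, e0), (s1, _) in zip(exons, exons[1:]):
        if e0 <= pos < s1:
            if pos < e0 + 2 or pos >= s1 - 2:
                return "splice_site"
            return "intron"
    if not _in_any(pos, exons):
        return None
    if _in_any(pos, tx.utr5):
        return "five_prime_utr"
    if _in_any(pos, tx.utr3):
        return "three_prime_utr"
    if not tx.cds:
        return "intron"  # exon of a non-coding transcript: inside gene, non-qualifying
    cds_pos = _cds_positions(tx)
    hit = np.flatnonzero(cds_pos == pos)
    if hit.size == 0:
        return "intron"  # exonic but outside CDS/UTR annotation
    if tx.flagged:
        return "synonymous"  # frame unknown: position-only, never qualifies
    i = int(hit[0])
    skip = _first_phase(tx)
    if i < skip:
        return "synonymous"  # upstream of the first complete codon
    frame = (i - skip) % 3
    c0 = i - frame
    if c0 + 3 > cds_pos.size:
        return "synonymous"  # trailing partial codon
    codon_pos = cds_pos[c0:c0 + 3]
    if tx.strand == "+":
        ref_codon = "".join(seq[p] for p in codon_pos)
        new = alt
    else:
        ref_codon = "".join(seq[p].translate(_COMP) for p in codon_pos)
        new = alt.translate(_COMP)
    alt_codon = ref_codon[:frame] + new + ref_codon[frame + 1:]
    aa0, aa1 = _translate(ref_codon), _translate(alt_codon)
    if aa0 == aa1:
        return "synonymous"
    if aa1 == "*":
        return "stop_gained"
    if aa0 == "*":
        return "stop_lost"
    return "nonsynonymous"


def classify_effects(markers: pd.DataFrame, genes: list, reference) -> pd.DataFrame:
    """Classify each marker against overlapping gene models.

    ``markers`` needs columns ``chrom, pos, ref, alt`` (0-based positions).
    ``reference`` is a dict chrom→sequence or a ``pyfaidx.Fasta``.  Each
    marker gets the most severe category over all overlapping transcripts
    (severity: stop > splice > nonsynonymous > UTR > synonymous > intron),
    with the gene contributing that category attached.  Markers outside all
    genes are intergenic.
    """
    by_chrom: dict = {}
    for gene in genes:
        by_chrom.setdefault(gene.chrom, []).append(gene)

    seqs: dict = {}
    rows = []
    for _, mk in markers.iterrows():
        chrom, pos = mk["chrom"], int(mk["pos"])
        ref, alt = mk["ref"], mk["alt"]
        best, best_gene, flagged = None, None, False
        for gene in by_chrom.get(chrom, []):
            if not (gene.start <= pos < gene.end):
                continue
            if chrom not in seqs:
                seqs[chrom] = _chrom_seq(reference, chrom)
            txs = gene.transcripts or [None]
            for tx in txs:
                if tx is None:
                    cat = "intron"
                else:
                    cat = _classify_in_transcript(pos, ref, alt, tx, seqs[chrom])
                if cat is None:
                    cat = "intron"  # inside gene span but between annotations
                if best is None or _SEV_RANK[cat] < _SEV_RANK[best]:
                    best, best_gene = cat, gene.gid
                    flagged = bool(tx is not None and tx.flagged)
        if best is None:
            best, best_gene = "intergenic", None
        rows.append((chrom, pos, ref, alt, best, best_gene, flagged))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                       "category", "gene", "flagged"])


# ---------------------------------------------------------------------------
# candidate-gene filter
# ---------------------------------------------------------------------------

def select_candidates(assoc: pd.DataFrame, effects: pd.DataFrame,
                      bf1_min: float, bf2_min: float,
                      require_both: bool = True, min_markers: int = 2,
                      qualifying=QUALIFYING, design_label: str = "") -> pd.DataFrame:
    """Apply the candidate-gene filter.

    A gene is a candidate iff at least ``min_markers`` of its markers pass
    the Bayes-factor thresholds (both bf1 and bf2 by default; either with
    ``require_both=False``) AND fall in a qualifying effect category (UTRs,
    nonsynonymous, splice site, stop gained/lost).

    ``assoc`` needs columns ``chrom, pos, bf1, bf2``.  Returns one row per
    candidate with supporting-marker evidence.
    """
    merged = assoc.merge(effects, on=["chrom", "pos"], how="inner")
    if require_both:
        hits = (merged["bf1"] >= bf1_min) & (merged["bf2"] >= bf2_min)
    else:
        hits = (merged["bf1"] >= bf1_min) | (merged["bf2"] >= bf2_min)
    qual = hits & merged["category"].isin(qualifying) & merged["gene"].notna()
    sup = merged.loc[qual]
    rows = []
    for gene, grp in sup.groupby("gene", sort=True):
        if len(grp) >= min_markers:
            rows.append({
                "gene": gene,
                "design": design_label,
                "n_support": len(grp),
                "positions": ",".join(str(p) for p in grp["pos"]),
                "categories": ",".join(grp["category"]),
                "min_bf1": float(grp["bf1"].min()),
                "min_bf2": float(grp["bf2"].min()),
            })
    out = pd.DataFrame(rows, columns=["gene", "design", "n_support", "positions",
                                      "categories", "min_bf1", "min_bf2"])
    logger.info("select_candidates: %d candidate genes (of %d genes with "
                "qualifying markers)", len(out), sup["gene"].nunique())
    return out
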