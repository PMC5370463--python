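"""Genotype, population and annotation I/O plus site-level filters.

Everything downstream (window scans, introgression block calling, the
domestication scan) works from three substrates built here:

* :class:`GenotypeMatrix` — per-site alternate-allele dosages for a set of
  diploid samples, restricted to biallelic SNPs.
* :class:`PopulationAssignment` — sample→population map plus the triad roles
  (P1 sister receptor, P2 receptor, P3 donor, O outgroup).
* :class:`PolarizedFrequencies` — per-site derived-allele frequencies per
  population, polarized against the allele fixed in the outgroup.

Coordinates are 0-based half-open internally; VCF and GFF3 readers convert on
ingest and the VCF writer converts back.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger("triadscan")

#: dosage value marking a missing genotype call
MISSING = -1

DROP_OK = ""
DROP_OUTGROUP_MISSING = "outgroup_missing"
DROP_OUTGROUP_POLYMORPHIC = "outgroup_polymorphic"
DROP_LOW_CALLS = "low_calls"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Biallelic SNP dosages for diploid samples.

    Attributes
    ----------
    chrom : array of str, per site
    pos : array of int, 0-based site positions (VCF POS − 1)
    dosage : int8 array, shape (n_sites, n_samples); count of alternate
        alleles in {0, 1, 2}, or ``MISSING`` (−1)
    samples : ordered sample identifiers
    ref, alt : single-base reference / alternate allele per site
    """

    chrom: np.ndarray
    pos: np.ndarray
    dosage: np.ndarray
    samples: list[str]
    ref: np.ndarray
    alt: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.ref = np.asarray(self.ref)
        self.alt = np.asarray(self.alt)
        self.samples = list(self.samples)
        if self.dosage.shape != (self.pos.size, len(self.samples)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{self.pos.size} sites x {len(self.samples)} samples"
            )
        ok = np.isin(self.dosage, (0, 1, 2, MISSING))
        if not ok.all():
            bad = np.unique(self.dosage[~ok])
            raise ValueError(f"invalid dosage values {bad.tolist()}")
        # sites must be sorted, strictly increasing within each chromosome
        same = self.chrom[1:] == self.chrom[:-1]
        if np.any(same & (np.diff(self.pos) <= 0)):
            raise ValueError("sites not strictly increasing within chromosome")

    @property
    def n_sites(self) -> int:
        return int(self.pos.size)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def take(self, idx) -> "GenotypeMatrix":
        """Subset sites (order-preserving)."""
        return GenotypeMatrix(
            self.chrom[idx], self.pos[idx], self.dosage[idx],
            self.samples, self.ref[idx], self.alt[idx],
        )

    def sample_index(self, names) -> np.ndarray:
        lut = {s: i for i, s in enumerate(self.samples)}
        missing = [n for n in names if n not in lut]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return np.array([lut[n] for n in names], dtype=np.intp)


@dataclass(frozen=True)
class Triad:
    """Test configuration: sister receptor P1, receptor P2, donor P3, outgroup O."""

    p1: str
    p2: str
    p3: str
    outgroup: str

    @property
    def roles(self) -> dict:
        return {"P1": self.p1, "P2": self.p2, "P3": self.p3, "O": self.outgroup}

    @property
    def id(self) -> str:
        return f"{self.p1}-{self.p2}-{self.p3}-{self.outgroup}"


@dataclass
class PopulationAssignment:
    """Sample→population mapping plus triad role bindings."""

    sample_to_pop: dict
    triad: Triad

    def __post_init__(self) -> None:
        labels = [self.triad.p1, self.triad.p2, self.triad.p3, self.triad.outgroup]
        if len(set(labels)) != 4:
            raise ValueError(f"triad roles must bind distinct populations: {labels}")
        for lab in labels:
            if not self.samples_of(lab):
                raise ValueError(f"population {lab!r} bound to a triad role has no samples")

    @property
    def populations(self) -> list[str]:
        seen: dict = {}
        for p in self.sample_to_pop.values():
            seen.setdefault(p, None)
        return list(seen)

    def samples_of(self, pop: str) -> list[str]:
        return [s for s, p in self.sample_to_pop.items() if p == pop]


def read_population_map(path) -> dict:
    """Read a 2-column tab-separated sample→population table (no header)."""
    mapping: dict = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{ln}: expected 2 tab-separated fields")
        mapping[parts[0]] = parts[1]
    return mapping


@dataclass
class PolarizedFrequencies:
    """Per-site derived-allele frequencies polarized against the outgroup.

    ``freq[i, k]`` is the derived-allele frequency of population ``pops[k]``
    at site ``i`` (NaN where the site was dropped); ``ncalls[i, k]`` the
    number of non-missing allele calls entering that frequency.  A site is
    retained only when the outgroup is fixed (unambiguous ancestral allele)
    and every population reaches ``min_calls`` allele calls.

    ``freq_raw`` holds the unpolarized alternate-allele frequency at every
    site with at least one call, regardless of outgroup state.  π and d_XY
    are invariant under allele relabelling, so they are computed from
    ``freq_raw`` and do not lose the sites polarization drops; only the
    pattern statistics (D, f_d) require ``freq``.
    """

    chrom: np.ndarray
    pos: np.ndarray
    pops: list[str]
    freq: np.ndarray
    ncalls: np.ndarray
    retained: np.ndarray
    drop_reason: np.ndarray
    freq_raw: np.ndarray = None

    def pop_col(self, pop: str) -> int:
        return self.pops.index(pop)

    @property
    def n_sites(self) -> int:
        return int(self.pos.size)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, samples=None) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Multiallelic and indel records are dropped (counts logged).  Positions
    are converted to 0-based.  Requesting a sample absent from the header
    raises ``KeyError`` naming it; unsorted input raises ``ValueError``.
    """
    from cyvcf2 import VCF

    path = str(path)
    header = VCF(path)
    available = list(header.samples)
    header.close()
    if samples is None:
        samples = available
    else:
        samples = list(samples)
        absent = [s for s in samples if s not in available]
        if absent:
            raise KeyError(f"sample(s) not present in VCF header: {absent}")

    vcf = VCF(path, samples=samples, gts012=True)
    order = [list(vcf.samples).index(s) for s in samples]

    chroms, poss, refs, alts, rows = [], [], [], [], []
    n_indel = n_multi = 0
    last = (None, -1)
    bases = {"A", "C", "G", "T"}
    for v in vcf:
        if v.CHROM == last[0] and v.POS <= last[1]:
            raise ValueError(f"unsorted VCF at {v.CHROM}:{v.POS}")
        last = (v.CHROM, v.POS)
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        if len(v.REF) != 1 or len(v.ALT[0]) != 1 or v.REF not in bases or v.ALT[0] not in bases:
            n_indel += 1
            continue
        gt = v.gt_types  # 0 hom-ref, 1 het, 2 hom-alt, 3 missing (gts012)
        dos = gt.astype(np.int8)
        dos[gt == 3] = MISSING
        chroms.append(v.CHROM)
        poss.append(v.POS - 1)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        rows.append(dos[order])
    vcf.close()
    logger.info(
        "read_vcf: %d biallelic SNPs kept, %d multiallelic and %d indel/non-SNP records dropped",
        len(poss), n_multi, n_indel,
    )
    dosage = np.array(rows, dtype=np.int8) if rows else np.empty((0, len(samples)), np.int8)
    return GenotypeMatrix(
        np.array(chroms), np.array(poss, dtype=np.int64), dosage,
        samples, np.array(refs), np.array(alts),
    )


def write_vcf(g: GenotypeMatrix, path, contig_lengths=None) -> None:
    """Write a GenotypeMatrix as uncompressed VCF 4.2 (GT only)."""
    gtmap = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=triadscan\n")
        if contig_lengths:
            for c, ln in contig_lengths.items():
                fh.write(f"##contig=<ID={c},length={ln}>\n")
        else:
            for c in dict.fromkeys(g.chrom.tolist()):
                fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.samples) + "\n")
        for i in range(g.n_sites):
            gts = "\t".join(gtmap[int(d)] for d in g.dosage[i])
            fh.write(f"{g.chrom[i]}\t{g.pos[i] + 1}\t.\t{g.ref[i]}\t{g.alt[i]}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# site filters
# ---------------------------------------------------------------------------

def filter_singletons(g: GenotypeMatrix) -> GenotypeMatrix:
    """Remove sites whose minor allele is carried by exactly one sample.

    A singleton is a SNP private to a single accession; such sites inflate
    terminal branches and are removed before any scan.  The minor allele is
    the one with the smaller allele count among non-missing calls; on a tie
    either allele being private to one sample removes the site.
    """
    dos = g.dosage
    miss = dos == MISSING
    alt_count = np.where(miss, 0, dos).sum(axis=1)
    ref_count = np.where(miss, 0, 2 - dos).sum(axis=1)
    carr_alt = ((dos >= 1) & ~miss).sum(axis=1)
    carr_ref = ((dos <= 1) & ~miss).sum(axis=1)

    singleton = np.where(
        alt_count < ref_count, carr_alt == 1,
        np.where(ref_count < alt_count, carr_ref == 1,
                 (carr_alt == 1) | (carr_ref == 1)),
    )
    # a monomorphic site has minor-allele count 0 → never a singleton
    singleton &= (alt_count > 0) & (ref_count > 0)
    logger.info("filter_singletons: removed %d of %d sites",
                int(singleton.sum()), g.n_sites)
    return g.take(~singleton)


def polarize(g: GenotypeMatrix, pops: PopulationAssignment,
             min_calls: int = 2) -> PolarizedFrequencies:
    """Polarize alleles against the outgroup and compute per-population
    derived-allele frequencies.

    The ancestral allele at a site is the allele fixed among non-missing
    outgroup calls; a heterozygous outgroup call counts as polymorphic and
    drops the site (polarization must be unambiguous).  Sites where any
    population has fewer than ``min_calls`` non-missing allele calls are
    dropped.  Missing genotypes are excluded from denominators rather than
    imputed.
    """
    out_samples = pops.samples_of(pops.triad.outgroup)
    if not out_samples:
        raise ValueError("outgroup population has no samples")
    pop_labels = pops.populations
    n_sites = g.n_sites

    out_idx = g.sample_index(out_samples)
    od = g.dosage[:, out_idx]
    omiss = od == MISSING
    o_n = (~omiss).sum(axis=1)
    any_het = ((od == 1) & ~omiss).any(axis=1)
    any_ref = ((od == 0) & ~omiss).any(axis=1)
    any_alt = ((od == 2) & ~omiss).any(axis=1)

    reason = np.full(n_sites, DROP_OK, dtype=object)
    reason[(o_n > 0) & (any_het | (any_ref & any_alt))] = DROP_OUTGROUP_POLYMORPHIC
    reason[o_n == 0] = DROP_OUTGROUP_MISSING
    # ancestral allele is alt wherever the outgroup is fixed for alt
    anc_is_alt = any_alt & ~any_ref & ~any_het

    freq = np.full((n_sites, len(pop_labels)), np.nan)
    freq_raw = np.full((n_sites, len(pop_labels)), np.nan)
    ncalls = np.zeros((n_sites, len(pop_labels)), dtype=np.int64)
    for k, lab in enumerate(pop_labels):
        idx = g.sample_index(pops.samples_of(lab))
        d = g.dosage[:, idx]
        m = d == MISSING
        n_k = 2 * (~m).sum(axis=1)
        alt = np.where(m, 0, d).sum(axis=1)
        derived = np.where(m, 0, np.where(anc_is_alt[:, None], 2 - d, d)).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq[:, k] = np.where(n_k > 0, derived / np.maximum(n_k, 1), np.nan)
            freq_raw[:, k] = np.where(n_k > 0, alt / np.maximum(n_k, 1), np.nan)
        ncalls[:, k] = n_k
        low = (n_k < min_calls) & (reason == DROP_OK)
        reason[low] = DROP_LOW_CALLS

    retained = reason == DROP_OK
    freq[~retained] = np.nan
    logger.info("polarize: %d/%d sites retained (%d outgroup-polymorphic, "
                "%d outgroup-missing, %d low-calls)",
                int(retained.sum()), n_sites,
                int((reason == DROP_OUTGROUP_POLYMORPHIC).sum()),
                int((reason == DROP_OUTGROUP_MISSING).sum()),
                int((reason == DROP_LOW_CALLS).sum()))
    return PolarizedFrequencies(
        g.chrom.copy(), g.pos.copy(), pop_labels, freq, ncalls,
        retained, reason.astype(str), freq_raw,
    )


# ---------------------------------------------------------------------------
# gene models (GFF3)
# ---------------------------------------------------------------------------

@dataclass
class Transcript:
    tid: str
    chrom: str
    strand: str
    exons: list = field(default_factory=list)   # 0-based half-open, sorted
    cds: list = field(default_factory=list)     # (start, end, phase)
    utr5: list = field(default_factory=list)
    utr3: list = field(default_factory=list)
    flagged: bool = False  # no CDS, or CDS length not divisible by 3

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e, _ in self.cds)


@dataclass
class Gene:
    gid: str
    chrom: str
    start: int
    end: int
    strand: str
    transcripts: list = field(default_factory=list)
    flagged: bool = False  # retained with span only (no CDS children)


def _infer_utrs(tx: Transcript) -> None:
    """Fill UTRs as exon minus CDS-span, split 5'/3' by strand."""
    if not tx.cds:
        return
    cmin = min(s for s, _, _ in tx.cds)
    cmax = max(e for _, e, _ in tx.cds)
    for s, e in tx.exons:
        if s < cmin:
            piece = (s, min(e, cmin))
            (tx.utr5 if tx.strand == "+" else tx.utr3).append(piece)
        if e > cmax:
            piece = (max(s, cmax), e)
            (tx.utr3 if tx.strand == "+" else tx.utr5).append(piece)


def read_gff_genes(path) -> list:
    """Read gene models from GFF3 into :class:`Gene` records.

    Coordinates convert from GFF's 1-based inclusive to 0-based half-open.
    UTRs are taken from explicit five_prime_UTR/three_prime_UTR features
    when present, otherwise inferred as exon minus CDS span.  A gene with
    no CDS children is retained with its span only and flagged.
    """
    import gffutils

    # fail fast with a line number on malformed rows; gffutils' own error
    # does not carry one
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        if len(line.split("\t")) != 9:
            raise ValueError(f"{path}:{ln}: malformed GFF3 line (expected 9 fields)")

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    genes: list = []
    for gf in db.features_of_type("gene", order_by=("seqid", "start")):
        gene = Gene(gf.id, gf.seqid, gf.start - 1, gf.end, gf.strand)
        for tf in db.children(gf, featuretype=("mRNA", "transcript"), order_by="start"):
            tx = Transcript(tf.id, tf.seqid, tf.strand)
            for ex in db.children(tf, featuretype="exon", order_by="start"):
                tx.exons.append((ex.start - 1, ex.end))
            for cd in db.children(tf, featuretype="CDS", order_by="start"):
                phase = 0 if cd.frame in (".", None) else int(cd.frame)
                tx.cds.append((cd.start - 1, cd.end, phase))
            for u in db.children(tf, featuretype="five_prime_UTR", order_by="start"):
                tx.utr5.append((u.start - 1, u.end))
            for u in db.children(tf, featuretype="three_prime_UTR", order_by="start"):
                tx.utr3.append((u.start - 1, u.end))
            if not tx.exons and tx.cds:
                tx.exons = [(s, e) for s, e, _ in tx.cds]
            if not tx.utr5 and not tx.utr3:
                _infer_utrs(tx)
            tx.flagged = (not tx.cds) or (tx.cds_length % 3 != 0)
            gene.transcripts.append(tx)
        gene.flagged = not any(tx.cds for tx in gene.transcripts)
        genes.append(gene)
    logger.info("read_gff_genes: %d genes (%d span-only)", len(genes),
                sum(g.flagged for g in genes))
    return genes
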