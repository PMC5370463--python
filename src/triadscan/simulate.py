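"""Synthetic genotype data with known introgression and sweep structure.

The generator emulates the data a triad scan consumes: four populations
(P1 sister receptor, P2 receptor, P3 donor, OUT outgroup) related by a
species tree, with per-window genealogy switching modelling an admixture
pulse from donor into receptor.

Model
-----
Windows are independent (no intra-window recombination; statistics are
per-window anyway).  Each window draws one genealogy:

* species:      (((P1,P2):t12, P3):t123, OUT):tO
* introgressed: (((P2,P3):t_admix, P1):t123, OUT):tO
* discordant (incomplete lineage sorting, probability ``p_ils`` split
  equally between the pairs (P2,P3) and (P1,P3)): the discordant pair
  coalesces *above* the species root at t123 + e1 and joins the remaining
  lineage after a further e2, with e1, e2 ~ Exponential(θ_anc).

Branch lengths are in expected substitutions per site; mutations are placed
Poisson(branch length × window length) per branch under infinite sites at
distinct integer positions.  Within-population variation sits on a star
tree: each haplotype carries Poisson(θ_tip × L) private mutations, so
E[π] = 2·θ_tip and E[d_XY(A,B)] = (branch path between A and B) + 2·θ_tip.

The three states reproduce the signal structure the scan exploits: only
discordant and introgressed windows generate ABBA/BABA patterns; the two
discordant pair choices are equally likely, so genome-wide D has
expectation 0 without gene flow; and d_XY(P2,P3) is *reduced* (2·t_admix)
in introgressed windows but *inflated* (≥ 2·t123) in discordant ones, so
the joint f_d/d_XY rule separates gene flow from lineage sorting.

Diploid genotypes pair consecutive haplotypes.  Every dataset is written
with a truth table (per-window genealogy state, per-gene sweep status), and
synthetic gene models (gene→mRNA→exon/CDS/UTR) plus a reference FASTA
support gene-overlap counting and variant-effect classification.

The domestication generator produces case accessions fixed for one founder
haplotype across sweep gene spans against segregating controls, the
structure a selective sweep leaves in a case-control panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, Gene, Transcript, write_vcf

logger = logging.getLogger("triadscan")

POPS = ("P1", "P2", "P3", "OUT")
_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Parameters of the synthetic genome.

    Branch lengths (expected substitutions/site) must satisfy
    t_admix < t12 < t123 < tO.  ``admix_fraction`` is the fraction of
    windows whose genealogy is the introgressed one; ``admix_windows``
    fixes the set explicitly instead.
    """

    window_length: int = 5_000
    n_windows: int = 100
    n_chromosomes: int = 1
    haplotypes: dict = field(default_factory=lambda: {p: 8 for p in POPS})
    t12: float = 0.01
    t123: float = 0.02
    tO: float = 0.05
    t_admix: float = 0.002
    theta_tip: float = 0.002
    p_ils: float = 0.0
    theta_anc: float = 0.002
    admix_fraction: float = 0.0
    admix_windows: list | None = None
    admix_tract_len: float = 5.0  # mean introgressed-tract length, in windows
    genes_per_window: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("t12", "t123", "tO", "t_admix", "theta_tip"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (self.t_admix < self.t12 < self.t123 < self.tO):
            raise ValueError("need t_admix < t12 < t123 < tO")
        if not 0 <= self.admix_fraction <= 1:
            raise ValueError("admix_fraction must be in [0, 1]")
        if not 0 <= self.p_ils <= 1:
            raise ValueError("p_ils must be in [0, 1]")
        for p, h in self.haplotypes.items():
            if h < 2 or h % 2:
                raise ValueError(f"haplotypes[{p}] must be an even count >= 2")

    @property
    def chrom_names(self) -> list:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def chrom_length(self) -> int:
        return self.window_length * self.n_windows


def _branches(cfg: SimulationConfig, state: str, rng: np.random.Generator):
    """(length, carrier populations) per branch of the window genealogy.

    Tip-population branches carry mutations fixed within that population;
    internal branches carry mutations shared by their clade.  Mutations on
    the outgroup tip appear derived in the ingroup after polarization,
    which is harmless (BBBA-type patterns carry no ABBA/BABA weight).
    """
    t12, t123, tO, ta = cfg.t12, cfg.t123, cfg.tO, cfg.t_admix
    if state == "introgressed":
        return [
            (ta, ("P2",)), (ta, ("P3",)), (t123 - ta, ("P2", "P3")),
            (t123, ("P1",)), (tO - t123, ("P1", "P2", "P3")), (tO, ("OUT",)),
        ]
    if state in ("ils_23", "ils_13"):
        pair = ("P2", "P3") if state == "ils_23" else ("P1", "P3")
        other = "P1" if state == "ils_23" else "P2"
        e1 = rng.exponential(cfg.theta_anc)
        e2 = rng.exponential(cfg.theta_anc)
        return [
            (t123 + e1, (pair[0],)), (t123 + e1, (pair[1],)),
            (e2, pair), (t123 + e1 + e2, (other,)),
            (max(tO - t123 - e1 - e2, 0.0), ("P1", "P2", "P3")), (tO, ("OUT",)),
        ]
    return [
        (t12, ("P1",)), (t12, ("P2",)), (t123 - t12, ("P1", "P2")),
        (t123, ("P3",)), (tO - t123, ("P1", "P2", "P3")), (tO, ("OUT",)),
    ]


def _sample_names(cfg: SimulationConfig) -> dict:
    out = {}
    for p in POPS:
        out[p] = [f"{p}_s{i + 1}" for i in range(cfg.haplotypes[p] // 2)]
    return out


def synthesize_genes(cfg: SimulationConfig, rng: np.random.Generator):
    """Synthetic gene models: one gene centred in each window (alternating
    strand), with 5'UTR/CDS/intron structure and CDS length divisible by 3."""
    genes = []
    L = cfg.window_length
    # template relative spans (scaled to a 5-kb window): 3 exons, 2 introns
    off = int(0.2 * L)
    exons = [(0, 400), (700, 1300), (1600, 2200)]
    cds = [(250, 400), (700, 1300), (1600, 1951)]  # 150+600+351 = 1101 = 367 codons
    utr5 = [(0, 250)]
    utr3 = [(1951, 2200)]
    if cfg.genes_per_window < 1:
        return genes
    for ci, chrom in enumerate(cfg.chrom_names):
        for w in range(cfg.n_windows):
            base = w * L + off
            strand = "+" if (w % 2 == 0) else "-"
            gid = f"gene_{chrom}_{w + 1:04d}"
            shift = lambda ivs: [(base + s, base + e) for s, e in ivs]  # noqa: E731
            tx = Transcript(
                tid=gid + ".1", chrom=chrom, strand=strand,
                exons=shift(exons),
                utr5=shift(utr5) if strand == "+" else shift(utr3),
                utr3=shift(utr3) if strand == "+" else shift(utr5),
            )
            # CDS phases in translation order
            segs = shift(cds)
            lens = [e - s for s, e in segs]
            if strand == "+":
                phases = [(3 - (sum(lens[:i]) % 3)) % 3 for i in range(len(segs))]
                tx.cds = [(s, e, ph) for (s, e), ph in zip(segs, phases)]
            else:
                order = list(range(len(segs)))[::-1]
                phases = {}
                done = 0
                for i in order:
                    phases[i] = (3 - (done % 3)) % 3
                    done += lens[i]
                tx.cds = [(s, e, phases[i]) for i, (s, e) in enumerate(segs)]
            tx.flagged = False
            genes.append(Gene(gid, chrom, base + exons[0][0], base + exons[-1][1],
                              strand, [tx]))
    return genes


def _random_sequences(cfg: SimulationConfig, rng: np.random.Generator) -> dict:
    return {c: "".join(rng.choice(_BASES, size=cfg.chrom_length))
            for c in cfg.chrom_names}


def simulate_genome(cfg: SimulationConfig):
    """Simulate the full dataset.

    Returns ``(GenotypeMatrix, truth, sequences, genes)`` where ``truth``
    is a per-window table with the generating genealogy state and
    ``sequences`` maps chromosome → reference string.  Deterministic under
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    sequences = _random_sequences(cfg, rng)
    genes = synthesize_genes(cfg, rng)
    names = _sample_names(cfg)
    samples = [s for p in POPS for s in names[p]]
    hap_slices = {}
    h0 = 0
    for p in POPS:
        hap_slices[p] = slice(h0, h0 + cfg.haplotypes[p])
        h0 += cfg.haplotypes[p]
    n_hap = h0
    L = cfg.window_length

    if cfg.admix_windows is not None:
        admix_set = set(cfg.admix_windows)
    else:
        # introgression arrives as contiguous tracts (recombination erodes a
        # pulse into multi-window blocks), placed until the target fraction
        total = cfg.n_chromosomes * cfg.n_windows
        n_admix = int(round(cfg.admix_fraction * total))
        admix_set: set = set()
        while len(admix_set) < n_admix:
            tract = int(rng.geometric(1.0 / max(cfg.admix_tract_len, 1.0)))
            start = int(rng.integers(0, total))
            for j in range(start, min(start + tract, total)):
                admix_set.add(j)
                if len(admix_set) >= n_admix:
                    break

    chroms, poss, refs, alts, rows = [], [], [], [], []
    truth_rows = []
    widx = -1
    for chrom in cfg.chrom_names:
        seq = sequences[chrom]
        for w in range(cfg.n_windows):
            widx += 1
            if widx in admix_set:
                state = "introgressed"
            elif rng.random() < cfg.p_ils:
                state = "ils_23" if rng.random() < 0.5 else "ils_13"
            else:
                state = "species"
            truth_rows.append((chrom, w * L, (w + 1) * L, state))
            events = []  # (branch carriers as hap indices)
            for blen, pops_c in _branches(cfg, state, rng):
                n_mut = rng.poisson(blen * L)
                for _ in range(n_mut):
                    carriers = np.zeros(n_hap, dtype=bool)
                    for p in pops_c:
                        carriers[hap_slices[p]] = True
                    events.append(carriers)
            if cfg.theta_tip > 0:
                for hi in range(n_hap):
                    for _ in range(rng.poisson(cfg.theta_tip * L)):
                        carriers = np.zeros(n_hap, dtype=bool)
                        carriers[hi] = True
                        events.append(carriers)
            if not events:
                continue
            n_mut = len(events)
            if n_mut > L:
                logger.warning("window %s:%d has %d mutations for %d positions; "
                               "extra mutations skipped", chrom, w, n_mut, L)
                events = events[:L]
                n_mut = L
            pos_local = np.sort(rng.choice(L, size=n_mut, replace=False))
            order = rng.permutation(n_mut)  # decouple position from branch order
            for pl, ev in zip(pos_local, (events[o] for o in order)):
                gpos = w * L + int(pl)
                ref = seq[gpos]
                alt = str(rng.choice(_BASES[_BASES != ref]))
                hap = ev
                # diploid dosage: consecutive haplotype pairs
                dos = hap.reshape(-1, 2).sum(axis=1).astype(np.int8)
                chroms.append(chrom)
                poss.append(gpos)
                refs.append(ref)
                alts.append(alt)
                rows.append(dos)

    dosage = (np.array(rows, dtype=np.int8) if rows
              else np.empty((0, len(samples)), np.int8))
    g = GenotypeMatrix(np.array(chroms), np.array(poss, dtype=np.int64),
                       dosage, samples, np.array(refs), np.array(alts))
    truth = pd.DataFrame(truth_rows, columns=["chrom", "start", "end", "state"])
    logger.info("simulate_genome: %d sites, %d samples, %d/%d introgressed windows",
                g.n_sites, g.n_samples, len(admix_set), len(truth))
    return g, truth, sequences, genes


def sample_populations(cfg: SimulationConfig) -> dict:
    """Sample→population map matching :func:`simulate_genome` output."""
    names = _sample_names(cfg)
    return {s: p for p in POPS for s in names[p]}


# ---------------------------------------------------------------------------
# domestication panel
# ---------------------------------------------------------------------------

@dataclass
class DomesticationConfig:
    """Case-control sweep panel parameters.

    ``n_case_hap`` haplotypes share one founder haplotype (fixed, zero
    diversity) across every sweep span; controls segregate everywhere.
    Background derived-allele frequencies are U-shaped (scaled
    Beta(sfs_a, sfs_b)), mimicking the excess of low- and high-frequency
    variants in a neutral frequency spectrum.  A sweep span is the sweep
    gene's body extended by ``sweep_margin`` bp of hitchhiked flank on each
    side.  Within a sweep span a fraction ``marking_frac`` of markers are
    haplotype-marking variants: derived alleles carried by the founder
    haplotype but rare among controls (frequency ~ U(marking_lo,
    marking_hi)) — the hitchhiked variation a sweep drags to fixation in
    the selected group.  Marker density (``markers_per_gene`` over ~2.2-kb
    genes plus an intergenic background) is of the order of resequencing
    SNP densities (~10 SNPs/kb).
    """

    window_length: int = 5_000
    n_genes: int = 50
    n_sweeps: int = 3
    n_case_hap: int = 6
    n_ctrl_hap: int = 26
    markers_per_gene: int = 30
    n_intergenic: int = 400
    freq_lo: float = 0.02
    freq_hi: float = 0.98
    sfs_a: float = 0.4
    sfs_b: float = 0.4
    sweep_margin: int = 1_500
    marking_frac: float = 0.35
    marking_lo: float = 0.02
    marking_hi: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case_hap % 2 or self.n_ctrl_hap % 2:
            raise ValueError("haplotype counts must be even (diploid samples)")
        if self.n_sweeps > self.n_genes:
            raise ValueError("more sweeps than genes")


def simulate_domestication(cfg: DomesticationConfig):
    """Simulate the case-control sweep panel.

    Returns ``(GenotypeMatrix, design_samples, truth, sequences, genes)``
    where ``design_samples`` is ``{"cases": [...], "controls": [...]}`` and
    ``truth`` has per-gene sweep status plus per-marker sweep membership.
    """
    rng = np.random.default_rng(cfg.seed)
    gcfg = SimulationConfig(window_length=cfg.window_length, n_windows=cfg.n_genes,
                            n_chromosomes=1, seed=cfg.seed)
    sequences = _random_sequences(gcfg, rng)
    genes = synthesize_genes(gcfg, rng)
    chrom = gcfg.chrom_names[0]

    sweep_idx = np.sort(rng.choice(cfg.n_genes, size=cfg.n_sweeps, replace=False))
    sweep_genes = {genes[i].gid for i in sweep_idx}
    sweep_spans = [(max(genes[i].start - cfg.sweep_margin, 0),
                    genes[i].end + cfg.sweep_margin) for i in sweep_idx]

    # marker positions: inside each gene + intergenic background
    positions = []
    for gene in genes:
        tx = gene.transcripts[0]
        exon_sorted = sorted(tx.exons)
        exon_pos = (np.concatenate([np.arange(s, e) for s, e in exon_sorted])
                    if exon_sorted else np.array([], dtype=int))
        intron_pos = np.concatenate(
            [np.arange(e0, s1) for (_, e0), (s1, _) in zip(exon_sorted, exon_sorted[1:])]
        ) if len(exon_sorted) > 1 else np.array([], dtype=int)
        pool = np.concatenate([exon_pos, intron_pos])
        take = min(cfg.markers_per_gene, pool.size)
        positions.append(rng.choice(pool, size=take, replace=False))
    gene_pos = np.concatenate(positions) if positions else np.array([], dtype=int)
    genic = np.zeros(gcfg.chrom_length, dtype=bool)
    for gene in genes:
        genic[gene.start:gene.end] = True
    intergenic_pool = np.flatnonzero(~genic)
    inter_pos = rng.choice(intergenic_pool, size=min(cfg.n_intergenic, intergenic_pool.size),
                           replace=False)
    pos = np.unique(np.concatenate([gene_pos, inter_pos]))
    n_markers = pos.size

    in_sweep = np.zeros(n_markers, dtype=bool)
    for s, e in sweep_spans:
        in_sweep |= (pos >= s) & (pos < e)

    # background frequencies; sweep spans carry founder-marking variants
    # (derived on the selected haplotype, rare among controls)
    n_hap = cfg.n_case_hap + cfg.n_ctrl_hap
    p_bg = cfg.freq_lo + (cfg.freq_hi - cfg.freq_lo) * rng.beta(
        cfg.sfs_a, cfg.sfs_b, size=n_markers)
    marking = in_sweep & (rng.random(n_markers) < cfg.marking_frac)
    p_bg[marking] = rng.uniform(cfg.marking_lo, cfg.marking_hi, int(marking.sum()))

    hap = (rng.random((n_hap, n_markers)) < p_bg).astype(np.int8)
    founder = (rng.random(n_markers) < p_bg).astype(np.int8)
    founder[marking] = 1
    hap[:cfg.n_case_hap, in_sweep] = founder[in_sweep]

    dosage = hap.T.reshape(n_markers, -1, 2).sum(axis=2).astype(np.int8)
    n_case_s = cfg.n_case_hap // 2
    cases = [f"case_s{i + 1}" for i in range(n_case_s)]
    controls = [f"ctrl_s{i + 1}" for i in range(cfg.n_ctrl_hap // 2)]
    samples = cases + controls

    seq = sequences[chrom]
    refs = np.array([seq[p] for p in pos])
    alts = np.array([str(rng.choice(_BASES[_BASES != r])) for r in refs])
    g = GenotypeMatrix(np.array([chrom] * n_markers), pos.astype(np.int64),
                       dosage, samples, refs, alts)

    truth_genes = pd.DataFrame({
        "gene": [gene.gid for gene in genes],
        "sweep": [gene.gid in sweep_genes for gene in genes],
    })
    truth_markers = pd.DataFrame({"chrom": chrom, "pos": pos, "in_sweep": in_sweep})
    logger.info("simulate_domestication: %d markers (%d in sweeps), %d sweep genes",
                n_markers, int(in_sweep.sum()), cfg.n_sweeps)
    return g, {"cases": cases, "controls": controls}, \
        {"genes": truth_genes, "markers": truth_markers}, sequences, genes


# ---------------------------------------------------------------------------
# fixture writing
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_gff3(genes: list, path) -> None:
    """Write gene models as GFF3 (1-based inclusive), nested
    gene→mRNA→exon/CDS/UTR."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genes:
            a = f"ID={gene.gid}"
            fh.write(f"{gene.chrom}\ttriadscan\tgene\t{gene.start + 1}\t{gene.end}"
                     f"\t.\t{gene.strand}\t.\t{a}\n")
            for tx in gene.transcripts:
                ta = f"ID={tx.tid};Parent={gene.gid}"
                tmin = min(s for s, _ in tx.exons)
                tmax = max(e for _, e in tx.exons)
                fh.write(f"{tx.chrom}\ttriadscan\tmRNA\t{tmin + 1}\t{tmax}"
                         f"\t.\t{tx.strand}\t.\t{ta}\n")
                for j, (s, e) in enumerate(sorted(tx.exons), 1):
                    fh.write(f"{tx.chrom}\ttriadscan\texon\t{s + 1}\t{e}\t.\t"
                             f"{tx.strand}\t.\tID={tx.tid}.exon{j};Parent={tx.tid}\n")
                for j, (s, e, ph) in enumerate(sorted(tx.cds), 1):
                    fh.write(f"{tx.chrom}\ttriadscan\tCDS\t{s + 1}\t{e}\t.\t"
                             f"{tx.strand}\t{ph}\tID={tx.tid}.cds{j};Parent={tx.tid}\n")
                for j, (s, e) in enumerate(sorted(tx.utr5), 1):
                    fh.write(f"{tx.chrom}\ttriadscan\tfive_prime_UTR\t{s + 1}\t{e}\t.\t"
                             f"{tx.strand}\t.\tID={tx.tid}.utr5.{j};Parent={tx.tid}\n")
                for j, (s, e) in enumerate(sorted(tx.utr3), 1):
                    fh.write(f"{tx.chrom}\ttriadscan\tthree_prime_UTR\t{s + 1}\t{e}\t.\t"
                             f"{tx.strand}\t.\tID={tx.tid}.utr3.{j};Parent={tx.tid}\n")


def write_fixtures(out_dir, g: GenotypeMatrix, truth, sequences: dict,
                   genes: list, pop_map: dict | None = None,
                   prefix: str = "sim") -> dict:
    """Write VCF + GFF3 + FASTA + truth tables (+ population map) to disk.

    Returns the path of every file written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    contigs = {c: len(s) for c, s in sequences.items()}
    paths["vcf"] = out / f"{prefix}.vcf"
    write_vcf(g, paths["vcf"], contig_lengths=contigs)
    paths["fasta"] = out / f"{prefix}.fa"
    write_fasta(sequences, paths["fasta"])
    paths["gff"] = out / f"{prefix}.gff3"
    write_gff3(genes, paths["gff"])
    if isinstance(truth, pd.DataFrame):
        truth = {"windows": truth}
    for name, df in truth.items():
        p = out / f"{prefix}.truth_{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[f"truth_{name}"] = p
    if pop_map is not None:
        p = out / f"{prefix}.pops.tsv"
        with open(p, "w") as fh:
            for s, pop in pop_map.items():
                fh.write(f"{s}\t{pop}\n")
        paths["pops"] = p
    return paths


def write_config(cfg, path) -> None:
    """Resolved config as a plain-text key-value file."""
    with open(path, "w") as fh:
        for k, v in asdict(cfg).items():
            fh.write(f"{k}\t{v}\n")
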