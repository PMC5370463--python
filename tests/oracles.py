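"""Independent oracles used by the acceptance-level tests.

Each function recomputes a quantity by direct enumeration, deliberately
avoiding the vectorized code paths it is used to check.
"""

import itertools

import numpy as np
from Bio.Seq import Seq


def site_alleles(dosages):
    """Expand diploid dosages (missing < 0) into a flat allele list."""
    out = []
    for d in dosages:
        if d < 0:
            continue
        out += [1] * int(d) + [0] * (2 - int(d))
    return out


def brute_pi(dos_by_site):
    """Mean pairwise difference per usable site across a population."""
    total, L = 0.0, 0
    for row in dos_by_site:
        al = site_alleles(row)
        if len(al) < 2:
            continue
        L += 1
        pairs = list(itertools.combinations(al, 2))
        total += sum(a != b for a, b in pairs) / len(pairs)
    return total / L if L else np.nan


def brute_dxy(dos_a, dos_b):
    """Mean between-population pairwise difference per usable site."""
    total, L = 0.0, 0
    for ra, rb in zip(dos_a, dos_b):
        a, b = site_alleles(ra), site_alleles(rb)
        if not a or not b:
            continue
        L += 1
        total += sum(x != y for x in a for y in b) / (len(a) * len(b))
    return total / L if L else np.nan


def brute_abba_baba(p1, p2, p3, po):
    """Direct per-site evaluation of the frequency-weighted pattern sums."""
    a = b = 0.0
    for q1, q2, q3, qo in zip(p1, p2, p3, po):
        a += (1 - q1) * q2 * q3 * (1 - qo)
        b += q1 * (1 - q2) * q3 * (1 - qo)
    return a, b


def run_length_blocks(flags, min_run):
    """Maximal runs of consecutive True of length >= min_run."""
    blocks, run = [], []
    for i, f in enumerate(flags):
        if f:
            run.append(i)
        else:
            if len(run) >= min_run:
                blocks.append((run[0], run[-1]))
            run = []
    if len(run) >= min_run:
        blocks.append((run[0], run[-1]))
    return blocks


def effect_by_translation(pos, alt, tx, seq):
    """Variant effect by translating the whole CDS for both alleles."""
    exons = sorted(tx.exons)
    for (s0, e0), (s1, _) in zip(exons, exons[1:]):
        if e0 <= pos < s1:
            return "splice_site" if (pos < e0 + 2 or pos >= s1 - 2) else "intron"
    if not any(s <= pos < e for s, e in exons):
        return None
    if any(s <= pos < e for s, e in tx.utr5):
        return "five_prime_utr"
    if any(s <= pos < e for s, e in tx.utr3):
        return "three_prime_utr"
    segs = sorted((s, e) for s, e, _ in tx.cds)
    cds_pos = np.concatenate([np.arange(s, e) for s, e in segs])
    if tx.strand == "-":
        cds_pos = cds_pos[::-1]
    if not np.isin(pos, cds_pos).any():
        return "intron"

    def protein(sq):
        s = ("".join(sq[p] for p in cds_pos) if tx.strand == "+" else
             "".join(str(Seq(sq[p]).complement()) for p in cds_pos))
        return str(Seq(s).translate())

    p0 = protein(seq)
    p1 = protein(seq[:pos] + alt + seq[pos + 1:])
    if p0 == p1:
        return "synonymous"
    for x, y in zip(p0, p1):
        if x != y:
            if y == "*":
                return "stop_gained"
            if x == "*":
                return "stop_lost"
            return "nonsynonymous"
    return "nonsynonymous"
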