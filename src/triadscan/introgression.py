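"""Introgressed-block calling from the window table.

A window is called introgressed when it belongs to the top 5% of defined
f_d values genome-wide AND its donor–receptor divergence d_XY(P2,P3) lies
below the genome-wide mean: gene flow makes donor and receptor coalesce
more recently than the species split, so true introgression depresses
d_XY(P2,P3) while elevating f_d, whereas incomplete lineage sorting does
not depress d_XY.  Runs of at least three adjacent flagged windows are
condensed into blocks, which are then annotated with overlapping-gene
counts.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger("triadscan")

DEFAULT_QUANTILE = 0.05
DEFAULT_MIN_RUN = 3
DXY_COL = "dxy_P2_P3"


def flag_windows(stats: pd.DataFrame, quantile: float = DEFAULT_QUANTILE,
                 dxy_col: str = DXY_COL) -> pd.DataFrame:
    """Flag joint f_d / d_XY outlier windows.

    Exactly ⌈quantile · N_defined⌉ windows satisfy the f_d condition: the
    top-k windows by f_d, ties at the boundary broken deterministically by
    genomic order.  Of these, the flagged set keeps those whose d_XY(P2,P3)
    is below the mean over all windows with a defined d_XY.

    Returns a copy of ``stats`` with boolean columns ``fd_pass`` and
    ``flagged`` plus attrs ``fd_threshold`` and ``mean_dxy``.
    """
    out = stats.reset_index(drop=True).copy()
    fd = out["fd"].to_numpy(dtype=float)
    defined = ~np.isnan(fd)
    n_defined = int(defined.sum())
    if n_defined == 0:
        raise ValueError("no windows with defined fd")
    k = math.ceil(quantile * n_defined)

    # stable sort on -fd keeps genomic order among ties
    idx_def = np.flatnonzero(defined)
    order = idx_def[np.argsort(-fd[idx_def], kind="stable")]
    top = order[:k]
    fd_pass = np.zeros(len(out), dtype=bool)
    fd_pass[top] = True
    threshold = float(fd[top].min()) if k else np.nan

    dxy = out[dxy_col].to_numpy(dtype=float)
    mean_dxy = float(np.nanmean(dxy))
    flagged = fd_pass & (dxy < mean_dxy)

    out["fd_pass"] = fd_pass
    out["flagged"] = flagged
    out.attrs["fd_threshold"] = threshold
    out.attrs["mean_dxy"] = mean_dxy
    logger.info("flag_windows: %d/%d defined windows pass fd>=%.4g; "
                "%d also below mean dxy=%.4g",
                k, n_defined, threshold, int(flagged.sum()), mean_dxy)
    return out


def condense_blocks(flags: pd.DataFrame, min_run: int = DEFAULT_MIN_RUN,
                    max_gap: int = 0, triad_id: str = "") -> pd.DataFrame:
    """Condense runs of neighbouring flagged windows into blocks.

    Neighbouring means coordinate-adjacent (the end of one window is the
    start of the next, same chromosome); runs of at least ``min_run``
    flagged windows become blocks.  ``max_gap`` > 0 allows that many
    consecutive unflagged (but coordinate-adjacent) windows inside a run
    without breaking it; gap windows do not count toward ``min_run`` nor
    enter block means.

    Returns a table (chrom, start, end, n_windows, mean_fd, mean_dxy, triad).
    """
    df = flags.sort_values(["chrom", "start"]).reset_index(drop=True)
    blocks = []
    run: list[int] = []
    gap = 0

    def emit(run):
        if len(run) >= min_run:
            rows = df.loc[run]
            blocks.append({
                "chrom": rows["chrom"].iloc[0],
                "start": int(rows["start"].min()),
                "end": int(rows["end"].max()),
                "n_windows": len(run),
                "mean_fd": float(rows["fd"].mean()),
                "mean_dxy": float(rows[DXY_COL].mean()) if DXY_COL in rows else np.nan,
                "triad": triad_id,
            })

    prev = None
    for i, row in df.iterrows():
        adjacent = (prev is not None
                    and row["chrom"] == prev["chrom"]
                    and row["start"] == prev["end"])
        if row["flagged"]:
            if run and adjacent and gap <= max_gap:
                run.append(i)
            else:
                emit(run)
                run = [i]
            gap = 0
        else:
            if not adjacent:
                emit(run)
                run = []
            gap = gap + 1 if run else 0
            if run and gap > max_gap:
                emit(run)
                run = []
        prev = row
    emit(run)
    res = pd.DataFrame(blocks, columns=["chrom", "start", "end", "n_windows",
                                        "mean_fd", "mean_dxy", "triad"])
    logger.info("condense_blocks: %d blocks (min_run=%d, max_gap=%d), "
                "total introgressed length %d bp",
                len(res), min_run, max_gap, int((res["end"] - res["start"]).sum()) if len(res) else 0)
    return res


def annotate_blocks(blocks: pd.DataFrame, genes) -> pd.DataFrame:
    """Count genes overlapping each block by ≥ 1 base (half-open intervals).

    ``genes`` is a list of :class:`triadscan.io.Gene`.  Adds a
    ``gene_count`` column and a ``gene_ids`` comma-joined column.
    """
    from intervaltree import IntervalTree

    trees: dict = {}
    for g in genes:
        if g.end > g.start:
            trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.gid)

    counts, ids = [], []
    for _, b in blocks.iterrows():
        tree = trees.get(b["chrom"])
        hits = sorted(iv.data for iv in tree.overlap(b["start"], b["end"])) if tree else []
        counts.append(len(hits))
        ids.append(",".join(hits))
    out = blocks.copy()
    out["gene_count"] = counts
    out["gene_ids"] = ids
    return out


def introgressed_length(blocks: pd.DataFrame) -> int:
    """Total introgressed span (bp) — blocks are disjoint by construction."""
    return int((blocks["end"] - blocks["start"]).sum()) if len(blocks) else 0


def compare_divergence_distributions(dxy_groups: dict):
    """Kruskal–Wallis rank test across labeled d_XY window-value groups.

    Returns ``(H, p)``.  If every value in every group is identical the
    test is undefined; returns ``(0.0, 1.0)`` with a warning.
    """
    groups = [np.asarray(v, dtype=float) for v in dxy_groups.values()]
    groups = [g[~np.isnan(g)] for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    flat = np.concatenate(groups)
    if np.all(flat == flat[0]):
        warnings.warn("all divergence values identical across groups; p set to 1")
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def write_blocks_bed(blocks: pd.DataFrame, path) -> None:
    """Write blocks as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for _, b in blocks.iterrows():
            name = b["triad"] or "block"
            fh.write(f"{b['chrom']}\t{b['start']}\t{b['end']}\t{name}\t"
                     f"{b['mean_fd']:.6g}\t.\n")
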