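"""DMR calling: maximal runs of contiguous differential CpG probes.

A differentially methylated region (DMR) is a maximal run of at least
``min_run`` consecutive array probes — consecutive in genomic order on
one chromosome — each satisfying the per-probe rule ``delta >= delta_min``
(or ``delta <= -delta_min`` for hypomethylated DMRs).  "Maximal" means
the run cannot be extended by one probe in either direction.  Runs never
span chromosomes; a gap between consecutive probes larger than
``max_gap`` bp (default unlimited) also breaks a run.  A manifest probe
with no delta value counts as failing and breaks contiguity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import PeakSet

__all__ = ["DMR", "call_dmrs", "dmr_conservation", "dmr_gene_content",
           "dmrs_to_bed"]


@dataclass
class DMR:
    chrom: str
    start: int           # position of first probe
    end: int             # last probe position + 1 (half-open)
    probe_ids: list[str]
    mean_delta: float

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)


def call_dmrs(track: pd.DataFrame, manifest: pd.DataFrame,
              min_run: int = 8, delta_min: float = 0.2,
              max_gap: float = math.inf,
              direction: str = "hyper") -> list[DMR]:
    """Scan probes in genomic order and emit maximal qualifying runs.

    Parameters
    ----------
    track
        Delta-beta table indexed by probe_id (column ``delta``).
    manifest
        Probe manifest (probe_id, chrom, pos); sorted internally.
    direction
        ``hyper`` tests delta >= delta_min (the default; matches how the
        regions are defined in SETD2-loss studies); ``hypo`` tests
        delta <= -delta_min.
    """
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    if direction not in ("hyper", "hypo"):
        raise ValueError(f"direction must be hyper or hypo: {direction!r}")
    man = manifest[["probe_id", "chrom", "pos"]].copy()
    man = man.sort_values(["chrom", "pos"], kind="mergesort")
    if man.duplicated(["chrom", "pos"]).any():
        d = man[man.duplicated(["chrom", "pos"])].iloc[0]
        raise ValueError(f"duplicate probe position {d['chrom']}:{d['pos']}")
    delta = track["delta"].reindex(man["probe_id"]).to_numpy()
    if direction == "hyper":
        passing = delta >= delta_min
    else:
        passing = delta <= -delta_min
    passing &= ~np.isnan(delta)

    chrom = man["chrom"].to_numpy()
    pos = man["pos"].to_numpy()
    probe_ids = man["probe_id"].to_numpy()

    dmrs: list[DMR] = []
    i = 0
    n = len(man)
    while i < n:
        if not passing[i]:
            i += 1
            continue
        j = i
        while (j + 1 < n and passing[j + 1] and chrom[j + 1] == chrom[j]
               and pos[j + 1] - pos[j] <= max_gap):
            j += 1
        if j - i + 1 >= min_run:
            ids = list(probe_ids[i:j + 1])
            dmrs.append(DMR(
                chrom=str(chrom[i]), start=int(pos[i]), end=int(pos[j]) + 1,
                probe_ids=ids,
                mean_delta=float(np.mean(delta[i:j + 1])),
            ))
        i = j + 1
    return dmrs


def dmr_conservation(dmrs_a: list[DMR], dmrs_b: list[DMR],
                     criterion: str = "probe",
                     min_fraction: float = 0.0) -> float | None:
    """Fraction of DMRs in *a* that recur in *b*.

    ``criterion='probe'`` (default): a DMR is conserved when it shares at
    least one probe with some DMR of *b* (or at least ``min_fraction`` of
    its probes when that is set).  ``criterion='bp'``: >=1 bp interval
    overlap.  Returns ``None`` (undefined) when *a* is empty — distinct
    from a genuine 0.0.
    """
    if not dmrs_a:
        return None
    if criterion == "probe":
        b_probes = set(p for d in dmrs_b for p in d.probe_ids)
        hits = 0
        for d in dmrs_a:
            shared = sum(p in b_probes for p in d.probe_ids)
            need = max(1, math.ceil(min_fraction * d.n_probes))
            hits += shared >= need
        return hits / len(dmrs_a)
    if criterion == "bp":
        a_set = PeakSet.from_arrays([d.chrom for d in dmrs_a],
                                    [d.start for d in dmrs_a],
                                    [d.end for d in dmrs_a])
        b_set = PeakSet.from_arrays([d.chrom for d in dmrs_b],
                                    [d.start for d in dmrs_b],
                                    [d.end for d in dmrs_b]) \
            if dmrs_b else PeakSet()
        # a_set is sorted; recompute hit count on sorted order
        return float(a_set.overlaps_intervals(b_set).mean())
    raise ValueError(f"unknown criterion: {criterion!r}")


def dmr_gene_content(dmrs: list[DMR], genes: pd.DataFrame,
                     tiers: pd.Series | None = None,
                     fold_change: pd.Series | None = None,
                     fc_threshold: float = 2.0) -> pd.DataFrame:
    """Genes whose span intersects each DMR, with expression context.

    Returns one row per (DMR, gene) pair with the gene's expression tier
    and fold-change class (``up`` / ``down`` / ``flat`` / NA), so a DMR in
    a gene desert contributes no rows.
    """
    rows = []
    for k, d in enumerate(dmrs):
        sub = genes[(genes["chrom"] == d.chrom) & (genes["start"] < d.end)
                    & (genes["end"] > d.start)]
        for gene_id in sub.index:
            fc = None if fold_change is None else fold_change.get(gene_id)
            if fc is None or pd.isna(fc):
                fc_class = None
            elif fc >= fc_threshold:
                fc_class = "up"
            elif fc <= 1.0 / fc_threshold:
                fc_class = "down"
            else:
                fc_class = "flat"
            rows.append({
                "dmr_index": k, "chrom": d.chrom, "start": d.start,
                "end": d.end, "n_probes": d.n_probes,
                "mean_delta": d.mean_delta, "gene_id": gene_id,
                "tier": None if tiers is None else tiers.get(gene_id),
                "fold_change": fc, "fc_class": fc_class,
            })
    return pd.DataFrame(rows, columns=[
        "dmr_index", "chrom", "start", "end", "n_probes", "mean_delta",
        "gene_id", "tier", "fold_change", "fc_class"])


def dmrs_to_bed(dmrs: list[DMR], path) -> None:
    """Write DMRs as BED6: name = probe count, score = 1000 x mean delta."""
    with open(path, "w") as fh:
        for d in dmrs:
            fh.write(f"{d.chrom}\t{d.start}\t{d.end}\t{d.n_probes}\t"
                     f"{1000 * d.mean_delta:.0f}\t.\n")
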