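"""Genomic interval sets with BED semantics.

All coordinates are 0-based half-open ``[start, end)``.  A :class:`PeakSet`
holds the intervals of one histone mark in one sample/condition; after
:meth:`PeakSet.merge` the intervals are sorted by (chrom, start) and
non-overlapping, which is the normal form every downstream overlap
computation assumes.
"""

from __future__ import annotations

import gzip
import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd
import pyranges as pr

__all__ = ["GenomicInterval", "PeakSet", "read_bed", "BedParseError"]

PathLike = Union[str, Path]


class BedParseError(ValueError):
    """Raised when a BED line cannot be parsed; carries the line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """One half-open genomic interval, optionally scored."""

    chrom: str
    start: int
    end: int
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start


class PeakSet:
    """A set of genomic intervals for one mark/condition.

    Parameters
    ----------
    df
        DataFrame with columns ``Chromosome``, ``Start``, ``End`` and
        optionally ``Score``.
    """

    def __init__(self, df: pd.DataFrame | None = None):
        if df is None or len(df) == 0:
            df = pd.DataFrame(
                {"Chromosome": pd.Series(dtype=str),
                 "Start": pd.Series(dtype=np.int64),
                 "End": pd.Series(dtype=np.int64)}
            )
        df = df.copy()
        df["Chromosome"] = df["Chromosome"].astype(str)
        df["Start"] = df["Start"].astype(np.int64)
        df["End"] = df["End"].astype(np.int64)
        if (df["Start"] < 0).any() or (df["End"] <= df["Start"]).any():
            bad = df[(df["Start"] < 0) | (df["End"] <= df["Start"])].iloc[0]
            raise ValueError(
                "invalid interval "
                f"{bad['Chromosome']}:{bad['Start']}-{bad['End']}"
            )
        self.df = df.sort_values(
            ["Chromosome", "Start", "End"], kind="mergesort"
        ).reset_index(drop=True)

    # -- constructors -------------------------------------------------
    @classmethod
    def from_intervals(cls, intervals: Iterable[GenomicInterval]) -> "PeakSet":
        rows = [(iv.chrom, iv.start, iv.end, iv.score) for iv in intervals]
        if not rows:
            return cls()
        df = pd.DataFrame(rows, columns=["Chromosome", "Start", "End", "Score"])
        if df["Score"].isna().all():
            df = df.drop(columns="Score")
        return cls(df)

    @classmethod
    def from_arrays(cls, chroms, starts, ends, scores=None) -> "PeakSet":
        data = {"Chromosome": chroms, "Start": starts, "End": ends}
        if scores is not None:
            data["Score"] = scores
        return cls(pd.DataFrame(data))

    # -- basics -------------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        score_col = "Score" if "Score" in self.df.columns else None
        for row in self.df.itertuples(index=False):
            score = getattr(row, score_col) if score_col else None
            yield GenomicInterval(row.Chromosome, row.Start, row.End, score)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        a = self.df[["Chromosome", "Start", "End"]]
        b = other.df[["Chromosome", "Start", "End"]]
        return a.equals(b)

    @property
    def chroms(self) -> list[str]:
        return sorted(self.df["Chromosome"].unique())

    def total_bp(self) -> int:
        """Total base pairs covered, counting overlaps once."""
        return int((self.merge().df["End"] - self.merge().df["Start"]).sum())

    def _pr(self) -> pr.PyRanges:
        return pr.PyRanges(self.df[["Chromosome", "Start", "End"]])

    @staticmethod
    def _from_pr(g: pr.PyRanges) -> "PeakSet":
        df = g.df if len(g) else None
        if df is not None:
            df = df[["Chromosome", "Start", "End"]]
        return PeakSet(df)

    # -- set algebra (bp-level) ---------------------------------------
    def merge(self) -> "PeakSet":
        """Union of the intervals themselves: sorted, non-overlapping.

        Book-ended intervals (end == next start) are joined, consistent
        with half-open union semantics.
        """
        if len(self) == 0:
            return PeakSet()
        return self._from_pr(self._pr().merge())

    def union(self, other: "PeakSet") -> "PeakSet":
        both = pd.concat(
            [self.df[["Chromosome", "Start", "End"]],
             other.df[["Chromosome", "Start", "End"]]],
            ignore_index=True,
        )
        return PeakSet(both).merge()

    def intersect(self, other: "PeakSet") -> "PeakSet":
        if len(self) == 0 or len(other) == 0:
            return PeakSet()
        return self._from_pr(
            self._pr().merge().intersect(other._pr().merge())
        ).merge()

    def subtract(self, other: "PeakSet") -> "PeakSet":
        if len(self) == 0:
            return PeakSet()
        if len(other) == 0:
            return self.merge()
        return self._from_pr(
            self._pr().merge().subtract(other._pr().merge())
        ).merge()

    # -- point queries ------------------------------------------------
    def contains_points(self, chroms, positions) -> np.ndarray:
        """Boolean membership of bp positions (vectorised).

        Works on the merged form, where membership reduces to a
        searchsorted parity test per chromosome.
        """
        chroms = np.asarray(chroms, dtype=object)
        positions = np.asarray(positions, dtype=np.int64)
        out = np.zeros(len(positions), dtype=bool)
        merged = self.merge().df
        for chrom, sub in merged.groupby("Chromosome", sort=False):
            sel = chroms == chrom
            if not sel.any():
                continue
            starts = sub["Start"].to_numpy()
            ends = sub["End"].to_numpy()
            idx = np.searchsorted(starts, positions[sel], side="right") - 1
            ok = idx >= 0
            hit = np.zeros(sel.sum(), dtype=bool)
            hit[ok] = positions[sel][ok] < ends[idx[ok]]
            out[sel] = hit
        return out

    def covered_bp(self, chroms, starts, ends) -> np.ndarray:
        """bp of each query interval covered by this set (vectorised).

        Queries are half-open ``[start, end)`` arrays; coverage is
        computed against the merged form of the set.
        """
        chroms = np.asarray(chroms, dtype=object)
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        out = np.zeros(len(starts), dtype=np.int64)
        merged = self.merge().df
        for chrom, sub in merged.groupby("Chromosome", sort=False):
            sel = chroms == chrom
            if not sel.any():
                continue
            S = sub["Start"].to_numpy()
            E = sub["End"].to_numpy()
            C = np.concatenate([[0], np.cumsum(E - S)])
            a, b = starts[sel], ends[sel]
            i0 = np.searchsorted(E, a, side="right")
            i1 = np.searchsorted(S, b, side="left") - 1
            res = np.zeros(len(a), dtype=np.int64)
            ok = i0 <= i1
            if ok.any():
                total = C[i1[ok] + 1] - C[i0[ok]]
                clip_left = np.maximum(a[ok] - S[i0[ok]], 0)
                clip_right = np.maximum(E[i1[ok]] - b[ok], 0)
                res[ok] = total - clip_left - clip_right
            out[sel] = res
        return out

    def overlaps_intervals(self, other: "PeakSet") -> np.ndarray:
        """For each interval of *self*, whether it shares ≥1 bp with *other*."""
        if len(self) == 0:
            return np.zeros(0, dtype=bool)
        if len(other) == 0:
            return np.zeros(len(self), dtype=bool)
        out = np.zeros(len(self), dtype=bool)
        merged = other.merge().df
        for chrom, sub in merged.groupby("Chromosome", sort=False):
            sel = (self.df["Chromosome"] == chrom).to_numpy()
            if not sel.any():
                continue
            ostarts = sub["Start"].to_numpy()
            oends = sub["End"].to_numpy()
            s = self.df.loc[sel, "Start"].to_numpy()
            e = self.df.loc[sel, "End"].to_numpy()
            # merged intervals are disjoint and sorted, so starts and ends
            # are both increasing; the only candidate overlapping [s, e) is
            # the last interval starting before e
            i = np.searchsorted(ostarts, e, side="left") - 1
            ok = i >= 0
            hit = np.zeros(sel.sum(), dtype=bool)
            hit[ok] = oends[i[ok]] > s[ok]
            out[sel] = hit
        return out

    # -- io -----------------------------------------------------------
    def write_bed(self, path: PathLike) -> None:
        df = self.df
        with _open_text(path, "wt") as fh:
            for row in df.itertuples(index=False):
                fields = [row.Chromosome, str(row.Start), str(row.End)]
                if "Score" in df.columns and not pd.isna(getattr(row, "Score", None)):
                    fields += [".", f"{row.Score:g}"]
                fh.write("\t".join(fields) + "\n")

    def __repr__(self) -> str:
        return f"PeakSet({len(self)} intervals, {len(self.chroms)} chroms)"


def _open_text(path: PathLike, mode: str = "rt") -> _io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_bed(path: PathLike, merge: bool = False) -> PeakSet:
    """Read a BED3/BED5(+) file into a :class:`PeakSet`.

    Column 5, when present, is kept as the interval score.  Lines starting
    with ``track``, ``browser`` or ``#`` are skipped.  Malformed
    coordinates raise :class:`BedParseError` naming the offending line.
    """
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    scores: list[float] = []
    any_score = False
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinate"
                ) from exc
            if start < 0 or end <= start:
                raise BedParseError(
                    f"{path}:{lineno}: invalid interval "
                    f"{fields[0]}:{start}-{end}"
                )
            chroms.append(fields[0])
            starts.append(start)
            ends.append(end)
            if len(fields) >= 5:
                try:
                    scores.append(float(fields[4]))
                    any_score = True
                except ValueError:
                    scores.append(np.nan)
            else:
                scores.append(np.nan)
    ps = PeakSet.from_arrays(
        chroms, starts, ends, scores if any_score else None
    )
    return ps.merge() if merge else ps
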