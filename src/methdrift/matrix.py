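"""Genome-positioned CpG count containers.

A :class:`CpGCountMatrix` holds, for every CpG site, the methylated and
total read counts of every replicate of every experimental group.  Sites
are strand-collapsed (one record per CpG dyad) and kept sorted by
``(chrom, pos)`` with 0-based positions.  A total count of 0 for a
replicate at a site means the site was not covered in that replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GroupCounts", "CpGCountMatrix"]


@dataclass
class GroupCounts:
    """Per-replicate (methylated, total) read counts for one group at one unit.

    The unit may be a single CpG or a region whose member-CpG counts were
    summed per replicate.  Replicates with ``total == 0`` are allowed in a
    matrix but must be removed (or never present) before testing.
    """

    meth: np.ndarray
    total: np.ndarray

    def __post_init__(self) -> None:
        self.meth = np.asarray(self.meth, dtype=np.int64)
        self.total = np.asarray(self.total, dtype=np.int64)
        if self.meth.shape != self.total.shape or self.meth.ndim != 1:
            raise ValueError("meth and total must be 1-D arrays of equal length")
        if self.meth.size == 0:
            raise ValueError("a group needs at least one replicate")
        if np.any(self.total < 1):
            raise ValueError("every replicate total must be >= 1")
        if np.any(self.meth < 0) or np.any(self.meth > self.total):
            raise ValueError("need 0 <= meth <= total in every replicate")

    @property
    def n_replicates(self) -> int:
        return int(self.meth.size)


@dataclass
class CpGCountMatrix:
    """CpG-by-replicate count matrices for several groups on one coordinate frame.

    Attributes
    ----------
    chrom, pos
        Site coordinates, sorted by ``(chrom, pos)``; ``pos`` is the
        0-based CpG start.
    meth, total
        Per-group ``(n_sites, n_replicates)`` integer arrays.  ``total``
        entries of 0 mark replicates without coverage at that site.
    """

    chrom: np.ndarray
    pos: np.ndarray
    meth: dict[str, np.ndarray] = field(default_factory=dict)
    total: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if self.chrom.shape != self.pos.shape:
            raise ValueError("chrom and pos must have the same length")
        order = np.lexsort((self.pos, self.chrom))
        if not np.array_equal(order, np.arange(self.pos.size)):
            raise ValueError("sites must be sorted by (chrom, pos)")
        for g in self.meth:
            m, t = np.asarray(self.meth[g]), np.asarray(self.total[g])
            if m.shape != t.shape or m.shape[0] != self.pos.size:
                raise ValueError(f"count arrays for group {g!r} do not match site count")
            self.meth[g] = m.astype(np.int64)
            self.total[g] = t.astype(np.int64)

    @property
    def groups(self) -> list[str]:
        return list(self.meth)

    @property
    def n_sites(self) -> int:
        return int(self.pos.size)

    def group_counts(self, group: str, site_index: int) -> GroupCounts:
        """Counts of one group at one site, covered replicates only."""
        t = self.total[group][site_index]
        covered = t > 0
        if not covered.any():
            raise ValueError(f"site {site_index} has no coverage in group {group!r}")
        return GroupCounts(self.meth[group][site_index][covered], t[covered])

    def region_counts(self, group: str, site_indices: np.ndarray) -> GroupCounts:
        """Member-CpG counts summed per replicate over a region."""
        idx = np.asarray(site_indices)
        m = self.meth[group][idx].sum(axis=0)
        t = self.total[group][idx].sum(axis=0)
        covered = t > 0
        if not covered.any():
            raise ValueError("region has no covered replicate in group " + repr(group))
        return GroupCounts(m[covered], t[covered])

    @classmethod
    def from_samples(
        cls, samples: dict[str, list[pd.DataFrame]]
    ) -> "CpGCountMatrix":
        """Assemble a matrix from per-replicate coverage frames.

        Parameters
        ----------
        samples
            Mapping from group label to a list of frames with columns
            ``chrom``, ``pos``, ``meth``, ``total`` (one per replicate,
            e.g. from :func:`methdrift.io.read_coverage_file`).  Sites are
            aligned on the union of positions; missing sites get total 0.
        """
        keys = pd.concat(
            [df[["chrom", "pos"]] for reps in samples.values() for df in reps]
        ).drop_duplicates()
        keys = keys.sort_values(["chrom", "pos"]).reset_index(drop=True)
        index = pd.MultiIndex.from_frame(keys)
        meth: dict[str, np.ndarray] = {}
        total: dict[str, np.ndarray] = {}
        for group, reps in samples.items():
            m = np.zeros((len(keys), len(reps)), dtype=np.int64)
            t = np.zeros_like(m)
            for j, df in enumerate(reps):
                aligned = (
                    df.set_index(["chrom", "pos"])[["meth", "total"]]
                    .reindex(index, fill_value=0)
                )
                m[:, j] = aligned["meth"].to_numpy()
                t[:, j] = aligned["total"].to_numpy()
            meth[group] = m
            total[group] = t
        return cls(keys["chrom"].to_numpy(), keys["pos"].to_numpy(), meth, total)
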