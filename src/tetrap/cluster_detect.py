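"""Local-score detection of piRNA clusters from binned small-RNA coverage.

Uniquely mapping piRNA-sized reads are counted in fixed-size genomic bins
(500 bp by default), normalised to a million sequenced miRNAs, and each bin
is scored ``min(count, max_bin_score) - threshold``.  piRNA clusters are the
maximal positive-scoring runs of this score sequence in the sense of Ruzzo
and Tompa's all-maximal-scoring-subsequences decomposition, reported as
bin-aligned half-open intervals.  Capping the per-bin contribution keeps a
single extreme bin from stitching unrelated regions together; the threshold
sets the background level a cluster must exceed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .smallrna_stats import ppm_normalize

__all__ = [
    "BinnedCounts",
    "Cluster",
    "ClusterSet",
    "bin_reads",
    "maximal_scoring_subsequences",
    "local_score_segments",
    "cluster_summary",
]


@dataclass(frozen=True)
class BinnedCounts:
    """Per-arm, left-to-right tiling of fixed-size bins with ppm counts."""

    counts: dict[str, np.ndarray]
    binsize: int
    arm_lengths: dict[str, int]


@dataclass(frozen=True)
class Cluster:
    """One detected piRNA cluster (bin-aligned, half-open, score > 0)."""

    arm: str
    start: int
    end: int
    score: float


@dataclass(frozen=True)
class ClusterSet:
    """Detected clusters plus their total genomic extent."""

    clusters: tuple[Cluster, ...]

    @property
    def total_bp(self) -> int:
        return sum(c.end - c.start for c in self.clusters)

    def to_bed(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (c.arm, c.start, c.end, f"cluster_{i+1}", f"{c.score:.3f}")
                for i, c in enumerate(self.clusters)
            ],
            columns=["chrom", "start", "end", "name", "score"],
        )


def bin_reads(
    reads: pd.DataFrame,
    arm_lengths: dict[str, int],
    binsize: int = 500,
    mirna_total: float = 1e6,
) -> BinnedCounts:
    """Count read 5' ends in fixed bins and normalise to ppm.

    Each read is assigned to the bin containing its 5' position (half-open
    bins, so positions 0..binsize-1 share bin 0).  Reads on references not
    in ``arm_lengths`` or beyond the stated arm length are an input error.
    """
    if binsize <= 0:
        raise ValueError("binsize must be > 0")
    if mirna_total <= 0:
        raise ValueError("miRNA total must be > 0")
    counts: dict[str, np.ndarray] = {}
    for arm, length in arm_lengths.items():
        nbins = -(-int(length) // binsize)  # ceil
        counts[arm] = np.zeros(nbins, dtype=float)
    for arm, grp in reads.groupby("reference", sort=False):
        if arm not in counts:
            raise ValueError(f"reads on unknown reference {arm!r}")
        pos = grp["pos5"].to_numpy(dtype=np.int64)
        if pos.size and (pos.min() < 0 or pos.max() >= arm_lengths[arm]):
            raise ValueError(f"read position outside arm {arm!r}")
        binned = np.bincount(
            pos // binsize, weights=grp["count"].to_numpy(dtype=float),
            minlength=counts[arm].size,
        )
        counts[arm] += binned
    counts = {a: ppm_normalize(c, mirna_total) for a, c in counts.items()}
    return BinnedCounts(counts=counts, binsize=binsize,
                        arm_lengths={a: int(v) for a, v in arm_lengths.items()})


def maximal_scoring_subsequences(scores) -> list[tuple[int, int, float]]:
    """All maximal-scoring subsequences of a score sequence (Ruzzo-Tompa).

    Returns disjoint half-open index ranges ``(start, end, score)`` in
    left-to-right order; every returned score is positive.  A subsequence
    is maximal when no proper sub- or supersequence achieves at least its
    score (under the standard disjoint decomposition).
    """
    stack: list[list] = []  # entries [start, end, L, R] with cumulative sums
    cum = 0.0
    for i, x in enumerate(scores):
        x = float(x)
        cum += x
        if x <= 0:
            continue
        cur = [i, i + 1, cum - x, cum]
        while True:
            j = len(stack) - 1
            while j >= 0 and stack[j][2] >= cur[2]:
                j -= 1
            if j < 0 or stack[j][3] >= cur[3]:
                stack.append(cur)
                break
            cur = [stack[j][0], cur[1], stack[j][2], cur[3]]
            del stack[j:]
    return [(s, e, r - l) for s, e, l, r in stack]


def local_score_segments(
    bins: BinnedCounts,
    threshold: float = 10.0,
    max_bin_score: float = 100.0,
    merge_gap: int = 0,
) -> ClusterSet:
    """piRNA clusters as maximal positive-score runs of capped bin counts.

    Per-bin score is ``min(ppm_count, max_bin_score) - threshold``; the
    Ruzzo-Tompa decomposition of that sequence yields the clusters, each a
    bin-aligned interval clipped to its arm.  ``merge_gap`` > 0 additionally
    joins neighbouring clusters separated by at most that many bp (their
    scores are summed); by default no merging is applied.
    """
    out: list[Cluster] = []
    for arm in bins.counts:
        score = np.minimum(bins.counts[arm], max_bin_score) - threshold
        segs = maximal_scoring_subsequences(score)
        arm_len = bins.arm_lengths[arm]
        arm_clusters = [
            Cluster(
                arm=arm,
                start=s * bins.binsize,
                end=min(e * bins.binsize, arm_len),
                score=float(sc),
            )
            for s, e, sc in segs
        ]
        if merge_gap > 0 and arm_clusters:
            merged = [arm_clusters[0]]
            for c in arm_clusters[1:]:
                last = merged[-1]
                if c.start - last.end <= merge_gap:
                    merged[-1] = Cluster(arm, last.start, c.end, last.score + c.score)
                else:
                    merged.append(c)
            arm_clusters = merged
        out.extend(arm_clusters)
    return ClusterSet(clusters=tuple(out))


def cluster_summary(clusters: ClusterSet, genome_size: int) -> tuple[int, float]:
    """Total cluster extent in bp and as a percentage of the genome."""
    if genome_size <= 0:
        raise ValueError("genome size must be > 0")
    total = clusters.total_bp
    return total, 100.0 * total / genome_size
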