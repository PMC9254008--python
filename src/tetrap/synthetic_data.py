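"""Synthetic inputs with known ground truth for every pipeline stage.

These generators emulate the tables a TE-invasion study derives from
sequencing data -- copy-number trajectories, small-RNA 5'-position tables,
insertion BED files and gonadal-dysgenesis ovary counts -- with planted,
machine-readable truth so every downstream estimator has a recovery test.
Each generator returns ``(data, truth)``; the CLI writes the data next to a
``.truth.json`` sidecar.  Identical seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TrajectoryConfig",
    "ReadsConfig",
    "InsertionsConfig",
    "GDConfig",
    "gen_trajectory",
    "gen_pirna_reads",
    "gen_insertions",
    "gen_gd_counts",
]


@dataclass(frozen=True)
class TrajectoryConfig:
    """Geometric-growth copy-number trajectory with a hard plateau.

    Copies per haploid follow n_g = n0*(1+u)^g up to ``plateau_generation``
    and stay at the plateau value afterwards; observations carry
    multiplicative lognormal noise of coefficient of variation ``noise_cv``
    (mean-one, so the expectation is unbiased).  Defaults mirror a hot
    P-element invasion: u = 0.154 from 0.86 copies per haploid, sampled
    every 10 generations.
    """

    u: float = 0.154
    n0: float = 0.86
    generations: int = 60
    plateau_generation: int = 20
    sampling_interval: int = 10
    replicates: int = 3
    noise_cv: float = 0.05

    def __post_init__(self) -> None:
        if self.u <= -1:
            raise ValueError("growth rate u must be > -1")
        if self.n0 <= 0:
            raise ValueError("initial copy number must be > 0")
        if self.noise_cv < 0 or self.sampling_interval < 1 or self.replicates < 1:
            raise ValueError("invalid trajectory config")


def gen_trajectory(
    cfg: TrajectoryConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, dict]:
    """Sampled copy-number observations plus their generating truth."""
    gens = np.arange(0, cfg.generations + 1, cfg.sampling_interval)
    expected = cfg.n0 * (1.0 + cfg.u) ** np.minimum(gens, cfg.plateau_generation)
    rows = []
    for rep in range(cfg.replicates):
        if cfg.noise_cv > 0:
            sigma = np.sqrt(np.log1p(cfg.noise_cv**2))
            noise = rng.lognormal(-0.5 * sigma**2, sigma, size=gens.size)
        else:
            noise = np.ones(gens.size)
        for g, n in zip(gens, expected * noise):
            rows.append({"replicate": rep, "generation": int(g),
                         "copies_per_haploid": float(n)})
    df = pd.DataFrame(rows)
    truth = {"u": cfg.u, "n0": cfg.n0, "plateau_generation": cfg.plateau_generation,
             "noise_cv": cfg.noise_cv, "sampling_interval": cfg.sampling_interval}
    return df, truth


@dataclass(frozen=True)
class ReadsConfig:
    """Small-RNA 5'-position table with planted ping-pong and cluster signal.

    Background reads fall uniformly on both strands of the reference (or
    concentrated into ``cluster_intervals`` at the given fold-densities); a
    ``pingpong_fraction`` of all reads is emitted as sense/antisense pairs
    whose 5' ends overlap by exactly 10 nt.  Read lengths are uniform on
    the piRNA range 23-29 nt.  ``mirna_total`` is recorded for downstream
    ppm normalisation.  The default reference is P-element-sized (2907 bp).
    """

    reference: str = "PPI251"
    ref_length: int = 2907
    total_reads: int = 20_000
    pingpong_fraction: float = 0.0
    cluster_intervals: tuple[tuple[int, int], ...] = ()
    cluster_densities: tuple[float, ...] = ()
    mirna_total: float = 1e6
    min_len: int = 23
    max_len: int = 29

    def __post_init__(self) -> None:
        if not 0 <= self.pingpong_fraction <= 1:
            raise ValueError("ping-pong fraction must be in [0, 1]")
        if len(self.cluster_intervals) != len(self.cluster_densities):
            raise ValueError("one density per planted cluster interval required")
        if any(d < 0 for d in self.cluster_densities):
            raise ValueError("cluster densities must be >= 0")
        for s, e in self.cluster_intervals:
            if not 0 <= s < e <= self.ref_length:
                raise ValueError(f"planted cluster [{s},{e}) outside reference")
        if self.ref_length < 10 or self.total_reads < 0:
            raise ValueError("invalid reads config")


def _piecewise_positions(
    n: int,
    ref_length: int,
    intervals: tuple[tuple[int, int], ...],
    densities: tuple[float, ...],
    rng: np.random.Generator,
) -> np.ndarray:
    """Positions from a piecewise-uniform density (fold-change in intervals)."""
    lens = np.array([e - s for s, e in intervals], dtype=float)
    outside = ref_length - lens.sum()
    mass = np.concatenate(([outside], lens * np.asarray(densities, dtype=float)))
    probs = mass / mass.sum()
    comp = rng.choice(len(mass), size=n, p=probs)
    pos = np.empty(n, dtype=np.int64)
    bg = comp == 0
    # uniform over the complement of the planted intervals
    gaps = []
    cursor = 0
    for s, e in sorted(intervals):
        if s > cursor:
            gaps.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < ref_length:
        gaps.append((cursor, ref_length))
    if bg.any():
        gap_lens = np.array([e - s for s, e in gaps], dtype=float)
        gi = rng.choice(len(gaps), size=int(bg.sum()), p=gap_lens / gap_lens.sum())
        offs = rng.random(int(bg.sum()))
        starts = np.array([s for s, _ in gaps])
        pos[bg] = (starts[gi] + offs * gap_lens[gi]).astype(np.int64)
    for k, (s, e) in enumerate(intervals):
        sel = comp == k + 1
        pos[sel] = rng.integers(s, e, size=int(sel.sum()))
    return pos


def gen_pirna_reads(
    cfg: ReadsConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, dict]:
    """Read table with planted ping-pong pairs and/or cluster enrichment."""
    n_pairs = int(round(cfg.total_reads * cfg.pingpong_fraction / 2))
    n_bg = cfg.total_reads - 2 * n_pairs

    recs = []
    if n_pairs:
        # sense 5' s, antisense 5' a = s + 9 => overlap d = a - s + 1 = 10
        s = rng.integers(0, cfg.ref_length - 10, size=n_pairs)
        recs.append((s, np.full(n_pairs, "+")))
        recs.append((s + 9, np.full(n_pairs, "-")))
    if n_bg:
        if cfg.cluster_intervals:
            pos = _piecewise_positions(
                n_bg, cfg.ref_length, cfg.cluster_intervals,
                cfg.cluster_densities, rng,
            )
        else:
            pos = rng.integers(0, cfg.ref_length, size=n_bg)
        strand = np.where(rng.integers(0, 2, size=n_bg) == 0, "+", "-")
        recs.append((pos, strand))

    all_pos = np.concatenate([p for p, _ in recs]) if recs else np.zeros(0, np.int64)
    all_strand = np.concatenate([s for _, s in recs]) if recs else np.zeros(0, "U1")
    lengths = rng.integers(cfg.min_len, cfg.max_len + 1, size=all_pos.size)
    df = pd.DataFrame(
        {
            "reference": cfg.reference,
            "pos5": all_pos.astype(np.int64),
            "strand": all_strand,
            "length": lengths,
            "count": 1,
        }
    )
    df = (
        df.groupby(["reference", "pos5", "strand", "length"], as_index=False)["count"]
        .sum()
        .sort_values(["reference", "pos5", "strand", "length"])
        .reset_index(drop=True)
    )
    truth = {
        "reference": cfg.reference,
        "ref_length": cfg.ref_length,
        "total_reads": cfg.total_reads,
        "pingpong_fraction": cfg.pingpong_fraction,
        "cluster_intervals": [list(iv) for iv in cfg.cluster_intervals],
        "cluster_densities": list(cfg.cluster_densities),
        "mirna_total": cfg.mirna_total,
    }
    return df, truth


@dataclass(frozen=True)
class InsertionsConfig:
    """TE insertion positions with planted per-feature enrichment.

    Each insertion falls into feature i with probability e_i * f_i (f_i the
    genomic fraction of the feature), so the measured enrichment o/(f*t)
    recovers e_i in expectation.  Defaults plant a 5.9-fold enrichment in a
    1% feature, the scale of telomere-associated-sequence enrichment.
    """

    genome_size: int = 1_000_000
    chrom: str = "genome"
    features: tuple[tuple[int, int], ...] = ((0, 10_000),)
    enrichments: tuple[float, ...] = (5.9,)
    total_insertions: int = 10_000

    def __post_init__(self) -> None:
        if len(self.features) != len(self.enrichments):
            raise ValueError("one target enrichment per feature required")
        if any(e < 0 for e in self.enrichments):
            raise ValueError("target enrichments must be >= 0")
        prev = 0
        for s, e in sorted(self.features):
            if not (0 <= s < e <= self.genome_size) or s < prev:
                raise ValueError("features must be disjoint and inside the genome")
            prev = e
        p = sum(
            e * (iv[1] - iv[0]) / self.genome_size
            for e, iv in zip(self.enrichments, self.features)
        )
        if p > 1:
            raise ValueError(
                f"infeasible config: implied feature probability {p:.3f} > 1"
            )


def gen_insertions(
    cfg: InsertionsConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, dict]:
    """BED-like frame of point insertions with planted feature enrichment."""
    fracs = np.array(
        [(e - s) / cfg.genome_size for s, e in cfg.features], dtype=float
    )
    p_feat = np.asarray(cfg.enrichments, dtype=float) * fracs
    # categorical sampling: feature i w.p. e_i*f_i, else the complement
    probs = np.concatenate((p_feat, [1.0 - p_feat.sum()]))
    comp = rng.choice(len(probs), size=cfg.total_insertions, p=probs)
    pos = np.empty(cfg.total_insertions, dtype=np.int64)
    for k, (s, e) in enumerate(cfg.features):
        sel = comp == k
        pos[sel] = rng.integers(s, e, size=int(sel.sum()))
    bg = comp == len(cfg.features)
    if bg.any():
        gaps = []
        cursor = 0
        for s, e in sorted(cfg.features):
            if s > cursor:
                gaps.append((cursor, s))
            cursor = max(cursor, e)
        if cursor < cfg.genome_size:
            gaps.append((cursor, cfg.genome_size))
        gap_lens = np.array([e - s for s, e in gaps], dtype=float)
        gi = rng.choice(len(gaps), size=int(bg.sum()), p=gap_lens / gap_lens.sum())
        starts = np.array([s for s, _ in gaps])
        pos[bg] = (starts[gi] + rng.random(int(bg.sum())) * gap_lens[gi]).astype(
            np.int64
        )
    pos.sort()
    df = pd.DataFrame(
        {
            "chrom": cfg.chrom,
            "start": pos,
            "end": pos + 1,
            "name": [f"ins_{i+1}" for i in range(pos.size)],
            "score": ".",
        }
    )
    truth = {
        "genome_size": cfg.genome_size,
        "features": [list(iv) for iv in cfg.features],
        "enrichments": list(cfg.enrichments),
        "feature_fractions": fracs.tolist(),
        "total_insertions": cfg.total_insertions,
    }
    return df, truth


@dataclass(frozen=True)
class GDConfig:
    """Multinomial ovary classification for a gonadal-dysgenesis assay."""

    p_normal: float = 0.8
    p_intermediate: float = 0.1
    p_dysgenic: float = 0.1
    n_ovaries: int = 200
    samples: int = 1

    def __post_init__(self) -> None:
        probs = (self.p_normal, self.p_intermediate, self.p_dysgenic)
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("class probabilities must be >= 0 and sum to 1")
        if self.n_ovaries < 1 or self.samples < 1:
            raise ValueError("need at least one ovary and one sample")


def gen_gd_counts(cfg: GDConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, dict]:
    """Ovary count table (one row per assayed sample)."""
    draws = rng.multinomial(
        cfg.n_ovaries, (cfg.p_normal, cfg.p_intermediate, cfg.p_dysgenic),
        size=cfg.samples,
    )
    df = pd.DataFrame(draws, columns=["normal", "intermediate", "dysgenic"])
    df.insert(0, "sample", [f"s{i+1}" for i in range(cfg.samples)])
    truth = {
        "p_normal": cfg.p_normal,
        "p_intermediate": cfg.p_intermediate,
        "p_dysgenic": cfg.p_dysgenic,
        "expected_gd_percent": 100.0 * (cfg.p_dysgenic + cfg.p_intermediate / 2.0),
        "n_ovaries": cfg.n_ovaries,
    }
    return df, truth
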