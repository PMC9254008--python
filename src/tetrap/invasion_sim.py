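"""Forward Wright-Fisher simulation of a TE invasion under the trap model.

The trap model posits that a transposable-element (TE) invasion proceeds
until copies of the TE jump into piRNA clusters -- discrete genomic loci
whose transcripts are processed into piRNAs.  A single cluster insertion per
diploid individual is taken to be biochemically sufficient to silence the TE
family in that individual.  The simulator implements this model for a
diploid, panmictic, constant-size population with non-overlapping
generations:

* The genome is a set of chromosome arms laid end to end on a single 0-based
  coordinate axis; designated half-open intervals act as piRNA clusters.
* Each individual carries two haplotypes, each a set of insertion positions.
* Fitness is linear in copy number, ``w = max(0, 1 - sum of effects)`` over
  *non-cluster* insertions (cluster insertions are treated as neutral, which
  avoids a transposition-selection-cluster balance).  Effects are either a
  constant ``x`` per insertion or drawn from a discrete distribution.
* Parents are sampled with replacement proportionally to fitness
  (monoecious, selfing allowed).  Gametes recombine with a uniform rate
  (Poisson crossovers per arm; arms assort independently).
* In the zygote, every non-cluster insertion spawns a new copy with
  probability ``u`` (or the residual rate ``u_r`` if the zygote carries a
  cluster insertion); new copies land uniformly on the genome and may
  themselves hit a cluster.

Two code paths produce gametes and offspring: the scalar operations
(:func:`make_gamete`, :func:`transpose`) act on a single :class:`Diploid`
and state the model one individual at a time, while :func:`step_generation`
advances the whole population with vectorised array operations.  Both follow
the same probabilistic model; the scalar path is the readable reference and
the vectorised path is what :func:`run_invasion` executes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "InvalidLayoutError",
    "PopulationCollapseError",
    "GenomeLayout",
    "build_genome",
    "standard_layout",
    "Selection",
    "SimParams",
    "Population",
    "Diploid",
    "Haplotype",
    "initialize_population",
    "fitness",
    "make_gamete",
    "transpose",
    "step_generation",
    "population_stats",
    "run_invasion",
    "run_replicates",
    "TRAJECTORY_COLUMNS",
]


class InvalidLayoutError(ValueError):
    """A genome layout violates its own geometry (e.g. cluster exceeds arm)."""


class PopulationCollapseError(RuntimeError):
    """Every individual has fitness zero; no parent can be drawn."""


# ---------------------------------------------------------------------------
# genome layout
# ---------------------------------------------------------------------------

class GenomeLayout:
    """Chromosome arms with piRNA-cluster intervals and a uniform recombination rate.

    Parameters
    ----------
    arm_lengths
        Length of each arm in bp.
    cluster_intervals
        Per arm, a list of half-open ``(start, end)`` intervals in local arm
        coordinates that act as piRNA clusters.  Intervals must lie within
        their arm and must not overlap.
    recombination_rate
        Uniform rate in cM/Mb.
    arm_names
        Optional arm names; defaults to ``chr1 .. chrK``.

    Notes
    -----
    Arms are concatenated on a single global axis, so an insertion position
    is one integer in ``[0, genome_bp)``.  All coordinates are 0-based and
    intervals half-open.
    """

    def __init__(
        self,
        arm_lengths: Sequence[int],
        cluster_intervals: Sequence[Sequence[tuple[int, int]]],
        recombination_rate: float,
        arm_names: Sequence[str] | None = None,
    ) -> None:
        lengths = np.asarray(arm_lengths, dtype=np.int64)
        if lengths.ndim != 1 or lengths.size == 0:
            raise InvalidLayoutError("need at least one chromosome arm")
        if (lengths <= 0).any():
            raise InvalidLayoutError("arm lengths must be positive")
        if recombination_rate < 0:
            raise InvalidLayoutError("recombination rate must be >= 0")
        if len(cluster_intervals) != lengths.size:
            raise InvalidLayoutError("one cluster-interval list per arm required")
        if arm_names is None:
            arm_names = tuple(f"chr{i + 1}" for i in range(lengths.size))
        if len(arm_names) != lengths.size:
            raise InvalidLayoutError("one name per arm required")

        self.arm_names: tuple[str, ...] = tuple(str(n) for n in arm_names)
        self.arm_lengths: np.ndarray = lengths
        self.recombination_rate: float = float(recombination_rate)
        self.arm_starts: np.ndarray = np.concatenate(
            ([0], np.cumsum(lengths))
        ).astype(np.int64)
        self.genome_bp: int = int(self.arm_starts[-1])

        per_arm: list[tuple[tuple[int, int], ...]] = []
        flat_start: list[int] = []
        flat_end: list[int] = []
        for a, ivs in enumerate(cluster_intervals):
            ivs = sorted((int(s), int(e)) for s, e in ivs)
            prev_end = -1
            for s, e in ivs:
                if not (0 <= s < e <= lengths[a]):
                    raise InvalidLayoutError(
                        f"cluster [{s},{e}) outside arm {self.arm_names[a]} "
                        f"of length {lengths[a]}"
                    )
                if s < prev_end:
                    raise InvalidLayoutError(
                        f"overlapping clusters on arm {self.arm_names[a]}"
                    )
                prev_end = e
                flat_start.append(int(self.arm_starts[a]) + s)
                flat_end.append(int(self.arm_starts[a]) + e)
            per_arm.append(tuple(ivs))
        self.cluster_intervals: tuple[tuple[tuple[int, int], ...], ...] = tuple(per_arm)
        self._clu_starts = np.asarray(flat_start, dtype=np.int64)
        self._clu_ends = np.asarray(flat_end, dtype=np.int64)
        self.total_cluster_bp: int = int((self._clu_ends - self._clu_starts).sum())
        self.cluster_fraction: float = self.total_cluster_bp / self.genome_bp
        # expected crossovers per arm per meiosis: r[cM/Mb] * L[Mb] / 100
        self.morgans_per_arm: np.ndarray = (
            self.recombination_rate * lengths.astype(float) / 1e8
        )

    @property
    def n_arms(self) -> int:
        return len(self.arm_names)

    def arm_of(self, pos: np.ndarray) -> np.ndarray:
        """Arm index containing each global position."""
        return np.searchsorted(self.arm_starts, pos, side="right") - 1

    def in_clusters(self, pos: np.ndarray) -> np.ndarray:
        """Boolean mask: does each global position fall in a piRNA cluster?"""
        pos = np.asarray(pos)
        out = np.zeros(pos.shape, dtype=bool)
        if self._clu_starts.size == 0 or pos.size == 0:
            return out
        idx = np.searchsorted(self._clu_starts, pos, side="right") - 1
        ok = idx >= 0
        out[ok] = pos[ok] < self._clu_ends[idx[ok]]
        return out

    def to_global(self, arm: str, pos: int) -> int:
        """Convert an (arm name, local bp) coordinate to the global axis."""
        a = self.arm_names.index(arm)
        if not 0 <= pos < self.arm_lengths[a]:
            raise ValueError(f"position {pos} outside arm {arm}")
        return int(self.arm_starts[a]) + int(pos)

    def to_local(self, pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Convert global positions to (arm index, local bp)."""
        pos = np.asarray(pos, dtype=np.int64)
        arm = self.arm_of(pos)
        return arm, pos - self.arm_starts[arm]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"GenomeLayout({self.n_arms} arms, {self.genome_bp/1e6:.1f} Mb, "
            f"clusters {self.total_cluster_bp/1e6:.2f} Mb "
            f"({100*self.cluster_fraction:.2f}%), r={self.recombination_rate} cM/Mb)"
        )


def build_genome(
    arm_lengths: Sequence[int],
    cluster_bp_per_arm: int,
    recombination_rate: float,
    arm_names: Sequence[str] | None = None,
) -> GenomeLayout:
    """Layout with one terminal piRNA cluster at the distal end of each arm."""
    ivs: list[list[tuple[int, int]]] = []
    for length in arm_lengths:
        if cluster_bp_per_arm > length:
            raise InvalidLayoutError(
                f"cluster of {cluster_bp_per_arm} bp longer than arm of {length} bp"
            )
        if cluster_bp_per_arm > 0:
            ivs.append([(int(length) - int(cluster_bp_per_arm), int(length))])
        else:
            ivs.append([])
    return GenomeLayout(arm_lengths, ivs, recombination_rate, arm_names)


def standard_layout(cluster_bp_per_arm: int = 850_000) -> GenomeLayout:
    """Five 32.4-Mb arms with terminal clusters and r = 4 cM/Mb.

    With the default 850-kb clusters this is a 162-Mb genome of which
    4.25 Mb (~2.6%) is piRNA cluster, mirroring Drosophila-scale estimates.
    """
    return build_genome([32_400_000] * 5, cluster_bp_per_arm, 4.0)


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Selection:
    """Per-insertion fitness effects: constant ``x`` or a discrete DFE.

    ``x`` is the cost of one (non-cluster) insertion under the linear
    fitness function w = 1 - x*n.  If ``dfe_effects`` is given, every new
    insertion draws its own effect from that discrete distribution
    (``dfe_probs`` defaults to uniform).
    """

    x: float = 0.0
    dfe_effects: tuple[float, ...] | None = None
    dfe_probs: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.x < 0:
            raise ValueError("selection effect x must be >= 0")
        if self.dfe_effects is not None:
            eff = tuple(float(e) for e in self.dfe_effects)
            if len(eff) == 0 or any(e < 0 for e in eff):
                raise ValueError("DFE effects must be a non-empty list of values >= 0")
            object.__setattr__(self, "dfe_effects", eff)
            if self.dfe_probs is None:
                probs = tuple(1.0 / len(eff) for _ in eff)
            else:
                probs = tuple(float(p) for p in self.dfe_probs)
                if len(probs) != len(eff) or any(p < 0 for p in probs):
                    raise ValueError("DFE probabilities must match effects")
                if abs(sum(probs) - 1.0) > 1e-9:
                    raise ValueError("DFE probabilities must sum to 1")
            object.__setattr__(self, "dfe_probs", probs)
        elif self.dfe_probs is not None:
            raise ValueError("dfe_probs given without dfe_effects")

    @property
    def is_dfe(self) -> bool:
        return self.dfe_effects is not None

    def draw_effects(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if not self.is_dfe:
            raise ValueError("draw_effects is only defined for a DFE model")
        return rng.choice(
            np.asarray(self.dfe_effects), size=n, p=np.asarray(self.dfe_probs)
        )


@dataclass(frozen=True)
class SimParams:
    """Parameters of one invasion run.

    Attributes
    ----------
    N : diploid census size.
    u : transposition rate per (non-cluster) insertion per generation in
        unsilenced individuals.
    u_r : residual rate in silenced individuals (0 <= u_r <= u).
    selection : per-insertion fitness effects.
    M : number of founder insertions, each at allele frequency 1/(2N).
    generations : number of generations to simulate.
    replicates : replicate count for :func:`run_replicates`.
    seed : master seed; replicate streams are spawned from it.
    silencing_lag : generations a cluster insertion must age before it
        silences (0 = instantaneous zygotic silencing, the default used in
        all headline runs).
    """

    N: int
    u: float
    u_r: float = 0.0
    selection: Selection = field(default_factory=Selection)
    M: int = 0
    generations: int = 100
    replicates: int = 1
    seed: int | None = None
    silencing_lag: int = 0

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("population size N must be >= 2")
        if self.M < 0:
            raise ValueError("founder insertion count M must be >= 0")
        if self.u < 0:
            raise ValueError("transposition rate u must be >= 0")
        if not 0 <= self.u_r <= self.u:
            raise ValueError("residual rate must satisfy 0 <= u_r <= u")
        if self.generations < 0 or self.replicates < 1 or self.silencing_lag < 0:
            raise ValueError("generations, replicates, silencing_lag out of range")

    @classmethod
    def from_config(cls, cfg: dict) -> "SimParams":
        """Build from a flat config mapping (see :func:`layout_from_config`)."""
        sel_cfg = cfg.get("dfe")
        if sel_cfg is not None:
            selection = Selection(
                dfe_effects=tuple(sel_cfg["effects"]),
                dfe_probs=tuple(sel_cfg["probs"]) if "probs" in sel_cfg else None,
            )
        else:
            selection = Selection(x=float(cfg.get("x", 0.0)))
        return cls(
            N=int(cfg["N"]),
            u=float(cfg["u"]),
            u_r=float(cfg.get("u_r", 0.0)),
            selection=selection,
            M=int(cfg.get("M", 0)),
            generations=int(cfg.get("generations", 100)),
            replicates=int(cfg.get("replicates", 1)),
            seed=None if cfg.get("seed") is None else int(cfg["seed"]),
            silencing_lag=int(cfg.get("silencing_lag", 0)),
        )


def layout_from_config(cfg: dict) -> GenomeLayout:
    """Build a :class:`GenomeLayout` from a config mapping.

    Recognised keys: ``arms`` (int count or list of lengths), ``arm_length``
    (bp, used with an integer ``arms``), ``cluster_bp`` (terminal cluster
    per arm) and ``recombination_rate`` (cM/Mb).
    """
    arms = cfg.get("arms", 5)
    if isinstance(arms, int):
        arm_lengths = [int(cfg.get("arm_length", 32_400_000))] * arms
    else:
        arm_lengths = [int(a) for a in arms]
    return build_genome(
        arm_lengths,
        int(cfg.get("cluster_bp", 850_000)),
        float(cfg.get("recombination_rate", 4.0)),
    )


# ---------------------------------------------------------------------------
# population state
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Haplotype:
    """One haploid genome: sorted insertion positions plus optional sidecars."""

    pos: np.ndarray
    eff: np.ndarray | None = None
    birth: np.ndarray | None = None


@dataclass(frozen=True)
class Diploid:
    """A single individual: two haplotypes, used by the scalar operations."""

    hap0: Haplotype
    hap1: Haplotype


@dataclass
class Population:
    """N diploid individuals stored as one flat, CSR-like position array.

    ``pos`` holds every insertion position grouped by haplotype; haplotype
    ``h`` occupies ``pos[ptr[h]:ptr[h+1]]`` (sorted), and individual ``i``
    owns haplotypes ``2i`` and ``2i+1``.  ``eff`` (per-insertion selection
    effect, DFE mode) and ``birth`` (generation of origin, silencing-lag
    mode) are parallel arrays when present.
    """

    N: int
    pos: np.ndarray
    ptr: np.ndarray
    eff: np.ndarray | None = None
    birth: np.ndarray | None = None

    @property
    def total_insertions(self) -> int:
        return int(self.pos.size)

    @property
    def copies_per_haploid(self) -> float:
        return self.pos.size / (2 * self.N)

    def haplotype(self, h: int) -> Haplotype:
        s, e = int(self.ptr[h]), int(self.ptr[h + 1])
        return Haplotype(
            pos=self.pos[s:e],
            eff=None if self.eff is None else self.eff[s:e],
            birth=None if self.birth is None else self.birth[s:e],
        )

    def diploid(self, i: int) -> Diploid:
        return Diploid(self.haplotype(2 * i), self.haplotype(2 * i + 1))


def _draw_positions(
    hap_new: np.ndarray,
    kept_hap: np.ndarray,
    kept_pos: np.ndarray,
    rng: np.random.Generator,
    genome_bp: int,
) -> np.ndarray:
    """Uniform insertion positions, re-drawing the rare same-haplotype collision."""
    n = hap_new.size
    pos = rng.integers(0, genome_bp, size=n, dtype=np.int64)
    if n == 0:
        return pos
    kept_key = np.sort(kept_hap.astype(np.int64) * genome_bp + kept_pos)
    while True:
        key = hap_new.astype(np.int64) * genome_bp + pos
        bad = np.zeros(n, dtype=bool)
        if kept_key.size:
            j = np.searchsorted(kept_key, key)
            hit = j < kept_key.size
            bad[hit] = kept_key[j[hit]] == key[hit]
        _, inv, cnt = np.unique(key, return_inverse=True, return_counts=True)
        bad |= cnt[inv] > 1
        if not bad.any():
            return pos
        pos[bad] = rng.integers(0, genome_bp, size=int(bad.sum()), dtype=np.int64)


def initialize_population(
    layout: GenomeLayout, params: SimParams, rng: np.random.Generator
) -> Population:
    """Seed the invasion: M insertions, each on one random haplotype.

    Every founder insertion therefore segregates at allele frequency
    1/(2N), and the population-wide mean is exactly M/(2N) copies per
    haploid genome.  Positions are uniform over the genome and may fall
    inside piRNA clusters.
    """
    H = 2 * params.N
    hap = rng.integers(0, H, size=params.M, dtype=np.int64)
    pos = _draw_positions(
        hap, np.empty(0, np.int64), np.empty(0, np.int64), rng, layout.genome_bp
    )
    order = np.lexsort((pos, hap))
    hap, pos = hap[order], pos[order]
    ptr = np.concatenate(([0], np.cumsum(np.bincount(hap, minlength=H)))).astype(
        np.int64
    )
    eff = (
        params.selection.draw_effects(rng, params.M)
        if params.selection.is_dfe
        else None
    )
    birth = np.zeros(params.M, dtype=np.int64) if params.silencing_lag > 0 else None
    return Population(N=params.N, pos=pos, ptr=ptr, eff=eff, birth=birth)


# ---------------------------------------------------------------------------
# scalar reference operations
# ---------------------------------------------------------------------------

def fitness(individual: Diploid, selection: Selection, layout: GenomeLayout) -> float:
    """w = max(0, 1 - sum of effects over non-cluster insertions).

    Cluster insertions are neutral; an individual with w = 0 never
    reproduces.
    """
    pos = np.concatenate([individual.hap0.pos, individual.hap1.pos])
    non = ~layout.in_clusters(pos)
    if selection.is_dfe:
        eff = np.concatenate(
            [
                individual.hap0.eff if individual.hap0.eff is not None else np.zeros(0),
                individual.hap1.eff if individual.hap1.eff is not None else np.zeros(0),
            ]
        )
        load = float(eff[non].sum())
    else:
        load = selection.x * int(non.sum())
    return max(0.0, 1.0 - load)


def _crossover_breakpoints(
    layout: GenomeLayout, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sampled crossover positions (global, fractional bp) and per-arm phases.

    The crossover count per arm is Poisson with mean r*L/100 Morgans and
    positions are uniform within the arm; a crossover at fractional
    position c separates integer positions <= c from positions > c.  Arms
    assort independently via an independent starting phase per arm.
    """
    nco = rng.poisson(layout.morgans_per_arm)
    arm = np.repeat(np.arange(layout.n_arms), nco)
    co = layout.arm_starts[arm] + rng.random(arm.size) * layout.arm_lengths[arm]
    phase0 = rng.integers(0, 2, size=layout.n_arms)
    return np.sort(co), phase0


def make_gamete(
    individual: Diploid, layout: GenomeLayout, rng: np.random.Generator
) -> Haplotype:
    """Recombinant gamete of one individual (scalar reference path)."""
    co, phase0 = _crossover_breakpoints(layout, rng)

    def phase_at(pos: np.ndarray) -> np.ndarray:
        arm = layout.arm_of(pos)
        k1 = np.searchsorted(co, pos)
        k0 = np.searchsorted(co, layout.arm_starts[arm])
        return phase0[arm] ^ ((k1 - k0) & 1)

    keep0 = phase_at(individual.hap0.pos) == 0
    keep1 = phase_at(individual.hap1.pos) == 1
    pos = np.concatenate([individual.hap0.pos[keep0], individual.hap1.pos[keep1]])
    order = np.argsort(pos, kind="stable")

    def _gather(a0, a1):
        if a0 is None and a1 is None:
            return None
        a0 = a0 if a0 is not None else np.zeros(0, dtype=float)
        a1 = a1 if a1 is not None else np.zeros(0, dtype=float)
        return np.concatenate([a0[keep0], a1[keep1]])[order]

    return Haplotype(
        pos=pos[order],
        eff=_gather(individual.hap0.eff, individual.hap1.eff),
        birth=_gather(individual.hap0.birth, individual.hap1.birth),
    )


def transpose(
    zygote: Diploid,
    params: SimParams,
    layout: GenomeLayout,
    rng: np.random.Generator,
    generation: int = 0,
) -> Diploid:
    """Apply one generation of transposition to a freshly formed zygote.

    The per-copy rate is ``u`` when the zygote carries no (silencing-
    competent) cluster insertion and ``u_r`` otherwise.  Only non-cluster
    insertions act as templates; each spawns a new copy independently, the
    new copy landing uniformly on the genome (it may hit a cluster, but a
    hit does not suppress the ongoing burst).  Existing copies are retained.
    """
    haps = [zygote.hap0, zygote.hap1]
    pos = np.concatenate([h.pos for h in haps])
    clu = layout.in_clusters(pos)
    if params.silencing_lag > 0:
        birth = np.concatenate(
            [h.birth if h.birth is not None else np.zeros(h.pos.size) for h in haps]
        )
        silencing = clu & (generation - birth >= params.silencing_lag)
    else:
        silencing = clu
    rate = params.u_r if silencing.any() else params.u
    templates = int((~clu).sum())
    n_new = int(rng.binomial(templates, rate)) if templates else 0
    target = rng.integers(0, 2, size=n_new)
    kept_hap = np.concatenate(
        [np.zeros(haps[0].pos.size, np.int64), np.ones(haps[1].pos.size, np.int64)]
    )
    new_pos = _draw_positions(target, kept_hap, pos, rng, layout.genome_bp)

    out = []
    for h in (0, 1):
        add = new_pos[target == h]
        merged = np.sort(np.concatenate([haps[h].pos, add]))
        eff = birth_arr = None
        if params.selection.is_dfe:
            eff_add = params.selection.draw_effects(rng, add.size)
            eff = np.concatenate([haps[h].eff, eff_add])[
                np.argsort(np.concatenate([haps[h].pos, add]), kind="stable")
            ]
        if params.silencing_lag > 0:
            b_add = np.full(add.size, generation, dtype=np.int64)
            birth_arr = np.concatenate([haps[h].birth, b_add])[
                np.argsort(np.concatenate([haps[h].pos, add]), kind="stable")
            ]
        out.append(Haplotype(pos=merged, eff=eff, birth=birth_arr))
    return Diploid(out[0], out[1])


# ---------------------------------------------------------------------------
# vectorised generation step
# ---------------------------------------------------------------------------

def _individual_loads(
    pop: Population, params: SimParams, layout: GenomeLayout, generation: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-individual (fitness, silencing cluster count, cluster mask, ind index)."""
    N = pop.N
    sizes = np.diff(pop.ptr)
    ind = np.repeat(np.arange(2 * N) // 2, sizes)
    clu = layout.in_clusters(pop.pos)
    if params.silencing_lag > 0:
        mature = clu & (generation - pop.birth >= params.silencing_lag)
    else:
        mature = clu
    clu_cnt = np.bincount(ind[mature], minlength=N)
    non = ~clu
    if params.selection.is_dfe:
        load = np.bincount(ind[non], weights=pop.eff[non], minlength=N)
    else:
        load = params.selection.x * np.bincount(ind[non], minlength=N)
    w = np.clip(1.0 - load, 0.0, None)
    return w, clu_cnt, clu, ind


def step_generation(
    pop: Population,
    params: SimParams,
    layout: GenomeLayout,
    rng: np.random.Generator,
    generation: int = 0,
) -> Population:
    """Advance the population by one Wright-Fisher generation.

    Order of events: fitness-proportional parent sampling -> recombinant
    gametes -> zygote -> transposition in the zygote.  The census size N is
    preserved exactly.
    """
    N = pop.N
    H = 2 * N
    G = layout.genome_bp

    w, _, _, _ = _individual_loads(pop, params, layout, generation)
    total_w = w.sum()
    if total_w <= 0:
        raise PopulationCollapseError(
            f"all {N} individuals have fitness 0 at generation {generation}"
        )
    parents = rng.choice(N, size=H, p=w / total_w)

    # --- gametes: gather both parental haplotypes as candidates ------------
    p0 = pop.ptr[2 * parents]
    p1 = pop.ptr[2 * parents + 1]
    p2 = pop.ptr[2 * parents + 2]
    csz = (p2 - p0).astype(np.int64)
    total = int(csz.sum())
    offs = np.concatenate(([0], np.cumsum(csz)))
    idx = p0.repeat(csz) + (np.arange(total) - offs[:-1].repeat(csz))
    cpos = pop.pos[idx]
    chap = idx >= p1.repeat(csz)  # False: candidate sits on parental hap0
    cg = np.repeat(np.arange(H), csz)

    # crossovers for all 2N meioses at once
    nco = rng.poisson(layout.morgans_per_arm, size=(H, layout.n_arms))
    co_flat = nco.ravel()
    co_arm = np.repeat(np.tile(np.arange(layout.n_arms), H), co_flat)
    co_g = np.repeat(np.repeat(np.arange(H), layout.n_arms), co_flat)
    co_pos = layout.arm_starts[co_arm] + rng.random(co_arm.size) * layout.arm_lengths[
        co_arm
    ]
    co_key = np.sort(co_g * float(G) + co_pos)
    phase0 = rng.integers(0, 2, size=(H, layout.n_arms))

    carm = layout.arm_of(cpos)
    base = cg * float(G)
    k1 = np.searchsorted(co_key, base + cpos)
    k0 = np.searchsorted(co_key, base + layout.arm_starts[carm])
    phase = phase0[cg, carm] ^ ((k1 - k0) & 1)
    keep = (phase == 1) == chap

    tg = cg[keep]
    tpos = cpos[keep]
    teff = pop.eff[idx][keep] if pop.eff is not None else None
    tbirth = pop.birth[idx][keep] if pop.birth is not None else None

    # --- transposition in the zygote ---------------------------------------
    off = tg >> 1
    t_clu = layout.in_clusters(tpos)
    if params.silencing_lag > 0:
        t_mature = t_clu & (generation + 1 - tbirth >= params.silencing_lag)
    else:
        t_mature = t_clu
    clu_off = np.bincount(off[t_mature], minlength=N)
    templates = np.bincount(off[~t_clu], minlength=N)
    rate = np.where(clu_off > 0, params.u_r, params.u)
    n_new = rng.binomial(templates, rate)
    tot_new = int(n_new.sum())
    hap_new = 2 * np.repeat(np.arange(N), n_new) + rng.integers(
        0, 2, size=tot_new, dtype=np.int64
    )
    pos_new = _draw_positions(hap_new, tg, tpos, rng, G)

    # --- assemble the next generation --------------------------------------
    ahap = np.concatenate([tg, hap_new])
    apos = np.concatenate([tpos, pos_new])
    order = np.lexsort((apos, ahap))
    ptr = np.concatenate(([0], np.cumsum(np.bincount(ahap, minlength=H)))).astype(
        np.int64
    )
    eff = None
    if params.selection.is_dfe:
        eff = np.concatenate([teff, params.selection.draw_effects(rng, tot_new)])[order]
    birth = None
    if params.silencing_lag > 0:
        birth = np.concatenate(
            [tbirth, np.full(tot_new, generation + 1, dtype=np.int64)]
        )[order]
    return Population(N=N, pos=apos[order], ptr=ptr, eff=eff, birth=birth)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

TRAJECTORY_COLUMNS = (
    "generation",
    "copies_per_haploid",
    "noncluster_per_haploid",
    "cluster_per_diploid",
    "frac_silenced",
    "mean_fitness",
    "lost",
)


def population_stats(
    pop: Population, params: SimParams, layout: GenomeLayout, generation: int = 0
) -> dict:
    """Per-generation invasion summary of the current population."""
    w, clu_cnt, clu, _ = _individual_loads(pop, params, layout, generation)
    n_clu = int(clu.sum())
    total = pop.total_insertions
    return {
        "generation": int(generation),
        "copies_per_haploid": total / (2 * pop.N),
        "noncluster_per_haploid": (total - n_clu) / (2 * pop.N),
        "cluster_per_diploid": n_clu / pop.N,
        "frac_silenced": float((clu_cnt > 0).mean()),
        "mean_fitness": float(w.mean()),
        "lost": total == 0,
    }


def run_invasion(
    params: SimParams,
    layout: GenomeLayout,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate one replicate and return its per-generation trajectory.

    The returned frame has one row per generation 0..generations with the
    columns in :data:`TRAJECTORY_COLUMNS`.  Once the TE is lost all later
    rows are zero.  Identically seeded runs are bit-reproducible.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    pop = initialize_population(layout, params, rng)
    rows = [population_stats(pop, params, layout, generation=0)]
    for g in range(params.generations):
        if pop.total_insertions == 0:
            for g_rest in range(g, params.generations):
                rows.append(
                    {
                        "generation": g_rest + 1,
                        "copies_per_haploid": 0.0,
                        "noncluster_per_haploid": 0.0,
                        "cluster_per_diploid": 0.0,
                        "frac_silenced": 0.0,
                        "mean_fitness": 1.0,
                        "lost": True,
                    }
                )
            break
        pop = step_generation(pop, params, layout, rng, generation=g)
        rows.append(population_stats(pop, params, layout, generation=g + 1))
    return pd.DataFrame(rows, columns=list(TRAJECTORY_COLUMNS))


def run_replicates(
    params: SimParams, layout: GenomeLayout, seed: int | None = None
) -> pd.DataFrame:
    """Simulate ``params.replicates`` independent invasions.

    Per-replicate random streams are spawned deterministically from the
    master seed (``seed`` overrides ``params.seed``), so results are
    reproducible and replicates are statistically independent.
    """
    master = params.seed if seed is None else seed
    children = np.random.SeedSequence(master).spawn(params.replicates)
    frames = []
    for r, child in enumerate(children):
        df = run_invasion(params, layout, rng=np.random.default_rng(child))
        df.insert(0, "replicate", r)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
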