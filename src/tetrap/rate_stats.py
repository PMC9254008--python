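"""Invasion statistics: transposition rate, GD percentage, feature enrichment.

The transposition-rate estimator inverts geometric copy-number growth,
``n_{k+t} = n_k (1+u)^t``, giving ``u = (n_{k+t}/n_k)^(1/t) - 1``.  Under
purifying selection only the effective rate u' = u - x is observable, where
x is the mean fitness cost of one insertion.  Gonadal dysgenesis (GD) is the
standard ovary-atrophy assay for P-element activity; intermediate ovaries
count half.  Enrichment of insertions in a genomic feature is
e = o / (f * t): observed count over the count expected if the t insertions
fell uniformly on a genome of which fraction f is feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io as tio

__all__ = [
    "RateEstimate",
    "GDCounts",
    "EnrichmentResult",
    "PlateauSummary",
    "transposition_rate",
    "effective_rate",
    "gd_percentage",
    "enrichment",
    "count_in_features",
    "rates_from_trajectory",
    "plateau_summary",
]


@dataclass(frozen=True)
class RateEstimate:
    """Estimated per-copy transposition rate over one time interval."""

    n_start: float
    n_end: float
    t: int
    u: float


@dataclass(frozen=True)
class GDCounts:
    """Ovary counts from a gonadal-dysgenesis assay."""

    normal: int
    intermediate: int
    dysgenic: int

    def __post_init__(self) -> None:
        if min(self.normal, self.intermediate, self.dysgenic) < 0:
            raise ValueError("ovary counts must be non-negative")

    @property
    def total(self) -> int:
        return self.normal + self.intermediate + self.dysgenic


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed/expected enrichment of insertions in a genomic feature."""

    o: int
    f: float
    t_total: int
    e: float


def transposition_rate(n_start: float, n_end: float, t: int) -> float:
    """Per-copy rate u solving n_end = n_start * (1+u)^t.

    Negative values (copy-number loss) are returned as-is, not clamped.
    """
    if n_start <= 0:
        raise ValueError("starting copy number must be > 0")
    if n_end < 0:
        raise ValueError("final copy number must be >= 0")
    if t < 1:
        raise ValueError("elapsed generations t must be >= 1")
    return float((n_end / n_start) ** (1.0 / t) - 1.0)


def effective_rate(u: float, x: float) -> float:
    """Effective (observable) transposition rate u' = u - x."""
    return u - x


def gd_percentage(counts: GDCounts) -> float:
    """Percent dysgenic ovaries: 100*(dysgenic + intermediate/2) / total."""
    if counts.total == 0:
        raise ValueError("GD percentage undefined for zero assayed ovaries")
    return 100.0 * (counts.dysgenic + counts.intermediate / 2.0) / counts.total


def enrichment(o: int, f: float, t_total: int) -> float:
    """Fold enrichment e = o / (f * t_total) of insertions in a feature."""
    if not 0 < f <= 1:
        raise ValueError("feature fraction f must be in (0, 1]")
    if t_total <= 0:
        raise ValueError("total insertion count must be > 0")
    if not 0 <= o <= t_total:
        raise ValueError("observed count must be in [0, t_total]")
    return o / (f * t_total)


def count_in_features(
    insertions: pd.DataFrame, features: pd.DataFrame, genome_size: int
) -> EnrichmentResult:
    """Enrichment of point insertions inside a set of feature intervals.

    ``insertions`` and ``features`` are BED-like frames (``chrom``,
    ``start``, ``end``; 0-based half-open).  An insertion is a point at its
    ``start`` coordinate and falls in a feature iff that point lies in any
    (merged) feature interval.  Overlapping features are merged before the
    genomic fraction f is computed.
    """
    if genome_size <= 0:
        raise ValueError("genome size must be > 0")
    merged = tio.merge_intervals(features)
    feat_bp = int((merged["end"] - merged["start"]).sum())
    f = feat_bp / genome_size
    t_total = len(insertions)
    o = 0
    for chrom, grp in merged.groupby("chrom", sort=False):
        pts = insertions.loc[insertions["chrom"] == chrom, "start"].to_numpy()
        if pts.size == 0:
            continue
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        idx = np.searchsorted(starts, pts, side="right") - 1
        ok = idx >= 0
        o += int((pts[ok] < ends[idx[ok]]).sum())
    return EnrichmentResult(o=o, f=f, t_total=t_total, e=enrichment(o, f, t_total))


def rates_from_trajectory(
    trajectory: pd.DataFrame,
    interval: int = 10,
    value_col: str = "copies_per_haploid",
) -> pd.DataFrame:
    """Per-interval transposition-rate estimates from a copy-number trajectory.

    The trajectory frame needs ``generation`` and ``value_col`` columns and
    may carry a ``replicate`` column.  For each replicate, u is estimated
    over consecutive windows of ``interval`` generations (using the rows
    closest to the window bounds that are present in the table).  Rows where
    the window's starting copy number is zero are skipped.
    """
    if interval < 1:
        raise ValueError("sampling interval must be >= 1")
    df = trajectory.copy()
    if "replicate" not in df.columns:
        df["replicate"] = 0
    rows = []
    for rep, grp in df.groupby("replicate", sort=True):
        grp = grp.sort_values("generation")
        gens = grp["generation"].to_numpy()
        vals = grp[value_col].to_numpy(dtype=float)
        bounds = np.arange(gens.min(), gens.max() + 1, interval)
        picks = np.searchsorted(gens, bounds)
        picks = np.unique(np.clip(picks, 0, len(gens) - 1))
        for a, b in zip(picks[:-1], picks[1:]):
            t = int(gens[b] - gens[a])
            if t < 1 or vals[a] <= 0:
                continue
            rows.append(
                {
                    "replicate": rep,
                    "gen_start": int(gens[a]),
                    "gen_end": int(gens[b]),
                    "n_start": vals[a],
                    "n_end": vals[b],
                    "u": transposition_rate(vals[a], vals[b], t),
                }
            )
    return pd.DataFrame(
        rows, columns=["replicate", "gen_start", "gen_end", "n_start", "n_end", "u"]
    )


@dataclass(frozen=True)
class PlateauSummary:
    """Level and onset of the copy-number plateau of an invasion."""

    level: float
    onset_generation: int
    cluster_per_diploid: float | None
    frac_silenced: float | None


def plateau_summary(
    trajectory: pd.DataFrame,
    smooth_window: int = 21,
    growth_threshold: float = 0.0025,
    plateau_span: int = 50,
) -> PlateauSummary:
    """Plateau level and onset of a (multi-replicate) invasion trajectory.

    The replicate-averaged copies-per-haploid series is smoothed with a
    centred ``smooth_window``-generation moving average.  The plateau onset
    is the first generation, after per-generation growth has peaked, at
    which the smoothed relative growth rate drops below
    ``growth_threshold`` (default 0.25%/generation -- flat on the scale of
    invasion-phase growth); the wide smoothing window keeps this first
    crossing from firing early on Monte Carlo dips when only a handful of
    replicates are averaged.  The plateau level is the highest smoothed
    copy number within the ``plateau_span`` generations after onset, i.e.
    the level the early plateau attains rather than the value at the bend
    itself.  The same rule reads both trajectory shapes the trap model
    produces: neutral invasions that plateau and then drift upward only
    very slowly (the window top), and invasions under selection that peak
    and slowly decline (the peak).  If growth never falls below the
    threshold the last generation is used as onset.  Cluster insertions
    per diploid and the silenced fraction are averaged over the same
    window when present.
    """
    mean = trajectory.groupby("generation")["copies_per_haploid"].mean().sort_index()
    smooth = mean.rolling(smooth_window, center=True, min_periods=1).mean()
    rel_growth = (
        (smooth.diff() / smooth.shift())
        .rolling(smooth_window, center=True, min_periods=1)
        .mean()
    )
    after_peak = rel_growth.loc[rel_growth.idxmax():]
    flat = after_peak.index[after_peak < growth_threshold]
    onset = int(flat[0]) if len(flat) else int(smooth.index[-1])
    window = smooth.loc[(smooth.index >= onset) & (smooth.index <= onset + plateau_span)]
    level = float(window.max())

    def _plateau_mean(col: str) -> float | None:
        if col not in trajectory.columns:
            return None
        m = trajectory.groupby("generation")[col].mean().sort_index()
        sel = (m.index >= onset) & (m.index <= onset + plateau_span)
        return float(m.loc[sel].mean())

    return PlateauSummary(
        level=level,
        onset_generation=onset,
        cluster_per_diploid=_plateau_mean("cluster_per_diploid"),
        frac_silenced=_plateau_mean("frac_silenced"),
    )
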