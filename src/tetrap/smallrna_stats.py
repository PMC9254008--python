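"""Ping-pong signature and z-score for small-RNA 5'-position data.

piRNAs produced by the ping-pong amplification loop come in sense/antisense
pairs whose 5' ends overlap by exactly 10 nt.  Given a table of aligned
small-RNA reads (reference, 5' position, strand, length, count; minus-strand
reads store their rightmost reference coordinate as the 5' position), the
signature is the distribution of 5'-overlap distances d = 1..20 over all
sense/antisense read pairs::

         sense 5' = s                 d = a - s + 1
         + read   s ----------->
         - read       <----------- a  (5' end of the - read)

so the canonical ping-pong configuration gives d = 10.  Pairs are weighted
by the product of the two read counts ("fraction of pairs"); distances
outside 1..20 are ignored.  The strength of the peak at d = 10 is
summarised by z = (h10 - mean(h, d != 10)) / sd(h, d != 10) and mapped to a
p-value through the upper tail of the standard normal (z = 3.09 ~ p 0.001).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "InsufficientDataError",
    "PingPongSignature",
    "filter_by_length",
    "ppm_normalize",
    "pingpong_signature",
    "pingpong_zscore",
    "zscore_to_pvalue",
    "DEFAULT_EXCLUDE_POSITIONS",
]

#: Highly abundant P-element piRNA 5' positions (1-based, as printed) whose
#: exclusion removes a coverage artefact from the signature.
DEFAULT_EXCLUDE_POSITIONS = (1162, 1164)


class InsufficientDataError(ValueError):
    """Too few sense/antisense pairs to compute a signature or z-score."""


@dataclass(frozen=True)
class PingPongSignature:
    """Overlap-distance distribution of sense/antisense piRNA pairs.

    ``h[d-1]`` is the fraction of (count-weighted) pairs with 5' overlap d,
    for d = 1..max_d; ``n_pairs`` is the total pair weight.
    """

    h: np.ndarray
    n_pairs: float

    @property
    def h10(self) -> float:
        return float(self.h[9])


def filter_by_length(
    reads: pd.DataFrame, min_len: int = 23, max_len: int = 29
) -> pd.DataFrame:
    """Keep reads with min_len <= length <= max_len (piRNA-sized by default)."""
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    mask = (reads["length"] >= min_len) & (reads["length"] <= max_len)
    return reads.loc[mask].reset_index(drop=True)


def ppm_normalize(count: float, mirna_total: float) -> float:
    """Scale a read count to 'per million sequenced miRNAs' (ppm)."""
    if mirna_total <= 0:
        raise ValueError("miRNA total must be > 0")
    return count * 1e6 / mirna_total


def pingpong_signature(
    reads: pd.DataFrame,
    reference: str,
    max_d: int = 20,
    exclude_positions: tuple[int, ...] = (),
    weighted: bool = True,
) -> PingPongSignature:
    """Ping-pong signature of the reads mapping to one reference.

    Parameters
    ----------
    reads
        Frame with columns reference, pos5, strand, length, count; pos5 is
        0-based and, for minus-strand reads, the rightmost reference base.
    reference
        Name of the (TE) reference to analyse.
    max_d
        Largest overlap distance tabulated (default 20).
    exclude_positions
        0-based 5' positions dropped from both strands before pairing
        (use :func:`tetrap.io.to_zero_based` on printed 1-based positions).
    weighted
        Weight each pair by the product of read counts (default); if False,
        every occupied 5' position contributes weight 1.
    """
    sub = reads.loc[reads["reference"] == reference]
    if exclude_positions:
        sub = sub.loc[~sub["pos5"].isin(set(int(p) for p in exclude_positions))]
    sense = sub.loc[sub["strand"] == "+"].groupby("pos5")["count"].sum()
    anti = sub.loc[sub["strand"] == "-"].groupby("pos5")["count"].sum()
    if not weighted:
        sense = (sense > 0).astype(float)
        anti = (anti > 0).astype(float)
    s_pos = sense.index.to_numpy(dtype=np.int64)
    s_cnt = sense.to_numpy(dtype=float)
    a_pos = anti.index.to_numpy(dtype=np.int64)
    a_cnt = anti.to_numpy(dtype=float)

    w = np.zeros(max_d, dtype=float)
    for d in range(1, max_d + 1):
        target = s_pos + d - 1  # antisense 5' = a with d = a - s + 1
        j = np.searchsorted(a_pos, target)
        hit = j < a_pos.size
        hit[hit] = a_pos[j[hit]] == target[hit]
        w[d - 1] = float((s_cnt[hit] * a_cnt[j[hit]]).sum())
    total = w.sum()
    if total <= 0:
        raise InsufficientDataError(
            f"no sense/antisense pairs with 5' overlap 1..{max_d} on {reference!r}"
        )
    return PingPongSignature(h=w / total, n_pairs=float(total))


def pingpong_zscore(signature: PingPongSignature, min_pairs: float = 100.0) -> float:
    """z = (h10 - mean of h at d != 10) / sample sd of h at d != 10.

    Requires at least ``min_pairs`` weighted pairs; the sd uses the sample
    convention (denominator 18 for the 19 off-peak distances).
    """
    if signature.n_pairs < min_pairs:
        raise InsufficientDataError(
            f"need >= {min_pairs} weighted pairs to report a z-score, "
            f"got {signature.n_pairs:.1f}"
        )
    others = np.delete(signature.h, 9)
    sd = float(np.std(others, ddof=1))
    if sd == 0:
        raise ValueError("z-score undefined: off-peak heights have zero variance")
    return (signature.h10 - float(others.mean())) / sd


def zscore_to_pvalue(z: float) -> float:
    """One-sided p-value: upper tail of the standard normal at z."""
    return float(sps.norm.sf(z))
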