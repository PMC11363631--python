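"""Genotype calling at amplicon-panel SNPs from per-sample allele counts.

Each panel SNP is biallelic with an anadromous allele (A) and a
landlocked allele (L).  Calls are made from read counts by depth and
allele-frequency rules:

* total read depth must reach ``min_depth`` (default 50), otherwise
  NO_CALL with reason ``LOW_DEPTH``;
* reads supporting neither panel allele above ``max_other_frac``
  (default 10% of depth) give NO_CALL with reason ``THIRD_ALLELE``;
* with f = n_A / (n_A + n_L): f > 0.90 calls AA, f < 0.10 calls LL,
  0.25 <= f <= 0.75 calls AL; frequencies in the gaps
  (0.10, 0.25) or (0.75, 0.90) give NO_CALL with reason
  ``AMBIGUOUS_FREQ`` rather than a silent guess.

All thresholds are configurable through :class:`CallingRules`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

AA, AL, LL, NO_CALL = "AA", "AL", "LL", "NO_CALL"
LOW_DEPTH, AMBIGUOUS_FREQ, THIRD_ALLELE = "LOW_DEPTH", "AMBIGUOUS_FREQ", "THIRD_ALLELE"

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class PanelLocus:
    """A panel SNP: 1-based position plus its two strain-diagnostic alleles."""

    chrom: str
    pos: int
    allele_A: str
    allele_L: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.chrom}: position must be 1-based (got {self.pos})")
        for a in (self.allele_A, self.allele_L):
            if a not in _BASES:
                raise ValueError(f"{self.chrom}:{self.pos}: bad allele {a!r}")
        if self.allele_A == self.allele_L:
            raise ValueError(f"{self.chrom}:{self.pos}: alleles must differ")

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.pos}"


@dataclass(frozen=True)
class AlleleCountRecord:
    """Read counts for one sample at one panel locus."""

    sample_id: str
    locus: PanelLocus
    n_A: int
    n_L: int
    n_other: int = 0

    def __post_init__(self) -> None:
        if min(self.n_A, self.n_L, self.n_other) < 0:
            raise ValueError("allele counts must be non-negative")

    @property
    def depth(self) -> int:
        return self.n_A + self.n_L + self.n_other


@dataclass(frozen=True)
class CallingRules:
    """Thresholds of the depth/frequency caller (defaults as published)."""

    min_depth: int = 50
    homo_freq: float = 0.90  # strict: f must exceed this for a homozygote
    het_lo: float = 0.25  # inclusive band for heterozygotes
    het_hi: float = 0.75
    max_other_frac: float = 0.10

    def __post_init__(self) -> None:
        if not (0.5 < self.homo_freq < 1.0):
            raise ValueError("homo_freq must lie in (0.5, 1)")
        if not (0.0 <= self.het_lo <= self.het_hi <= 1.0):
            raise ValueError("het band must satisfy 0 <= lo <= hi <= 1")
        if self.het_hi > self.homo_freq:
            raise ValueError("het band may not overlap the homozygous zone")
        if self.min_depth < 1:
            raise ValueError("min_depth must be positive")


@dataclass(frozen=True)
class GenotypeCall:
    sample_id: str
    locus: PanelLocus
    call: str  # AA | AL | LL | NO_CALL
    depth: int
    freq_major: float
    reason: str | None = None  # set iff call == NO_CALL


def _call_vectors(
    n_A: np.ndarray, n_L: np.ndarray, n_other: np.ndarray, rules: CallingRules
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized caller core: returns (call, reason, freq_major) arrays."""
    n_A = np.asarray(n_A, dtype=np.int64)
    n_L = np.asarray(n_L, dtype=np.int64)
    n_other = np.asarray(n_other, dtype=np.int64)
    depth = n_A + n_L + n_other
    informative = n_A + n_L

    call = np.full(n_A.shape, NO_CALL, dtype=object)
    reason = np.full(n_A.shape, AMBIGUOUS_FREQ, dtype=object)

    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(informative > 0, n_A / np.maximum(informative, 1), np.nan)
        other_frac = np.where(depth > 0, n_other / np.maximum(depth, 1), 0.0)

    ok_depth = depth >= rules.min_depth
    ok_other = other_frac <= rules.max_other_frac
    has_info = informative > 0

    is_AA = has_info & (f > rules.homo_freq)
    is_LL = has_info & (f < 1.0 - rules.homo_freq)
    is_AL = has_info & (f >= rules.het_lo) & (f <= rules.het_hi)

    callable_ = ok_depth & ok_other
    call[callable_ & is_AA] = AA
    call[callable_ & is_LL] = LL
    call[callable_ & is_AL] = AL
    reason[callable_ & (is_AA | is_LL | is_AL)] = None
    reason[ok_depth & ~ok_other] = THIRD_ALLELE
    reason[~ok_depth] = LOW_DEPTH  # depth failure reported first

    freq_major = np.where(has_info, np.maximum(f, 1.0 - f), np.nan)
    return call, reason, freq_major


def call_genotype(rec: AlleleCountRecord, rules: CallingRules | None = None) -> GenotypeCall:
    """Call a single sample/locus record; pure function of (counts, rules)."""
    rules = rules or CallingRules()
    call, reason, fmaj = _call_vectors(
        np.array([rec.n_A]), np.array([rec.n_L]), np.array([rec.n_other]), rules
    )
    return GenotypeCall(
        sample_id=rec.sample_id,
        locus=rec.locus,
        call=str(call[0]),
        depth=rec.depth,
        freq_major=float(fmaj[0]),
        reason=None if reason[0] is None else str(reason[0]),
    )


def call_genotypes(counts: pd.DataFrame, rules: CallingRules | None = None) -> pd.DataFrame:
    """Call genotypes for a counts table.

    Parameters
    ----------
    counts : DataFrame
        Columns ``sample_id, chrom, pos, n_A, n_L, n_other``
        (``n_other`` optional, defaulting to 0).

    Returns
    -------
    DataFrame with ``sample_id, chrom, pos, call, depth, freq_major, reason``.
    """
    rules = rules or CallingRules()
    n_other = counts["n_other"] if "n_other" in counts.columns else np.zeros(len(counts))
    call, reason, fmaj = _call_vectors(
        counts["n_A"].to_numpy(), counts["n_L"].to_numpy(), np.asarray(n_other, dtype=np.int64), rules
    )
    out = counts[["sample_id", "chrom", "pos"]].copy()
    out["call"] = call
    out["depth"] = counts["n_A"].to_numpy() + counts["n_L"].to_numpy() + np.asarray(n_other, dtype=np.int64)
    out["freq_major"] = fmaj
    out["reason"] = reason
    return out


def allele_frequencies(
    calls: pd.DataFrame | Iterable[GenotypeCall],
    grouping: Mapping[str, str],
) -> pd.DataFrame:
    """Per-group per-locus allele frequencies from called genotypes.

    NO_CALL records are excluded; freq_L = (2 n_LL + n_AL) / (2 n_called).
    Groups with zero called samples at a locus are reported with missing
    frequency (never zero).
    """
    if not isinstance(calls, pd.DataFrame):
        calls = pd.DataFrame(
            {
                "sample_id": [c.sample_id for c in calls],
                "chrom": [c.locus.chrom for c in calls],
                "pos": [c.locus.pos for c in calls],
                "call": [c.call for c in calls],
            }
        )
    df = calls[calls["call"] != NO_CALL].copy()
    df["group"] = df["sample_id"].map(dict(grouping))
    if df["group"].isna().any():
        missing = df.loc[df["group"].isna(), "sample_id"].iloc[0]
        raise KeyError(f"sample {missing!r} has no group assignment")
    df["l_dose"] = df["call"].map({AA: 0, AL: 1, LL: 2})

    rows = []
    all_groups = sorted(set(grouping.values()))
    for (chrom, pos), sub in df.groupby(["chrom", "pos"], sort=True):
        for group in all_groups:
            g = sub[sub["group"] == group]
            n_called = len(g)
            if n_called == 0:
                rows.append((chrom, pos, group, np.nan, np.nan, 0))
            else:
                freq_l = g["l_dose"].sum() / (2.0 * n_called)
                rows.append((chrom, pos, group, 1.0 - freq_l, freq_l, n_called))
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "group", "freq_A", "freq_L", "n_called"]
    )


def frequency_table(freqs: pd.DataFrame, allele: str = "L") -> pd.DataFrame:
    """Pivot the tidy frequency table: rows = loci, columns = groups."""
    col = f"freq_{allele}"
    wide = freqs.pivot_table(index=["chrom", "pos"], columns="group", values=col)
    wide.columns.name = None
    return wide.reset_index()
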