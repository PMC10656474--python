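"""Clonotype tables and repertoire clonality/diversity statistics.

A clonotype is an equivalence class of reconstructed VHHs under a chosen key
(full amino-acid sequence, CDR3 amino acids, or CDR3 nucleotides).  This
module builds per-sample clonotype tables and computes the standard
repertoire statistics: Shannon and Simpson indices, Hill-number true
diversity D_q (the effective number of equally abundant types), analytic
rarefaction and Chao1-based extrapolation of richness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "BULK_SUBTYPE",
    "CELL_SUBTYPES",
    "SUBTYPE_ROSTER",
    "KEY_LEVELS",
    "DEFAULT_RANK_BINS",
    "DEFAULT_COUNT_BINS",
    "SampleMeta",
    "ClonotypeTable",
    "DiversityResult",
    "build_clonotypes",
    "table_from_counts",
    "merge_replicates",
    "percent_unique",
    "clonality_by_rank",
    "clonality_by_count",
    "shannon",
    "simpson",
    "true_diversity",
    "hill_numbers",
    "rarefaction",
    "extrapolation",
    "diversity_result",
    "rarefaction_curve",
]

# Study design vocabulary: one bulk-leukocyte pool seeds each round, five
# sorted subtypes are measured per round.
BULK_SUBTYPE = "CD45"
CELL_SUBTYPES = ("CD11b", "CD11c", "CD8", "CD4CD25neg", "CD4CD25pos")
SUBTYPE_ROSTER = (BULK_SUBTYPE,) + CELL_SUBTYPES

KEY_LEVELS = ("full_aa", "cdr3_aa", "cdr3_nt")

# (lo, hi) 1-based inclusive rank bins; hi=None means open-ended.
DEFAULT_RANK_BINS = ((1, 10), (11, 100), (101, 1000), (1001, 10000), (10001, None))
# count bins on raw clone counts
DEFAULT_COUNT_BINS = ((1, 1), (2, 3), (4, 10), (11, 30), (31, 100), (101, None))


@dataclass(frozen=True)
class SampleMeta:
    """Stratum labels for one sequenced sample."""

    tumor_model: str = ""
    tissue: str = ""
    subtype: str = ""
    round: int = 0
    replicate: Optional[int] = None

    def stratum(self) -> "SampleMeta":
        """Metadata with the replicate dimension removed."""
        return replace(self, replicate=None)


@dataclass
class ClonotypeTable:
    """Per-sample clonotype counts, sorted by count desc then key.

    Invariants: counts sum to ``n``; proportions sum to 1; ``f1``/``f2`` are
    the singleton and doubleton counts used by richness estimators.
    """

    counts: pd.Series
    key_level: str = "full_aa"
    meta: SampleMeta = field(default_factory=SampleMeta)

    def __post_init__(self) -> None:
        if self.key_level not in KEY_LEVELS:
            raise ValueError(f"unknown key_level {self.key_level!r}")
        c = self.counts
        if not isinstance(c, pd.Series):
            c = pd.Series(c, dtype="int64")
        c = c.astype("int64")
        if (c <= 0).any():
            raise ValueError("clonotype counts must be positive")
        df = c.rename("count").rename_axis("key").reset_index()
        df = df.sort_values(["count", "key"], ascending=[False, True], kind="mergesort")
        self.counts = df.set_index("key")["count"]

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def s_obs(self) -> int:
        return int(len(self.counts))

    @property
    def f1(self) -> int:
        return int((self.counts == 1).sum())

    @property
    def f2(self) -> int:
        return int((self.counts == 2).sum())

    @property
    def proportions(self) -> pd.Series:
        return self.counts / self.n

    def _require_nonempty(self) -> None:
        if self.s_obs == 0 or self.n == 0:
            raise ValueError("statistic undefined on an empty clonotype table")

    def to_frame(self) -> pd.DataFrame:
        """Tidy export with metadata columns."""
        df = self.counts.rename("count").reset_index()
        df["proportion"] = df["count"] / self.n
        df["key_level"] = self.key_level
        for name in ("tumor_model", "tissue", "subtype"):
            df[name] = getattr(self.meta, name)
        df["round"] = self.meta.round
        df["replicate"] = self.meta.replicate
        return df


def _key_of(record, key_level: str) -> str:
    if key_level == "full_aa":
        return record.full_aa
    if key_level == "cdr3_aa":
        return record.cdr3_aa
    if key_level == "cdr3_nt":
        return record.region_nt("CDR3")
    raise ValueError(f"unknown key_level {key_level!r}")


def build_clonotypes(
    records: Iterable, key_level: str = "full_aa", meta: SampleMeta = SampleMeta()
) -> ClonotypeTable:
    """Group complete VHH records into a clonotype table under ``key_level``."""
    counts: dict[str, int] = {}
    for rec in records:
        k = _key_of(rec, key_level)
        counts[k] = counts.get(k, 0) + 1
    return ClonotypeTable(pd.Series(counts, dtype="int64"), key_level, meta)


def table_from_counts(
    counts: Mapping[str, int], key_level: str = "full_aa", meta: SampleMeta = SampleMeta()
) -> ClonotypeTable:
    """Clonotype table straight from a key -> count mapping (zeros dropped)."""
    nz = {k: int(v) for k, v in counts.items() if v}
    return ClonotypeTable(pd.Series(nz, dtype="int64"), key_level, meta)


def merge_replicates(tables: Sequence[ClonotypeTable]) -> ClonotypeTable:
    """Pool replicate samples of one stratum by summing counts per key."""
    if not tables:
        raise ValueError("no tables to merge")
    first = tables[0]
    for t in tables[1:]:
        if t.key_level != first.key_level:
            raise ValueError("cannot merge tables with different key levels")
        if t.meta.stratum() != first.meta.stratum():
            raise ValueError("cannot merge tables from different strata")
    total = pd.concat([t.counts for t in tables]).groupby(level=0).sum()
    return ClonotypeTable(total, first.key_level, first.meta.stratum())


# ---------------------------------------------------------------------------
# Clonality
# ---------------------------------------------------------------------------


def percent_unique(table: ClonotypeTable) -> float:
    """Distinct clonotypes as a percentage of total reads, 100 * S_obs / n."""
    table._require_nonempty()
    return 100.0 * table.s_obs / table.n


def _check_bins(bins: Sequence[tuple[int, Optional[int]]]) -> None:
    prev_hi = 0
    for lo, hi in bins:
        if lo <= prev_hi:
            raise ValueError(f"bins overlap or are unordered at ({lo}, {hi})")
        if hi is not None:
            if hi < lo:
                raise ValueError(f"empty bin ({lo}, {hi})")
            prev_hi = hi
        else:
            prev_hi = np.iinfo(np.int64).max


def clonality_by_rank(
    table: ClonotypeTable,
    rank_bins: Sequence[tuple[int, Optional[int]]] = DEFAULT_RANK_BINS,
) -> dict[tuple[int, Optional[int]], float]:
    """Proportion of reads occupied by clones in each abundance-rank bin."""
    table._require_nonempty()
    _check_bins(rank_bins)
    p = table.proportions.to_numpy()  # already sorted desc, ties lexicographic
    csum = np.concatenate([[0.0], np.cumsum(p)])
    out = {}
    for lo, hi in rank_bins:
        a = min(lo - 1, len(p))
        b = len(p) if hi is None else min(hi, len(p))
        out[(lo, hi)] = float(csum[b] - csum[a]) if b > a else 0.0
    return out


def clonality_by_count(
    table: ClonotypeTable,
    count_bins: Sequence[tuple[int, Optional[int]]] = DEFAULT_COUNT_BINS,
) -> dict[tuple[int, Optional[int]], float]:
    """Proportion of reads occupied by clones whose raw count falls in each bin."""
    table._require_nonempty()
    _check_bins(count_bins)
    x = table.counts.to_numpy()
    n = table.n
    out = {}
    for lo, hi in count_bins:
        mask = (x >= lo) if hi is None else (x >= lo) & (x <= hi)
        out[(lo, hi)] = float(x[mask].sum() / n)
    return out


# ---------------------------------------------------------------------------
# Diversity
# ---------------------------------------------------------------------------


def shannon(table: ClonotypeTable) -> float:
    """Shannon entropy H = -sum p_i ln p_i, in nats."""
    table._require_nonempty()
    p = table.proportions.to_numpy()
    return float(-(p * np.log(p)).sum())


def simpson(table: ClonotypeTable) -> tuple[float, float]:
    """(Simpson index sum p_i^2, inverse Simpson)."""
    table._require_nonempty()
    s = float((table.proportions.to_numpy() ** 2).sum())
    return s, 1.0 / s


def true_diversity(table: ClonotypeTable, q: float) -> float:
    """Hill number D_q = (sum p_i^q)^(1/(1-q)); D_1 = exp(H) by continuity."""
    table._require_nonempty()
    if q < 0:
        raise ValueError("Hill order q must be >= 0")
    if q == 0:
        return float(table.s_obs)
    if q == 1:
        return float(math.exp(shannon(table)))
    p = table.proportions.to_numpy()
    return float((p**q).sum() ** (1.0 / (1.0 - q)))


def hill_numbers(table: ClonotypeTable, orders: Sequence[float] = (0, 1, 2)) -> dict[float, float]:
    return {float(q): true_diversity(table, q) for q in orders}


def _log_choose(n: np.ndarray | float, k: float) -> np.ndarray:
    return gammaln(np.asarray(n) + 1) - gammaln(k + 1) - gammaln(np.asarray(n) - k + 1)


def rarefaction(table: ClonotypeTable, depths: Sequence[int]) -> dict[int, float]:
    """Expected richness at subsampled depths m <= n (analytic hypergeometric).

    E[S(m)] = S_obs - sum_i C(n - x_i, m) / C(n, m), evaluated in log space.
    """
    table._require_nonempty()
    x = table.counts.to_numpy().astype(np.float64)
    n = table.n
    out = {}
    for m in depths:
        if not 1 <= m <= n:
            raise ValueError(f"rarefaction depth {m} outside [1, {n}]")
        keep = (n - x) >= m
        terms = np.exp(_log_choose(n - x[keep], m) - _log_choose(float(n), m))
        out[int(m)] = float(table.s_obs - terms.sum())
    return out


def chao1_unseen(table: ClonotypeTable) -> float:
    """Chao1-style estimate of the number of unseen clonotypes, f0_hat."""
    n, f1, f2 = table.n, table.f1, table.f2
    if f1 == 0:
        return 0.0
    if f2 > 0:
        return (n - 1) / n * f1 * f1 / (2.0 * f2)
    return (n - 1) / n * f1 * (f1 - 1) / 2.0


def extrapolation(table: ClonotypeTable, depths: Sequence[int]) -> dict[int, float]:
    """Estimated richness at depths m > n (Chao1-based extrapolation).

    S(n + m*) = S_obs + f0_hat * [1 - (1 - f1 / (n f0_hat + f1))^m*]; with
    f1 = 0 the curve is flat at S_obs.
    """
    table._require_nonempty()
    n, s, f1 = table.n, table.s_obs, table.f1
    f0 = chao1_unseen(table)
    out = {}
    for m in depths:
        if m <= n:
            raise ValueError(f"extrapolation depth {m} must exceed n={n}")
        if f0 == 0.0 or f1 == 0:
            out[int(m)] = float(s)
            continue
        mstar = m - n
        out[int(m)] = float(s + f0 * (1.0 - (1.0 - f1 / (n * f0 + f1)) ** mstar))
    return out


@dataclass
class DiversityResult:
    """Bundle of diversity statistics for one clonotype table."""

    shannon: float
    simpson: float
    inverse_simpson: float
    hill: dict[float, float]
    rarefaction: list[tuple[int, float]]
    extrapolation: list[tuple[int, float]]

    def to_dict(self) -> dict:
        return {
            "shannon_nats": self.shannon,
            "simpson": self.simpson,
            "inverse_simpson": self.inverse_simpson,
            "hill": {str(q): v for q, v in self.hill.items()},
            "rarefaction": [[m, s] for m, s in self.rarefaction],
            "extrapolation": [[m, s] for m, s in self.extrapolation],
        }


def _depth_grid(n: int, n_points: int, cap: float) -> tuple[list[int], list[int]]:
    interp = sorted({max(1, round(f * n)) for f in np.linspace(0.05, 1.0, n_points)})
    extra = sorted({m for m in (round(f * n) for f in np.linspace(1.0, cap, n_points)) if m > n})
    return interp, extra


def diversity_result(
    table: ClonotypeTable, n_points: int = 20, extrapolation_cap: float = 2.0
) -> DiversityResult:
    """All diversity statistics; extrapolation capped at ``cap * n`` reads."""
    si, inv = simpson(table)
    interp, extra = _depth_grid(table.n, n_points, extrapolation_cap)
    rare = rarefaction(table, interp)
    ext = extrapolation(table, extra) if extra else {}
    return DiversityResult(
        shannon=shannon(table),
        simpson=si,
        inverse_simpson=inv,
        hill=hill_numbers(table),
        rarefaction=sorted(rare.items()),
        extrapolation=sorted(ext.items()),
    )


def rarefaction_curve(
    table: ClonotypeTable,
    sample_id: str = "",
    n_points: int = 20,
    extrapolation_cap: float = 2.0,
) -> pd.DataFrame:
    """Tidy interpolated + extrapolated richness curve for plotting/export."""
    res = diversity_result(table, n_points, extrapolation_cap)
    rows = [(sample_id, m, s, "interpolated") for m, s in res.rarefaction]
    rows += [(sample_id, m, s, "extrapolated") for m, s in res.extrapolation]
    return pd.DataFrame(rows, columns=["sample_id", "depth", "richness", "method"])
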