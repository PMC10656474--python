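"""Cross-round clone tracking, enrichment filtering and subtype selectivity.

Tracks clonotype proportions across biopanning rounds, applies the
late-over-early enrichment screen (BP3+BP4 mass versus BP1+BP2 mass on
pseudocounted proportions), scores cell-subtype selectivity as each clone's
share of late-round abundance across the five sorted subtypes, and compares
NGS clonotypes with Sanger-sequenced clone inserts at the CDR3 level.

The screen is a filter, not a significance test: proportions are computed
with a pseudocount added to every clone's count in every round (default 0.5,
which keeps the ratio depth-invariant and defined for absent clones), a
clone passes when its late mass exceeds its early mass and it has at least
``min_late_count`` raw reads in BP3+BP4.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import amplicon as amp
from .repertoire import CELL_SUBTYPES, ClonotypeTable, SampleMeta

__all__ = [
    "BiopanningSeries",
    "SelectivityMatrix",
    "SangerComparison",
    "track_clones",
    "top_clone_fate",
    "enrichment_filter",
    "selectivity_matrix",
    "overlap_sets",
    "sanger_compare",
]

logger = logging.getLogger(__name__)

EARLY_ROUNDS = (1, 2)
LATE_ROUNDS = (3, 4)


@dataclass
class BiopanningSeries:
    """Ordered clonotype tables for one stratum across rounds BP0..BP4."""

    tables: dict[int, ClonotypeTable]
    meta: SampleMeta = field(default_factory=SampleMeta)

    def __post_init__(self) -> None:
        if not self.tables:
            raise ValueError("empty series")
        levels = {t.key_level for t in self.tables.values()}
        if len(levels) > 1:
            raise ValueError(f"mixed key levels in series: {sorted(levels)}")
        self.tables = dict(sorted(self.tables.items()))

    @property
    def rounds(self) -> list[int]:
        return list(self.tables)

    @property
    def key_level(self) -> str:
        return next(iter(self.tables.values())).key_level

    def union_keys(self) -> pd.Index:
        keys: pd.Index = pd.Index([], dtype=object)
        for t in self.tables.values():
            keys = keys.union(t.counts.index)
        return keys.sort_values()

    def count_matrix(self, keys: Optional[pd.Index] = None) -> pd.DataFrame:
        """Keys x rounds raw count matrix (absent = 0)."""
        if keys is None:
            keys = self.union_keys()
        data = {
            r: t.counts.reindex(keys, fill_value=0) for r, t in self.tables.items()
        }
        return pd.DataFrame(data, index=keys)


def track_clones(series: BiopanningSeries, keys: Sequence[str]) -> pd.DataFrame:
    """Per-key proportion trajectories across rounds (0 where absent)."""
    if len(keys) == 0:
        raise ValueError("no keys to track")
    idx = pd.Index(keys)
    data = {
        r: t.proportions.reindex(idx, fill_value=0.0) for r, t in series.tables.items()
    }
    traj = pd.DataFrame(data, index=idx)
    absent = traj.sum(axis=1) == 0
    if absent.any():
        warnings.warn(
            f"{int(absent.sum())} tracked key(s) absent from every round", stacklevel=2
        )
    return traj


def top_clone_fate(series: BiopanningSeries, k: int, anchor_round: int) -> pd.DataFrame:
    """Trajectories of the k most abundant clones of ``anchor_round``."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if anchor_round not in series.tables:
        raise ValueError(f"round BP{anchor_round} missing from series")
    anchor = series.tables[anchor_round]
    if k > anchor.s_obs:
        warnings.warn(
            f"k={k} exceeds the {anchor.s_obs} clones of BP{anchor_round}; truncating",
            stacklevel=2,
        )
        k = anchor.s_obs
    top = anchor.counts.index[:k]  # counts sorted desc, ties lexicographic
    return track_clones(series, list(top))


def enrichment_filter(
    series: BiopanningSeries,
    pseudocount: float = 0.5,
    min_late_count: int = 2,
    min_ratio: float = 1.0,
) -> pd.DataFrame:
    """Late-over-early enrichment screen on rounds BP1-BP4.

    Returns one row per union key with pseudocounted per-round proportions,
    early/late masses, the enrichment ratio, log2 ratio, raw late count and
    the pass flag, sorted by log2 enrichment descending.  A clone passes
    when ratio > ``min_ratio`` and its raw BP3+BP4 count reaches
    ``min_late_count``; all three constants are screen calibration, exposed
    because their useful values scale with sequencing depth.
    """
    for r in EARLY_ROUNDS + LATE_ROUNDS:
        if r not in series.tables:
            raise ValueError(f"enrichment filter requires round BP{r}")
    rounds = list(EARLY_ROUNDS + LATE_ROUNDS)
    keys: pd.Index = pd.Index([], dtype=object)
    for r in rounds:
        keys = keys.union(series.tables[r].counts.index)
    keys = keys.sort_values()
    counts = series.count_matrix(keys)
    pseudo = counts[rounds] + pseudocount
    props = pseudo / pseudo.sum(axis=0)

    early = props[list(EARLY_ROUNDS)].sum(axis=1)
    late = props[list(LATE_ROUNDS)].sum(axis=1)
    ratio = late / early
    raw_late = counts[list(LATE_ROUNDS)].sum(axis=1)

    out = props.rename(columns={r: f"p_bp{r}" for r in rounds})
    out["early_mass"] = early
    out["late_mass"] = late
    out["enrichment_ratio"] = ratio
    out["log2_enrichment"] = np.log2(ratio)
    out["late_count"] = raw_late
    out["passes_filter"] = (ratio > min_ratio) & (raw_late >= min_late_count)
    out = out.rename_axis("key").reset_index()
    return out.sort_values(
        ["log2_enrichment", "key"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


@dataclass
class SelectivityMatrix:
    """Clones x subtypes relative-enrichment shares (rows sum to 1)."""

    shares: pd.DataFrame  # index key, columns subtypes
    assigned_subtype: pd.Series
    score: pd.Series
    ambiguous: pd.Series
    mode: str = "share"

    def to_frame(self) -> pd.DataFrame:
        df = self.shares.copy()
        df["assigned_subtype"] = self.assigned_subtype
        df["selectivity_score"] = self.score
        df["ambiguous"] = self.ambiguous
        return df.rename_axis("key").reset_index()


def selectivity_matrix(
    series_by_subtype: Mapping[str, BiopanningSeries],
    keys: Sequence[str],
    pseudocount: float = 0.5,
    mode: str = "share",
    subtype_order: Sequence[str] = CELL_SUBTYPES,
) -> SelectivityMatrix:
    """Relative late-round enrichment of each clone across cell subtypes.

    For clone c and subtype s, a_{c,s} is the mean pseudocounted proportion
    of c in BP3 and BP4 of subtype s; shares r_{c,s} = a_{c,s} / sum_s'
    a_{c,s'} so each row sums to 1.  ``mode='zscore'`` instead z-scores each
    row of a.  Clones with zero raw counts in every subtype's late rounds are
    dropped with a warning; rows whose maximum is tied are flagged ambiguous
    and assigned by the fixed ``subtype_order``.
    """
    missing = [s for s in subtype_order if s not in series_by_subtype]
    if missing:
        raise ValueError(f"missing subtype series: {missing}")
    levels = {series_by_subtype[s].key_level for s in subtype_order}
    if len(levels) > 1:
        raise ValueError("subtype series must share a key level")
    if mode not in ("share", "zscore"):
        raise ValueError(f"unknown mode {mode!r}")

    idx = pd.Index(keys).drop_duplicates()
    a = pd.DataFrame(index=idx, columns=list(subtype_order), dtype=float)
    raw = pd.DataFrame(0, index=idx, columns=list(subtype_order), dtype=int)
    for s in subtype_order:
        series = series_by_subtype[s]
        for r in LATE_ROUNDS:
            if r not in series.tables:
                raise ValueError(f"subtype {s} lacks round BP{r}")
        union = series.union_keys()
        cols = []
        for r in LATE_ROUNDS:
            c = series.tables[r].counts.reindex(union, fill_value=0) + pseudocount
            cols.append((c / c.sum()).reindex(idx, fill_value=pseudocount / c.sum()))
            raw[s] += series.tables[r].counts.reindex(idx, fill_value=0).astype(int)
        a[s] = sum(cols) / len(cols)

    present = raw.sum(axis=1) > 0
    if (~present).any():
        warnings.warn(
            f"dropping {int((~present).sum())} clone(s) absent from all subtypes",
            stacklevel=2,
        )
    a = a.loc[present]

    if mode == "share":
        shares = a.div(a.sum(axis=1), axis=0)
    else:
        mu = a.mean(axis=1)
        sd = a.std(axis=1, ddof=0)
        shares = a.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0).fillna(0.0)

    maxval = shares.max(axis=1)
    ambiguous = (shares.eq(maxval, axis=0)).sum(axis=1) > 1
    assigned = shares.idxmax(axis=1)  # first column on ties = fixed order
    return SelectivityMatrix(
        shares=shares, assigned_subtype=assigned, score=maxval, ambiguous=ambiguous, mode=mode
    )


def overlap_sets(
    tables: Mapping[str, ClonotypeTable | Iterable[str]],
) -> tuple[pd.DataFrame, dict[tuple[str, ...], int]]:
    """Venn-style membership of clonotype keys across named samples.

    Returns (membership table: keys x sample booleans, counts per exclusive
    intersection region keyed by the tuple of member names).
    """
    names = list(tables)
    key_sets: dict[str, set[str]] = {}
    levels = set()
    for name, t in tables.items():
        if isinstance(t, ClonotypeTable):
            key_sets[name] = set(t.counts.index)
            levels.add(t.key_level)
        else:
            key_sets[name] = set(t)
    if len(levels) > 1:
        raise ValueError("overlap requires a shared key level")
    all_keys = sorted(set().union(*key_sets.values())) if key_sets else []
    member = pd.DataFrame(
        {name: [k in key_sets[name] for k in all_keys] for name in names},
        index=pd.Index(all_keys, name="key"),
    )
    regions: dict[tuple[str, ...], int] = {}
    for _, row in member.iterrows():
        region = tuple(n for n in names if row[n])
        regions[region] = regions.get(region, 0) + 1
    return member, regions


@dataclass
class SangerComparison:
    """Sanger-picked clones versus late-round NGS clonotypes (CDR3 level)."""

    n_sanger_records: int
    n_annotated: int
    n_unique_cdr3: int
    n_found_in_ngs: int
    per_clone: pd.DataFrame  # cdr3_aa, found, best_proportion, total_count

    @property
    def fraction_found(self) -> float:
        return self.n_found_in_ngs / self.n_unique_cdr3 if self.n_unique_cdr3 else float("nan")

    @property
    def percent_found(self) -> float:
        return 100.0 * self.fraction_found


def sanger_compare(
    sanger_seqs: Mapping[str, str],
    ngs_tables: Sequence[ClonotypeTable],
    scaffold: amp.Scaffold = amp.DEFAULT_SCAFFOLD,
) -> SangerComparison:
    """Annotate Sanger-sequenced inserts and look their CDR3s up in
    late-round (BP3/BP4) NGS clonotype tables keyed at ``cdr3_aa``.

    ``sanger_seqs`` maps record id to a coding nucleotide sequence.  A
    Sanger clone counts as found when its CDR3 amino-acid key occurs in any
    supplied table.  Unannotatable records are excluded and logged.
    """
    for t in ngs_tables:
        if t.key_level != "cdr3_aa":
            raise ValueError("NGS tables must be keyed at cdr3_aa for Sanger comparison")

    cdr3s: list[str] = []
    for rid, seq in sanger_seqs.items():
        try:
            rec = amp.annotate_vhh(seq, scaffold=scaffold, read_id=rid)
        except ValueError:
            rec = None
        if rec is None or not rec.complete:
            logger.info("Sanger record %s could not be annotated; excluded", rid)
            continue
        cdr3s.append(rec.cdr3_aa)
    unique = sorted(set(cdr3s))

    rows = []
    for c in unique:
        best_p, total = 0.0, 0
        for t in ngs_tables:
            if c in t.counts.index:
                total += int(t.counts[c])
                best_p = max(best_p, float(t.counts[c] / t.n))
        rows.append((c, total > 0, best_p, total))
    per_clone = pd.DataFrame(rows, columns=["cdr3_aa", "found", "best_proportion", "total_count"])
    return SangerComparison(
        n_sanger_records=len(sanger_seqs),
        n_annotated=len(cdr3s),
        n_unique_cdr3=len(unique),
        n_found_in_ngs=int(per_clone["found"].sum()) if len(per_clone) else 0,
        per_clone=per_clone,
    )
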