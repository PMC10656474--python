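"""Clonotype tables and diversity statistics against independent oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from panrep import (
    build_clonotypes,
    clonality_by_count,
    clonality_by_rank,
    extrapolation,
    hill_numbers,
    merge_replicates,
    percent_unique,
    rarefaction,
    shannon,
    simpson,
    table_from_counts,
    true_diversity,
)
from panrep.amplicon import annotate_vhh
from panrep.repertoire import SampleMeta, chao1_unseen, diversity_result
from panrep.simdata import SimulationConfig, emit_sample_reads, simulate_biopanning

counts_strategy = st.lists(st.integers(min_value=1, max_value=50), min_size=1, max_size=30)


def _table(counts, **meta):
    return table_from_counts({f"k{i:03d}": c for i, c in enumerate(counts)},
                             meta=SampleMeta(**meta))


class TestTables:
    def test_counts_proportions_and_rare_classes(self):
        t = _table([2, 1])  # keys k000:2, k001:1
        assert t.n == 3 and t.s_obs == 2
        assert list(t.proportions) == pytest.approx([2 / 3, 1 / 3])
        assert t.f1 == 1 and t.f2 == 1

    def test_ordering_count_desc_then_key(self):
        t = table_from_counts({"b": 2, "c": 5, "a": 2})
        assert list(t.counts.index) == ["c", "a", "b"]

    def test_synonymous_nucleotide_variants_collapse_at_aa_level(self, tiny_library):
        from Bio.Data.CodonTable import standard_dna_table

        clone = tiny_library[0]
        # same protein, different codon at some CDR3 residue
        rec1 = annotate_vhh(clone.nt_cds)
        start, end = rec1.regions["CDR3"]
        alt = None
        for s in range(start, end):
            codons = sorted(
                c for c, a in standard_dna_table.forward_table.items()
                if a == rec1.aa_sequence[s]
            )
            if len(codons) > 1:
                old = clone.nt_cds[3 * s : 3 * s + 3]
                new = codons[1] if old == codons[0] else codons[0]
                alt = clone.nt_cds[: 3 * s] + new + clone.nt_cds[3 * s + 3 :]
                break
        assert alt is not None
        rec2 = annotate_vhh(alt)
        t_aa = build_clonotypes([rec1, rec2], key_level="full_aa")
        t_nt = build_clonotypes([rec1, rec2], key_level="cdr3_nt")
        assert t_aa.s_obs == 1 and t_nt.s_obs == 2

    def test_error_free_sample_matches_truth_clone_count(self):
        cfg = SimulationConfig(seed=17, n_clones=150, n_binders_per_subtype=0,
                               reads_per_sample=400, n_replicates=1, seq_error_rate=0.0)
        sim = simulate_biopanning(cfg)
        emit_sample_reads(sim, 1, "CD45", 0)
        smp = sim.sample(1, "CD45")
        aa_of = {i: c.aa_sequence() for i, c in enumerate(sim.library)}
        sampled_aa = {aa_of[i] for i in np.nonzero(smp.read_counts)[0]}
        counts = {}
        for i in np.nonzero(smp.read_counts)[0]:
            counts[aa_of[i]] = counts.get(aa_of[i], 0) + int(smp.read_counts[i])
        t = table_from_counts(counts)
        assert t.s_obs == len(sampled_aa)
        assert t.n == cfg.reads_per_sample

    def test_merge_replicates_sums_counts(self):
        a = table_from_counts({"A": 1}, meta=SampleMeta(subtype="CD8", round=1, replicate=0))
        b = table_from_counts({"A": 1, "B": 2}, meta=SampleMeta(subtype="CD8", round=1, replicate=1))
        m = merge_replicates([a, b])
        assert m.counts.to_dict() == {"B": 2, "A": 2}
        assert m.n == a.n + b.n
        assert merge_replicates([a]).counts.to_dict() == {"A": 1}

    def test_merge_rejects_mixed_key_levels_or_strata(self):
        a = table_from_counts({"A": 1}, key_level="full_aa")
        b = table_from_counts({"A": 1}, key_level="cdr3_aa")
        with pytest.raises(ValueError, match="key level"):
            merge_replicates([a, b])
        c = table_from_counts({"A": 1}, meta=SampleMeta(subtype="CD8"))
        with pytest.raises(ValueError, match="strata"):
            merge_replicates([a, c])


class TestClonality:
    def test_percent_unique(self):
        assert percent_unique(_table([1, 1, 1])) == pytest.approx(100.0)
        assert percent_unique(_table([2, 1])) == pytest.approx(100 * 2 / 3)
        assert percent_unique(_table([3])) == pytest.approx(100 / 3)

    def test_rank_bins(self):
        t = _table([60, 30, 10])
        out = clonality_by_rank(t, [(1, 2), (3, 10)])
        assert out[(1, 2)] == pytest.approx(0.9)
        assert out[(3, 10)] == pytest.approx(0.1)
        single = clonality_by_rank(_table([5]), [(1, 10), (11, 100)])
        assert single == {(1, 10): pytest.approx(1.0), (11, 100): 0.0}
        uniform = clonality_by_rank(_table([1] * 100), [(1, 10), (11, None)])
        assert uniform[(1, 10)] == pytest.approx(0.1)
        assert uniform[(11, None)] == pytest.approx(0.9)

    def test_count_bins(self):
        t = _table([1, 2, 3, 100])
        out = clonality_by_count(t, [(1, 1), (2, 3), (4, None)])
        assert out[(1, 1)] == pytest.approx(1 / 106)
        assert out[(2, 3)] == pytest.approx(5 / 106)
        assert out[(4, None)] == pytest.approx(100 / 106)

    def test_overlapping_bins_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            clonality_by_rank(_table([1, 1]), [(1, 10), (5, 20)])


class TestDiversity:
    def test_shannon_closed_forms(self):
        assert shannon(_table([5] * 4)) == pytest.approx(math.log(4), abs=1e-12)
        assert shannon(_table([7])) == pytest.approx(0.0, abs=1e-12)
        # direct-summation oracle for counts [1,2,3,4]
        p = np.array([1, 2, 3, 4]) / 10
        assert shannon(_table([1, 2, 3, 4])) == pytest.approx(-(p * np.log(p)).sum(), abs=1e-12)
        assert shannon(_table([1, 2, 3, 4])) == pytest.approx(1.27985, abs=1e-5)

    def test_simpson_closed_forms(self):
        assert simpson(_table([3] * 5)) == (pytest.approx(0.2), pytest.approx(5.0))
        assert simpson(_table([9])) == (pytest.approx(1.0), pytest.approx(1.0))
        si, inv = simpson(_table([1, 1, 2]))
        assert si == pytest.approx(0.375) and inv == pytest.approx(8 / 3)

    def test_hill_numbers_closed_forms(self):
        t = _table([1, 1, 2])
        assert true_diversity(t, 0) == 3
        assert true_diversity(t, 2) == pytest.approx(8 / 3)
        uniform = _table([4] * 7)
        for q in (0, 0.5, 1, 2, 3):
            assert true_diversity(uniform, q) == pytest.approx(7.0, abs=1e-9)
        with pytest.raises(ValueError):
            true_diversity(t, -1)

    def test_empty_table_rejected(self):
        empty = build_clonotypes([])
        for fn in (shannon, simpson, percent_unique):
            with pytest.raises(ValueError):
                fn(empty)

    @settings(deadline=None, derandomize=True)
    @given(counts_strategy)
    def test_hill_identities_on_random_tables(self, counts):
        t = _table(counts)
        h = hill_numbers(t, (0, 1, 2))
        p = t.proportions.to_numpy()
        assert h[0.0] == t.s_obs
        assert h[1.0] == pytest.approx(math.exp(shannon(t)), rel=1e-9)
        assert h[2.0] == pytest.approx(1 / (p ** 2).sum(), rel=1e-9)

    @settings(deadline=None, derandomize=True)
    @given(counts_strategy)
    def test_hill_nonincreasing_in_order(self, counts):
        t = _table(counts)
        qs = (0, 0.5, 1, 1.5, 2, 3)
        d = [true_diversity(t, q) for q in qs]
        assert all(a >= b - 1e-9 for a, b in zip(d, d[1:]))

    def test_against_scikit_bio(self):
        # independent implementation cross-check
        from skbio.diversity.alpha import enspie, shannon as sk_shannon, simpson as sk_simpson

        counts = [5, 3, 3, 2, 1, 1]
        t = _table(counts)
        assert shannon(t) == pytest.approx(sk_shannon(counts, base=math.e), rel=1e-12)
        assert simpson(t)[0] == pytest.approx(1 - sk_simpson(counts), rel=1e-12)
        assert true_diversity(t, 2) == pytest.approx(enspie(counts), rel=1e-12)


def _rarefaction_enumeration(counts, m):
    """Exhaustive expectation of richness over all m-subsets of reads."""
    reads = [i for i, c in enumerate(counts) for _ in range(c)]
    vals = [len(set(sub)) for sub in itertools.combinations(reads, m)]
    return sum(vals) / len(vals)


class TestRarefaction:
    def test_boundary_depths(self):
        t = _table([4, 3, 2, 1])
        assert rarefaction(t, [t.n])[t.n] == pytest.approx(t.s_obs, abs=1e-9)
        assert rarefaction(t, [1])[1] == pytest.approx(1.0, abs=1e-9)

    def test_matches_exhaustive_enumeration(self):
        assert rarefaction(_table([2, 2]), [2])[2] == pytest.approx(5 / 3, abs=1e-12)
        for counts, m in [([3, 1], 2), ([2, 2, 1], 3), ([4, 2, 1], 4)]:
            expect = _rarefaction_enumeration(counts, m)
            assert rarefaction(_table(counts), [m])[m] == pytest.approx(expect, abs=1e-9)

    def test_matches_monte_carlo_subsampling(self, rng):
        counts = np.array([12, 7, 5, 3, 2, 1, 1, 1])
        t = _table(list(counts))
        reads = np.repeat(np.arange(len(counts)), counts)
        for m in (5, 15, 25):
            sims = np.array([
                len(np.unique(rng.choice(reads, size=m, replace=False)))
                for _ in range(1000)
            ])
            se = sims.std(ddof=1) / math.sqrt(len(sims))
            assert abs(rarefaction(t, [m])[m] - sims.mean()) <= 3 * se + 1e-9

    def test_nondecreasing_in_depth(self):
        t = _table([9, 4, 2, 1, 1])
        vals = list(rarefaction(t, range(1, t.n + 1)).values())
        assert all(a <= b + 1e-9 for a, b in zip(vals, vals[1:]))

    def test_depth_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rarefaction(_table([2, 2]), [5])


class TestExtrapolation:
    def test_worked_chao1_case(self):
        t = _table([1, 1, 2])  # n=4, f1=2, f2=1
        assert chao1_unseen(t) == pytest.approx(1.5, abs=1e-12)
        far = extrapolation(t, [4000])[4000]
        assert far == pytest.approx(3 + 1.5, abs=1e-6)  # asymptote S_obs + f0

    def test_no_singletons_flat_curve(self):
        t = _table([2, 2, 3])
        out = extrapolation(t, [8, 20])
        assert all(v == t.s_obs for v in out.values())

    def test_meets_rarefaction_continuously_at_n(self):
        t = _table([1, 1, 2, 5, 3])
        at_n = rarefaction(t, [t.n])[t.n]
        just_past = extrapolation(t, [t.n + 1])[t.n + 1]
        assert at_n == pytest.approx(t.s_obs, abs=1e-9)
        f0, f1, n = chao1_unseen(t), t.f1, t.n
        assert just_past - at_n == pytest.approx(f0 * f1 / (n * f0 + f1), abs=1e-9)

    def test_depth_below_n_rejected(self):
        with pytest.raises(ValueError):
            extrapolation(_table([2, 2]), [3])

    def test_diversity_result_bundle(self):
        t = _table([5, 3, 1, 1])
        res = diversity_result(t, n_points=5)
        d = res.to_dict()
        assert d["hill"]["0.0"] == t.s_obs
        assert res.rarefaction[-1][0] == t.n
        assert all(m > t.n for m, _ in res.extrapolation)
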