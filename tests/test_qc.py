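"""Tests for the amplicon filter cascade."""

import collections

import numpy as np
import pytest

from mhcmate import synth
from mhcmate.qc import (
    CombinedVariant,
    GenotypeRejection,
    QCConfig,
    call_genotype,
    clean_variants,
    combine_runs,
    consolidate_errors,
    flag_chimeras,
    genotype_summary,
    pairwise_differences,
    run_pipeline,
)
from mhcmate.types import AmpliconVariantRecord, IndividualGenotype

from conftest import make_genotype


def rec(seq, depth, ind="i1", run="run1", quality=37.0):
    return AmpliconVariantRecord(individual_id=ind, run_id=run,
                                 sequence=seq, depth=depth,
                                 mean_quality=quality)


CFG20 = QCConfig(expected_length_nt=20, min_singleton_reads=10)


# ----------------------------------------------------------------- clean

def test_quality_threshold_strictly_below_30():
    cfg = QCConfig(expected_length_nt=4)
    kept = clean_variants(
        [rec("ACGT", 5, quality=29.9), rec("ACGT", 5, quality=30.0)], cfg
    )
    assert [r.mean_quality for r in kept] == [30.0]


def test_anomalous_length_dropped():
    cfg = QCConfig(expected_length_nt=298)
    seq298 = "ACGT" * 74 + "AC"
    kept = clean_variants(
        [rec(seq298[:297], 5), rec(seq298, 5), rec(seq298 + "A", 5)], cfg
    )
    assert [len(r.sequence) for r in kept] == [298]


def test_clean_empty_input():
    assert clean_variants([], QCConfig()) == []


# ------------------------------------------------------------ consolidate

def test_single_substitution_merges_into_deeper_parent():
    # L=298 budgets: subs <= max(1, floor(0.005*298)) = 1
    parent = "A" * 298
    child = "C" + "A" * 297
    out = consolidate_errors([rec(parent, 500), rec(child, 50)], QCConfig())
    assert len(out) == 1
    assert out[0].sequence == parent
    assert out[0].depth == 550


def test_two_substitutions_retained():
    parent = "A" * 298
    child = "CC" + "A" * 296
    out = consolidate_errors([rec(parent, 500), rec(child, 50)], QCConfig())
    assert sorted(r.depth for r in out) == [50, 500]


def test_indel_budget_two_bases():
    # floor(0.01*298)=2 indel bases allowed
    parent = "ACGT" * 74 + "AC"
    child_1del = parent[:100] + parent[101:]
    child_3del = parent[:100] + parent[103:]
    out = consolidate_errors(
        [rec(parent, 500), rec(child_1del, 40), rec(child_3del, 40)],
        QCConfig(),
    )
    seqs = {r.sequence for r in out}
    assert child_1del not in seqs
    assert child_3del in seqs


def test_depth_conservation(rng):
    base = "".join(rng.choice(list("ACGT"), size=40))
    records = [rec(base, 300)]
    for i in range(6):
        pos = int(rng.integers(0, 40))
        alt = "ACGT"[(("ACGT".index(base[pos])) + 1) % 4]
        records.append(rec(base[:pos] + alt + base[pos + 1:],
                           int(rng.integers(1, 30))))
    cfg = QCConfig(expected_length_nt=40)
    out = consolidate_errors(records, cfg)
    assert sum(r.depth for r in out) == sum(r.depth for r in records)


def test_merge_order_most_abundant_parent_first():
    # child within budget of two parents merges into the deeper one
    p1 = "A" * 20
    p2 = "A" * 19 + "T"
    child = "A" * 19 + "G"  # 1 sub from both parents
    out = consolidate_errors(
        [rec(p1, 500), rec(p2, 100), rec(child, 10)], CFG20
    )
    by_seq = {r.sequence: r.depth for r in out}
    # p2 itself is 1 sub from p1 and shallower -> merged too
    assert by_seq == {p1: 610}


def test_pairwise_differences_alignment():
    assert pairwise_differences("ACGTACGT", "ACGAACGT") == (1, 0)
    subs, indels = pairwise_differences("ACGTACGT", "ACGACGT")
    assert indels == 1 and subs == 0


# --------------------------------------------------------------- chimeras

def _amplicon_with_chimera(freq_parents=0.4):
    p1 = "AAAAACCCCCGGGGGTTTTT"
    p2 = "TTTTTGGGGGCCCCCAAAAA"
    chim = p1[:10] + p2[10:]
    total = 1000
    d_parent = int(freq_parents * total)
    d_other = total - 2 * d_parent - 50
    other = "ACGT" * 5
    return [rec(p1, d_parent), rec(p2, d_parent), rec(chim, 50),
            rec(other, d_other)], p1, p2, chim, other


def test_injected_chimera_removed():
    records, p1, p2, chim, other = _amplicon_with_chimera(0.4)
    out = flag_chimeras(records, CFG20)
    seqs = {r.sequence for r in out}
    assert chim not in seqs
    assert {p1, p2, other} <= seqs


def test_true_allele_not_a_splice_retained():
    records, *_ , other = _amplicon_with_chimera(0.4)
    out = flag_chimeras(records, CFG20)
    assert other in {r.sequence for r in out}


def test_low_frequency_parents_protect_chimera():
    # parents at 3% < 5% threshold: chimera retained
    p1 = "AAAAACCCCCGGGGGTTTTT"
    p2 = "TTTTTGGGGGCCCCCAAAAA"
    chim = p1[:10] + p2[10:]
    filler = "ACGT" * 5
    records = [rec(p1, 30), rec(p2, 30), rec(chim, 20), rec(filler, 920)]
    out = flag_chimeras(records, CFG20)
    assert chim in {r.sequence for r in out}


# ------------------------------------------------------------ combine/call

def test_combine_runs_sums_depths():
    records = [rec("ACGT", 120, run="run1"), rec("ACGT", 150, run="run2"),
               rec("AAAA", 40, run="run1")]
    out = combine_runs(records, QCConfig(expected_length_nt=4))
    by_seq = {v.sequence: v for v in out}
    assert by_seq["ACGT"].depth == 270
    assert by_seq["ACGT"].runs == {"run1", "run2"}
    assert by_seq["AAAA"].runs == {"run1"}
    assert sum(v.depth for v in out) == sum(r.depth for r in records)


def _cv(seq, depth, runs=("run1", "run2"), ind="i1"):
    return CombinedVariant(individual_id=ind, sequence=seq, depth=depth,
                           runs=frozenset(runs))


GOOD = "GGA" * 6 + "AC"  # 20 nt, stop-free in frame 0


def test_singleton_depth_rule_inclusive():
    cfg = QCConfig(expected_length_nt=20, min_singleton_reads=200,
                   min_amplicon_freq=0.0)
    low = call_genotype([_cv(GOOD, 199, runs=("run1",))], cfg)
    ok = call_genotype([_cv(GOOD, 200, runs=("run1",))], cfg)
    assert isinstance(low, GenotypeRejection)
    assert isinstance(ok, IndividualGenotype)


def test_amplicon_frequency_rule_inclusive():
    cfg = QCConfig(expected_length_nt=20, min_singleton_reads=1,
                   min_amplicon_freq=0.01)
    filler = "CCA" * 6 + "GT"
    out = call_genotype(
        [_cv(filler, 990), _cv(GOOD, 10)], cfg
    )
    assert isinstance(out, IndividualGenotype)
    assert len(out.allele_ids) == 2
    out2 = call_genotype([_cv(filler, 991), _cv(GOOD, 9)], cfg)
    assert len(out2.allele_ids) == 1


def test_two_run_rule_both_or_min_reads():
    cfg = QCConfig(expected_length_nt=20, min_singleton_reads=200,
                   min_amplicon_freq=0.0)
    single_low = _cv("CCA" * 6 + "GT", 150, runs=("run1",))
    single_high = _cv("TCA" * 6 + "GT", 250, runs=("run2",))
    both = _cv(GOOD, 50)
    out = call_genotype([both, single_low, single_high], cfg)
    assert isinstance(out, IndividualGenotype)
    assert len(out.allele_ids) == 2  # both-runs variant + deep single-run


def test_orf_and_length_validation():
    cfg = QCConfig(expected_length_nt=20, min_singleton_reads=1,
                   min_amplicon_freq=0.0)
    stop_seq = "TAA" + "GGA" * 5 + "AC"  # stop codon in frame 0
    short = "GGA" * 6  # 18 nt
    out = call_genotype(
        [_cv(GOOD, 500), _cv(stop_seq, 400), _cv(short, 300)], cfg
    )
    assert isinstance(out, IndividualGenotype)
    assert len(out.allele_ids) == 1


def test_truncation_to_four_deepest():
    cfg = QCConfig(expected_length_nt=20, min_singleton_reads=1,
                   min_amplicon_freq=0.0)
    variants = [
        _cv("GGA" * 6 + "AA", 500), _cv("GGC" * 6 + "AA", 400),
        _cv("GGG" * 6 + "AA", 300), _cv("GGT" * 6 + "AA", 200),
        _cv("GCA" * 6 + "AA", 100),
    ]
    out = call_genotype(variants, cfg)
    assert len(out.allele_ids) == 4
    assert out.allele_depths is not None
    assert min(out.allele_depths.values()) == 200


def test_rejection_is_typed_not_raised():
    cfg = QCConfig(expected_length_nt=20, min_singleton_reads=10_000)
    out = call_genotype([_cv(GOOD, 5, runs=("run1",))], cfg)
    assert isinstance(out, GenotypeRejection)
    assert out.individual_id == "i1"


def test_call_idempotence():
    cfg = QCConfig(expected_length_nt=20, min_singleton_reads=1,
                   min_amplicon_freq=0.01)
    first = call_genotype([_cv(GOOD, 500), _cv("CCA" * 6 + "GT", 300)], cfg)
    assert isinstance(first, IndividualGenotype)
    again = call_genotype(
        [_cv(seq, depth) for seq, depth in
         zip([GOOD, "CCA" * 6 + "GT"], [500, 300])], cfg
    )
    assert again.allele_ids == first.allele_ids


def test_min_freq_monotonicity(rng):
    # raising min_amplicon_freq never increases the called allele count
    seqs = ["GGA" * 6 + x for x in ("AA", "AC", "AG", "AT", "CA", "CC")]
    variants = [_cv(s, int(d)) for s, d in
                zip(seqs, rng.integers(5, 500, size=len(seqs)))]
    prev = None
    for freq in (0.0, 0.01, 0.05, 0.1, 0.3, 0.6):
        cfg = QCConfig(expected_length_nt=20, min_singleton_reads=1,
                       min_amplicon_freq=freq)
        out = call_genotype(variants, cfg)
        n = 0 if isinstance(out, GenotypeRejection) else len(out.allele_ids)
        if prev is not None:
            assert n <= prev
        prev = n


# ----------------------------------------------------- end-to-end recovery

def test_noiseless_pipeline_recovers_truth_exactly(small_pool):
    genotypes = synth.assign_genotypes(small_pool, 10, 2, 0.7, seed=8)
    cfg_sim = synth.ReadSimulationConfig(
        depth_mean=400, substitution_error_rate=0.0, indel_error_rate=0.0,
        chimera_fraction=0.0, n_runs=2, seed=2,
    )
    records = synth.simulate_reads(genotypes, small_pool, cfg_sim)
    qc_cfg = QCConfig(expected_length_nt=small_pool.length_nt)
    catalog = {a.seq: a.id for a in small_pool.alleles}
    called, rejected, _ = run_pipeline(records, qc_cfg, catalog)
    assert not rejected
    truth = {g.individual_id: g.allele_ids for g in genotypes}
    for g in called:
        assert g.allele_ids == truth[g.individual_id]


def test_noisy_pipeline_recall_precision(study_pool):
    # paper-level error rates, 500x depth, two runs: recall/precision >= 0.95
    skew = synth.solve_skew_for_top_share(99, 0.5)
    genotypes = synth.assign_genotypes(study_pool, 15, 2, skew, seed=3)
    cfg_sim = synth.ReadSimulationConfig(
        depth_mean=500, substitution_error_rate=0.005,
        indel_error_rate=0.01, chimera_fraction=0.05, n_runs=2, seed=7,
    )
    records = synth.simulate_reads(genotypes, study_pool, cfg_sim)
    catalog = {a.seq: a.id for a in study_pool.alleles}
    called, _, _ = run_pipeline(records, QCConfig(), catalog)
    truth = {g.individual_id: g.allele_ids for g in genotypes}
    called_by = {g.individual_id: g.allele_ids for g in called}
    tp = fp = fn = 0
    for ind, t in truth.items():
        c = called_by.get(ind, frozenset())
        tp += len(t & c)
        fp += len(c - t)
        fn += len(t - c)
    assert tp / (tp + fn) >= 0.95
    assert tp / (tp + fp) >= 0.95


# ---------------------------------------------------------------- summary

def test_summary_trivial_enumeration():
    genotypes = [make_genotype("a", {"A"}), make_genotype("b", {"A", "B"})]
    s = genotype_summary(genotypes)
    assert s.size_counts == {1: 1, 2: 1}
    assert s.size_percent == {1: 50.0, 2: 50.0}
    table = s.allele_table.set_index("allele_id")
    assert table.loc["A", "n_carriers"] == 2
    assert table.loc["B", "n_carriers"] == 1


def test_summary_single_population_all_unique():
    genotypes = [make_genotype("a", {"A"}, pop="p"),
                 make_genotype("b", {"B"}, pop="p")]
    s = genotype_summary(genotypes)
    assert s.population_unique_percent == {"p": 100.0}


def test_summary_matches_brute_force_tally(study_pool):
    genotypes = synth.assign_genotypes(
        study_pool, 120, 2, 0.6, seed=13,
        population_props={"x": 0.5, "y": 0.5},
    )
    s = genotype_summary(genotypes)
    # independent tally
    sizes = collections.Counter(g.n_alleles for g in genotypes)
    assert s.size_counts == dict(sizes)
    for pop in ("x", "y"):
        members = [g for g in genotypes if g.population_id == pop]
        alleles = set().union(*(g.allele_ids for g in members))
        assert s.population_allele_counts[pop] == len(alleles)
        others = set().union(*(g.allele_ids for g in genotypes
                               if g.population_id != pop))
        expect_unique = 100.0 * len(alleles - others) / len(alleles)
        assert s.population_unique_percent[pop] == pytest.approx(
            expect_unique)
    carriers = collections.Counter(
        a for g in genotypes for a in g.allele_ids
    )
    table = s.allele_table.set_index("allele_id")
    for allele, count in carriers.items():
        assert table.loc[allele, "n_carriers"] == count


def test_summary_empty_fails():
    with pytest.raises(ValueError):
        genotype_summary([])
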