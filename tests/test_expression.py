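"""FPKM arithmetic, Fisher/BH against independent oracles, segregation verdicts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from genomecut.expression import call_degs, deg_summary, fpkm, segregation_check
from genomecut.model import CandidateRegion, CountMatrix
from genomecut.simulate import gen_counts, gen_genome


def fisher_two_sided_oracle(ga, ra, gb, rb):
    """Two-sided Fisher p by explicit hypergeometric enumeration: sum the
    probabilities of all tables (same margins) no more likely than observed."""
    N = ga + ra + gb + rb
    K = ga + gb
    n = ga + ra
    hg = stats.hypergeom(N, K, n)
    ks = np.arange(max(0, K - (gb + rb)), min(K, n) + 1)
    pmf = hg.pmf(ks)
    return float(pmf[pmf <= hg.pmf(ga) * (1 + 1e-7)].sum())


def bh_oracle(pvals):
    """Textbook Benjamini-Hochberg step-up with monotonicity enforcement."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        q[i] = running
    return q


def simple_counts(rows, lengths=None, n_rep=1):
    rows = np.asarray(rows)
    genes = [f"g{i}" for i in range(rows.shape[0])]
    lengths = lengths if lengths is not None else [1000] * rows.shape[0]
    samples = [f"A_{i}" for i in range(n_rep)] + [f"B_{i}" for i in range(n_rep)]
    return CountMatrix(genes, lengths, samples, rows)


def test_fpkm_direct_formula():
    counts = simple_counts([[100, 0], [999_900, 1_000_000]])
    df = fpkm(counts)
    # 100 fragments / (1 kb gene x 1e6 library) -> FPKM 100
    assert df.iloc[0, 0] == pytest.approx(100.0)
    assert df.iloc[0, 1] == 0.0


def test_fpkm_normalization_identity():
    rng = np.random.default_rng(0)
    counts = simple_counts(
        rng.integers(0, 5000, size=(300, 2)),
        lengths=rng.integers(100, 5000, size=300).tolist(),
    )
    df = fpkm(counts)
    for s in counts.samples:
        total = (df[s].to_numpy() * counts.gene_lengths_bp / 1e3).sum()
        assert total == pytest.approx(1e6, rel=1e-9)


def test_fpkm_rejects_all_zero_sample():
    with pytest.raises(ValueError, match="zero total"):
        fpkm(simple_counts([[1, 0], [1, 0]]))


def test_fisher_matches_enumeration_oracle_random_tables():
    rng = np.random.default_rng(12)
    for _ in range(200):
        ga, ra, gb, rb = (int(x) for x in rng.integers(0, 250, 4))
        if ga + ra == 0 or gb + rb == 0:
            continue
        p_impl = stats.fisher_exact([[ga, ra], [gb, rb]])[1]
        assert abs(p_impl - fisher_two_sided_oracle(ga, ra, gb, rb)) < 1e-12


@settings(max_examples=100, derandomize=True, deadline=None)
@given(st.tuples(*[st.integers(0, 250)] * 4))
def test_fisher_oracle_property(table):
    ga, ra, gb, rb = table
    if ga + ra == 0 or gb + rb == 0:
        return
    p_impl = stats.fisher_exact([[ga, ra], [gb, rb]])[1]
    assert abs(p_impl - fisher_two_sided_oracle(ga, ra, gb, rb)) < 1e-12


def test_bh_matches_textbook_oracle():
    rng = np.random.default_rng(4)
    from statsmodels.stats.multitest import multipletests

    for _ in range(20):
        p = rng.uniform(0, 1, size=rng.integers(1, 400))
        q_impl = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(q_impl, bh_oracle(p), atol=1e-12)
        assert np.all(q_impl >= p - 1e-15) and np.all(q_impl <= 1.0)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q_impl[order]) >= -1e-15)  # monotone in sorted p


def test_identical_conditions_are_ns_with_p_one():
    counts = simple_counts([[50, 50], [1000, 1000], [3, 3]])
    degs = call_degs(counts, ["A_0"], ["B_0"])
    assert all(d.p_value == pytest.approx(1.0) for d in degs)
    assert all(d.direction == "ns" for d in degs)


def test_fold_change_exactly_two_is_not_called():
    # 1 kb genes, 1e6 totals -> FPKM == counts; a=99, b=199 with eps=1 -> fc 2.0
    rows = [[99, 199], [999_901, 999_801]]
    counts = simple_counts(rows)
    degs = call_degs(counts, ["A_0"], ["B_0"], pseudo_fpkm=1.0)
    d = degs[0]
    assert d.fold_change == pytest.approx(2.0)
    assert d.q_value < 0.05
    assert d.direction == "ns"  # strict "greater than 2"


def test_per_replicate_variant_is_no_less_conservative():
    rng = np.random.default_rng(30)
    rows = rng.poisson(200, size=(40, 6))
    rows[0, 3:] *= 20  # one strongly shifted gene
    counts = CountMatrix(
        [f"g{i}" for i in range(40)],
        [1000] * 40,
        ["A_0", "A_1", "A_2", "B_0", "B_1", "B_2"],
        rows,
    )
    pooled = call_degs(counts, ["A_0", "A_1", "A_2"], ["B_0", "B_1", "B_2"])
    per_rep = call_degs(
        counts, ["A_0", "A_1", "A_2"], ["B_0", "B_1", "B_2"], per_replicate=True
    )
    assert per_rep[0].direction == "up" == pooled[0].direction
    # Bonferroni over pairings keeps every p valid (within [0, 1])
    assert all(0 <= d.p_value <= 1 for d in per_rep)


def test_overlapping_condition_sets_rejected():
    counts = simple_counts([[1, 2], [3, 4]])
    with pytest.raises(ValueError, match="overlap"):
        call_degs(counts, ["A_0"], ["A_0"])


def test_deleted_genes_flagged_and_left_out_of_down_count():
    rows = [[5000, 0], [5000, 0], [995_000, 1_000_000], [100_000, 100_000]]
    counts = simple_counts(rows)
    degs = call_degs(counts, ["A_0"], ["B_0"], deleted_gene_ids={"g0"})
    by_id = {d.gene_id: d for d in degs}
    assert by_id["g0"].excluded_deleted and by_id["g0"].direction == "down"
    assert by_id["g1"].direction == "down" and not by_id["g1"].excluded_deleted
    summary = deg_summary(degs)
    assert summary.n_down == 1  # g0 omitted, g1 counted


def test_summary_mean_fpkm_of_singleton_set():
    counts = simple_counts([[100, 400], [900, 600]])
    degs = call_degs(counts, ["A_0"], ["B_0"])
    s = deg_summary(degs, gene_set=["g0"])
    d = next(x for x in degs if x.gene_id == "g0")
    assert s.mean_fpkm_a == pytest.approx(d.mean_fpkm_a)
    assert s.mean_fpkm_b == pytest.approx(d.mean_fpkm_b)
    assert deg_summary(degs, gene_set=None).mean_fpkm_a is None


def test_all_ns_summary_zeroes():
    counts = simple_counts([[10, 10], [20, 20]])
    degs = call_degs(counts, ["A_0"], ["B_0"])
    s = deg_summary(degs)
    assert (s.n_up, s.n_down, s.n_up_over_32fold) == (0, 0, 0)


@pytest.fixture(scope="module")
def seg_setup():
    genome, truth = gen_genome(n_genes=60, region_size_targets=[11000, 12000], seed=21)
    regions = truth.planted_regions
    deleted = tuple(t for r in regions for t in r.member_locus_tags)
    return genome, regions, deleted


def test_segregation_clean_deletion_verdict(seg_setup):
    genome, regions, deleted = seg_setup
    counts, _ = gen_counts(genome, deleted_tags=deleted, leak_rate=0.0, seed=22)
    rep = segregation_check(
        fpkm(counts), regions, ["WT_1", "WT_2", "WT_3"], ["MUT_1", "MUT_2", "MUT_3"]
    )
    assert all(r.verdict == "segregated" for r in rep.regions)
    assert all(r.flank_ok for r in rep.regions)
    assert all(r.mean_log_fpkm_mut == 0.0 for r in rep.regions)  # log10(0+1)=0


def test_segregation_partial_at_thirty_percent_leak(seg_setup):
    genome, regions, deleted = seg_setup
    counts, _ = gen_counts(genome, deleted_tags=deleted, leak_rate=0.3, seed=23)
    rep = segregation_check(
        fpkm(counts), regions, ["WT_1", "WT_2", "WT_3"], ["MUT_1", "MUT_2", "MUT_3"]
    )
    assert all(r.verdict == "partial" for r in rep.regions)
    assert all(0.05 <= r.residual_fraction <= 0.5 for r in rep.regions)


def test_segregation_failed_at_full_residual(seg_setup):
    genome, regions, deleted = seg_setup
    counts, _ = gen_counts(genome, deleted_tags=deleted, leak_rate=1.0, seed=24)
    rep = segregation_check(
        fpkm(counts), regions, ["WT_1", "WT_2", "WT_3"], ["MUT_1", "MUT_2", "MUT_3"]
    )
    assert all(r.verdict == "failed" for r in rep.regions)


def test_segregation_errors_without_quantified_members(seg_setup):
    genome, regions, deleted = seg_setup
    counts, _ = gen_counts(genome, seed=25)
    ghost = CandidateRegion(1, 100, ("NOT_A_GENE",))
    with pytest.raises(ValueError, match="no quantified"):
        segregation_check(
            fpkm(counts), [ghost], ["WT_1"], ["MUT_1"]
        )
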