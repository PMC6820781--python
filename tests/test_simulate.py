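"""Synthetic-data generators: determinism, truth consistency, calibration."""

import numpy as np
import pandas as pd
import pytest

from famex.combing import cohort_summary, read_measurements
from famex.decompose import decompose_read
from famex.phenostats import pearson_with_ci
from famex.simulate import (ExpansionModel, PhenotypeModel, ReadErrorModel,
                            apply_errors, emit_cohort, emit_combing_table,
                            emit_long_reads, emit_short_reads,
                            simulate_allele_population)


def small_model(**kw):
    defaults = dict(germline=(40, 30, 10), somatic_cv=0.2)
    defaults.update(kw)
    return ExpansionModel(**defaults)


# ---------------------------------------------------------------------------
# model validation and determinism
# ---------------------------------------------------------------------------

def test_model_invariants():
    with pytest.raises(ValueError):
        ExpansionModel(config_mix={"C1": 0.5})  # probabilities don't sum to 1
    with pytest.raises(ValueError):
        ExpansionModel(germline=(-1, 0, 0))
    with pytest.raises(ValueError):
        ReadErrorModel(substitution=0.5)


def test_p_rearrange_bounded():
    m = ExpansionModel()
    for size in (0.0, 4.0, 12.0, 14.0, 100.0):
        assert 0.0 <= m.p_rearrange(size) <= 1.0


def test_same_seed_identical_outputs(locus):
    a = simulate_allele_population(small_model(), 30, seed=5)
    b = simulate_allele_population(small_model(), 30, seed=5)
    pd.testing.assert_frame_equal(a, b)
    ra, ta = emit_long_reads(a, locus, ReadErrorModel(), 10, seed=6)
    rb, tb = emit_long_reads(b, locus, ReadErrorModel(), 10, seed=6)
    assert ra == rb
    pd.testing.assert_frame_equal(ta, tb)
    ca = emit_combing_table(a, seed=7)
    cb = emit_combing_table(b, seed=7)
    pd.testing.assert_frame_equal(ca, cb)


def test_degenerate_jitter_gives_germline(locus):
    cells = simulate_allele_population(
        small_model(somatic_cv=0.0, config_mix={"C2": 1.0}), 20, seed=1)
    exp = cells[cells["allele"] == 2]
    assert (exp["n_5p"] == 40).all()
    assert (exp["n_mid"] == 30).all()
    assert (exp["n_3p"] == 10).all()


# ---------------------------------------------------------------------------
# rearrangement calibration
# ---------------------------------------------------------------------------

def test_rearranged_fraction_near_10pct_at_14kb():
    # germline 14 kb total (2800 units), defaults midpoint 12 / slope 3 /
    # max 0.15: expected rearranged fraction ~ 10% (Monte-Carlo check)
    model = ExpansionModel(germline=(1200, 1400, 200), somatic_cv=0.25)
    cells = simulate_allele_population(model, 3000, seed=9)
    frac = cells[cells["allele"] == 2]["rearranged"].mean()
    assert 0.07 <= frac <= 0.13


def test_rearranged_fraction_low_at_4kb():
    model = ExpansionModel(germline=(400, 300, 100), somatic_cv=0.25)
    cells = simulate_allele_population(model, 3000, seed=10)
    frac = cells[cells["allele"] == 2]["rearranged"].mean()
    assert frac < 0.03


# ---------------------------------------------------------------------------
# long reads
# ---------------------------------------------------------------------------

def test_error_free_reads_decompose_to_truth(locus):
    cells = simulate_allele_population(small_model(), 20, seed=11)
    reads, truth = emit_long_reads(cells, locus, ReadErrorModel(0, 0, 0),
                                   n_reads=10, seed=12)
    for (rid, seq), t in zip(reads, truth.itertuples(index=False)):
        d = decompose_read(rid, seq, locus)
        assert d.coverage == "full"
        assert (d.units_5p, d.units_mid, d.units_3p) == (t.n_5p, t.n_mid, t.n_3p)


def test_strand_flip_identical_decomposition(locus):
    from famex.sequence import reverse_complement
    cells = simulate_allele_population(small_model(somatic_cv=0.0), 1, seed=13)
    reads, _ = emit_long_reads(cells, locus, ReadErrorModel(0, 0, 0), 1, seed=14)
    rid, seq = reads[0]
    d1 = decompose_read(rid, seq, locus)
    d2 = decompose_read(rid, reverse_complement(seq), locus)
    assert d1.structure.structure_string() == d2.structure.structure_string()


def test_truncation_creates_partial_coverage(locus):
    cells = simulate_allele_population(small_model(), 20, seed=15)
    reads, truth = emit_long_reads(cells, locus, ReadErrorModel(0, 0, 0),
                                   n_reads=40, seed=16, p_truncate=0.5)
    partial_ids = set(truth.loc[truth["kind"] == "left_partial", "read_id"])
    assert partial_ids
    for rid, seq in reads:
        d = decompose_read(rid, seq, locus)
        assert (d.coverage == "left_partial") == (rid in partial_ids)


def test_translocated_read_lacks_right_anchor(locus):
    cells = simulate_allele_population(small_model(), 5, seed=17)
    reads, truth = emit_long_reads(cells, locus, ReadErrorModel(0, 0, 0),
                                   n_reads=10, seed=18, p_translocate=1.0)
    assert (truth["kind"] == "translocated").all()
    for rid, seq in reads:
        d = decompose_read(rid, seq, locus)
        assert d.coverage == "left_partial"  # anchor asymmetry detection


def test_apply_errors_rate():
    rng = np.random.default_rng(19)
    seq = "ACGT" * 5000
    out = apply_errors(seq, ReadErrorModel(0.03, 0.03, 0.04), rng)
    # expected length factor: 1 - del + ins = 0.99
    assert abs(len(out) / len(seq) - 0.99) < 0.02
    assert apply_errors(seq, ReadErrorModel(0, 0, 0), rng) == seq


# ---------------------------------------------------------------------------
# short reads
# ---------------------------------------------------------------------------

def test_zero_coverage_empty(locus):
    cells = simulate_allele_population(small_model(), 5, seed=20)
    r1, r2 = emit_short_reads(cells, locus, coverage=0, seed=21)
    assert r1 == [] and r2 == []


def test_short_read_lengths(locus):
    cells = simulate_allele_population(small_model(), 5, seed=22)
    r1, r2 = emit_short_reads(cells, locus, coverage=5, seed=23)
    assert len(r1) == len(r2) > 0
    assert all(len(s) == 150 for _, s in r1 + r2)


# ---------------------------------------------------------------------------
# combing table
# ---------------------------------------------------------------------------

def test_noise_free_combing_recovers_sizes_exactly(tmp_path, locus):
    model = ExpansionModel(germline=(600, 1600, 300), somatic_cv=0.0,
                           config_mix={"C2": 1.0}, rearrange_max=0.0)
    cells = simulate_allele_population(model, 30, seed=24)
    table = emit_combing_table(cells, seed=25, noise_sd_kb=0.0)
    path = tmp_path / "comb.tsv"
    table.to_csv(path, sep="\t", index=False)
    df = cohort_summary(read_measurements(path))
    truth = cells[cells["allele"] == 2]["size_kb"].iloc[0]
    # Yn includes the normal allele's own 12-unit tract (0.06 kb), the only
    # systematic offset at zero noise
    assert df.loc[0, "mean_expansion_kb"] == pytest.approx(truth - 0.06, abs=1e-6)


def test_default_noise_recovery_within_5pct(tmp_path):
    model = ExpansionModel(germline=(600, 1600, 300), somatic_cv=0.25)
    cells = simulate_allele_population(model, 200, seed=26)
    table = emit_combing_table(cells, seed=27)
    path = tmp_path / "comb.tsv"
    table.to_csv(path, sep="\t", index=False)
    df = cohort_summary(read_measurements(path))
    truth_mean = cells[cells["allele"] == 2]["size_kb"].mean()
    assert abs(df.loc[0, "mean_expansion_kb"] - truth_mean) / truth_mean < 0.05


def test_control_model_no_p_calls(tmp_path):
    model = ExpansionModel(germline=(16, 0, 0), normal_units=12, somatic_cv=0.0,
                           config_mix={"C5": 1.0}, rearrange_max=0.0)
    cells = simulate_allele_population(model, 100, seed=28)
    table = emit_combing_table(cells, seed=29)
    path = tmp_path / "comb.tsv"
    table.to_csv(path, sep="\t", index=False)
    df = cohort_summary(read_measurements(path))
    assert df.loc[0, "n_P"] == 0


def test_rearranged_cells_emit_violating_patterns(tmp_path):
    model = ExpansionModel(germline=(1200, 1400, 200), somatic_cv=0.25,
                           rearrange_max=1.0, rearrange_midpoint_kb=-100.0)
    cells = simulate_allele_population(model, 50, seed=30)
    assert cells[cells["allele"] == 2]["rearranged"].all()
    table = emit_combing_table(cells, seed=31)
    path = tmp_path / "comb.tsv"
    table.to_csv(path, sep="\t", index=False)
    df = cohort_summary(read_measurements(path))
    assert df.loc[0, "n_rearranged"] == 50


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def test_cohort_inverse_correlation_default_model():
    negatives = 0
    for seed in range(20):
        cohort = emit_cohort(10, seed=seed)
        res = pearson_with_ci(cohort["age_seizure_onset"],
                              cohort["combing_blood_mid_kb"])
        negatives += res.r < 0
    assert negatives >= 19


def test_cohort_null_model_centered_on_zero():
    rs = []
    for seed in range(30):
        cohort = emit_cohort(10, seed=seed,
                             phenotype_model=PhenotypeModel(slope_years_per_kb=0.0))
        rs.append(pearson_with_ci(cohort["age_seizure_onset"],
                                  cohort["combing_blood_mid_kb"]).r)
    assert abs(np.mean(rs)) < 0.2


def test_cohort_noiseless_limit():
    cohort = emit_cohort(10, seed=3,
                         phenotype_model=PhenotypeModel(sigma_years=0.0))
    res = pearson_with_ci(cohort["age_seizure_onset"],
                          cohort["combing_blood_mid_kb"])
    assert res.r < -0.95
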