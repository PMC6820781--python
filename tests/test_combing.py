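"""Combing allele classification, sizing, configurations, cohort summaries."""

import numpy as np
import pytest

from famex.combing import (AlleleCall, BaselineUnavailableError, CombingAllele,
                           MeasurementError, assign_configuration,
                           call_individual, classify_allele, cohort_summary,
                           expansion_size, flag_rearrangement,
                           read_measurements, write_measurements)


def make_allele(tokens, lengths, individual="i1", fiber="f", complete=True):
    return CombingAllele(individual_id=individual, fiber_id=fiber,
                         tokens=tuple(tokens), lengths_kb=tuple(lengths),
                         complete=complete)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def test_normal_allele():
    assert classify_allele(make_allele("BYG", (10, 3.0, 10))) == "N"


def test_threshold_boundaries():
    # printed inequalities: 5.5 <= Y < 8.5 -> U; Y >= 8.5 -> P
    assert classify_allele(make_allele("BYG", (10, 5.5, 10))) == "U"
    assert classify_allele(make_allele("BYG", (10, 8.5, 10))) == "P_likely"
    assert classify_allele(make_allele("BYG", (10, 8.499, 10))) == "U"
    assert classify_allele(make_allele("BYG", (10, 5.499, 10))) == "N"


def test_red_positive_is_definite():
    assert classify_allele(make_allele("BYRG", (10, 1.0, 2.0, 10))) == "P_definite"


def test_missing_y_on_red_negative_raises():
    with pytest.raises(MeasurementError):
        classify_allele(make_allele("BG", (10, 10)))


def test_classification_is_total_partition():
    rng = np.random.default_rng(0)
    for _ in range(200):
        y = float(rng.uniform(0, 15))
        red = rng.random() < 0.5
        allele = (make_allele("BYRG", (10, y, 2.0, 10)) if red
                  else make_allele("BYG", (10, y, 10)))
        cls = classify_allele(allele)
        assert cls in {"N", "U", "P_likely", "P_definite"}
        if not red:  # monotone in Y
            expected = "N" if y < 5.5 else ("U" if y < 8.5 else "P_likely")
            assert cls == expected


# ---------------------------------------------------------------------------
# sizing
# ---------------------------------------------------------------------------

def test_size_formula():
    assert expansion_size(10.0, 2.0, 3.0, 1.0) == pytest.approx(12.0)
    assert expansion_size(2.0, 2.0, 0.0, 0.0) == pytest.approx(0.0)
    assert expansion_size(2.0, 2.0, 10.4, 1.3) == pytest.approx(11.7)


def test_size_affine_in_yp():
    base = expansion_size(7.0, 2.0, 3.0, 1.0)
    for delta in (0.1, 1.0, -0.5):
        assert expansion_size(7.0 + delta, 2.0, 3.0, 1.0) - base == pytest.approx(delta)


# ---------------------------------------------------------------------------
# rearrangement grammar
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("tokens,expected,reason", [
    ("BYRG", False, None),
    ("BYG", False, None),
    ("BYRWG", False, None),
    ("BMG", True, "overlay"),
    ("BYCG", True, "overlay"),
    (("B", "Y", "R", "R", "B", "G"), True, "duplicated_flank"),
    (("B", "Y", "R"), True, "missing_flank"),
    (("G", "Y", "B"), True, "flank_polarity"),
    (("Y", "R", "G"), True, "missing_flank"),
])
def test_flag_rearrangement(tokens, expected, reason):
    flagged, why = flag_rearrangement(tuple(tokens))
    assert flagged == expected
    assert why == reason


# ---------------------------------------------------------------------------
# configurations
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("tokens,label", [
    ("BYRG", "C1"),
    ("BYRWG", "C2"),
    (("B", "Y", "R", "W", "R", "G"), "C3"),
    (("B", "Y", "R", "W", "R", "W", "G"), "C4"),
    (("B", "Y", "R", "W", "R", "W", "R", "G"), "C6"),
])
def test_configurations(tokens, label):
    assert assign_configuration(tuple(tokens)) == label


def test_c5_requires_expanded_y():
    assert assign_configuration(("B", "Y", "G"), y_kb=9.0) == "C5"
    assert assign_configuration(("B", "Y", "G"), y_kb=3.0) == "NA"


def test_configuration_rejects_rearranged():
    with pytest.raises(ValueError):
        assign_configuration(("B", "M", "G"))


# ---------------------------------------------------------------------------
# per-individual calls and cohort summary
# ---------------------------------------------------------------------------

def _individual(yn=2.0):
    alleles = [make_allele("BYG", (10, yn + d, 10), fiber=f"n{i}")
               for i, d in enumerate((-0.1, 0.0, 0.1))]
    alleles.append(make_allele("BYRG", (10, 3.0, 5.0, 10), fiber="p1"))
    alleles.append(make_allele("BYRWG", (10, 4.0, 6.0, 1.0, 10), fiber="p2"))
    return alleles


def test_call_individual_sizes():
    calls, baseline = call_individual(_individual())
    assert baseline.yn_kb == pytest.approx(2.0)
    assert baseline.n_normal_alleles == 3
    p = [c for c in calls if c.is_pathogenic]
    assert [c.expansion_kb for c in p] == [pytest.approx(3.0 - 2.0 + 5.0),
                                           pytest.approx(4.0 - 2.0 + 6.0 + 1.0)]
    for c in p:
        assert c.part_5p_kb + c.part_mid_kb + c.part_3p_kb == pytest.approx(c.expansion_kb)


def test_no_normal_alleles_raises():
    with pytest.raises(BaselineUnavailableError):
        call_individual([make_allele("BYRG", (10, 3.0, 5.0, 10))])


def test_negative_size_retained_and_flagged():
    alleles = [make_allele("BYG", (10, 3.0, 10), fiber=f"n{i}") for i in range(3)]
    alleles.append(make_allele("BYRG", (10, 2.5, 0.2, 10), fiber="p"))
    calls, _ = call_individual(alleles)
    p = [c for c in calls if c.is_pathogenic][0]
    assert p.expansion_kb == pytest.approx(-0.3)
    assert p.negative_size


def test_rearranged_does_not_shift_baseline():
    alleles = _individual()
    calls_before, base_before = call_individual(alleles)
    alleles.append(make_allele("BMG", (10, 3.0, 10), fiber="r1"))
    calls_after, base_after = call_individual(alleles)
    assert base_before.yn_kb == base_after.yn_kb


def test_cohort_summary_mean():
    alleles = _individual()
    df = cohort_summary({"i1": alleles})
    # oracle: brute-force recomputation of the two pathogenic sizes
    expected = np.mean([3.0 - 2.0 + 5.0, 4.0 - 2.0 + 6.0 + 1.0])
    assert df.loc[0, "mean_expansion_kb"] == pytest.approx(expected)
    assert df.loc[0, "n_P"] == 2


def test_allele_to_cell_conversion():
    # 10% rearranged alleles -> 20% of cells (factor 2, capped)
    alleles = [make_allele("BYG", (10, 2.0, 10), fiber=f"n{i}") for i in range(18)]
    alleles += [make_allele("BMG", (10, 2.0, 10), fiber=f"r{i}") for i in range(2)]
    df = cohort_summary({"i1": alleles})
    assert df.loc[0, "percent_rearranged_alleles"] == pytest.approx(10.0)
    assert df.loc[0, "percent_rearranged_cells"] == pytest.approx(20.0)


def test_cell_percentage_capped_at_100():
    alleles = [make_allele("BYG", (10, 2.0, 10), fiber="n0")]
    alleles += [make_allele("BMG", (10, 2.0, 10), fiber=f"r{i}") for i in range(3)]
    df = cohort_summary({"i1": alleles})
    assert df.loc[0, "percent_rearranged_cells"] == 100.0


def test_incomplete_alleles_excluded_from_stats():
    alleles = _individual()
    alleles.append(make_allele(("B", "Y", "R", "END_TRUNCATED"),
                               (10, 3.0, 50.0, 0.0), fiber="t", complete=False))
    df = cohort_summary({"i1": alleles})
    assert df.loc[0, "n_incomplete"] == 1
    expected = np.mean([6.0, 9.0])
    assert df.loc[0, "mean_expansion_kb"] == pytest.approx(expected)


def test_control_individual_no_pathogenic_calls():
    rng = np.random.default_rng(42)
    ys = np.clip(rng.normal(2.5, 0.5, size=200), 0.01, None)
    alleles = [make_allele("BYG", (10, float(y), 10), fiber=f"f{i}")
               for i, y in enumerate(ys)]
    df = cohort_summary({"ctrl": alleles})
    assert df.loc[0, "n_P"] == 0
    assert df.loc[0, "n_U"] <= 2  # <=1% of 200
    assert df.loc[0, "n_N"] >= 198


def test_measurement_tsv_round_trip(tmp_path):
    alleles = _individual() + [make_allele(
        ("B", "Y", "END_TRUNCATED"), (10, 3.0, 0.0), fiber="t", complete=False)]
    path = tmp_path / "comb.tsv"
    write_measurements(alleles, path)
    back = read_measurements(path)
    assert list(back) == ["i1"]
    assert len(back["i1"]) == len(alleles)
    for orig, loaded in zip(alleles, back["i1"]):
        assert loaded.tokens == orig.tokens
        assert loaded.complete == orig.complete
        assert loaded.lengths_kb == pytest.approx(orig.lengths_kb, abs=1e-3)


def test_allele_invariants_enforced():
    with pytest.raises(MeasurementError):
        make_allele("BYG", (10, 3.0))  # length mismatch
    with pytest.raises(MeasurementError):
        make_allele("BXG", (10, 3.0, 10))  # unknown token
    with pytest.raises(MeasurementError):
        make_allele("BYG", (10, -1.0, 10))  # negative length
    with pytest.raises(MeasurementError):
        make_allele("BYG", (10, 3.0, 10), complete=False)  # flag inconsistent
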