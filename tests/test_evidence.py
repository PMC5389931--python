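"""Evidence-confidence scoring: anchor lookups, interpolation, combination,
Z-adjustment, and the dataset driver."""

import math
import random

import pytest
from hypothesis import given, settings, strategies as st

from nudixclan.evidence import (
    EvidenceRecord,
    ScoreTable,
    adjust_final,
    combine_overall,
    pseudo_kcat_km,
    read_evidence_tsv,
    score_category,
    score_dataset,
    score_kinetic,
    score_pseudo_kinetic,
    score_relative_activity,
    write_scores_tsv,
)

SETTINGS = settings(deadline=None, derandomize=True, max_examples=200)


@pytest.mark.parametrize("value,expected", [
    (1e3, 0.1), (1e4, 0.2), (1e5, 0.5), (1e6, 0.85), (1e7, 0.99),
    (0.0, 0.01),
    (5e6, (math.log10(5e6) - 6) * (0.99 - 0.85) + 0.85),  # worked example
    (1e8, 0.99),   # clamp above top anchor
    (500.0, 0.1),  # nonzero below bottom anchor clamps to bottom score
])
def test_kinetic_anchor_and_interpolation(value, expected):
    assert score_kinetic(value) == pytest.approx(expected, abs=1e-12)


def test_worked_kinetic_example_three_decimals():
    """A kcat/Km of 5e6 interpolates to 0.948 on the anchored log scale."""
    assert round(score_kinetic(5e6), 3) == 0.948


@pytest.mark.parametrize("value,expected", [
    (1e3, 0.05), (1e7, 0.7), (0.0, 0.01),
    (5e6, (math.log10(5e6) - 6) * (0.7 - 0.5) + 0.5),
])
def test_pseudo_kinetic_scoring(value, expected):
    assert score_pseudo_kinetic(value) == pytest.approx(expected, abs=1e-12)


def test_negative_kinetic_value_is_an_error():
    with pytest.raises(ValueError):
        score_kinetic(-1.0)


@pytest.mark.parametrize("rel_a,rel_b,kk_b,expected", [
    (100, 100, 1e6, 1e6),
    (0, 100, 1e6, 0.0),
    (50, 100, 1e6, 2.5e5),
])
def test_pseudo_kcat_km_formula(rel_a, rel_b, kk_b, expected):
    assert pseudo_kcat_km(rel_a, rel_b, kk_b) == pytest.approx(expected)


def test_pseudo_kcat_km_zero_reference_is_an_error():
    with pytest.raises(ValueError):
        pseudo_kcat_km(50, 0, 1e6)


@pytest.mark.parametrize("rel,expected", [(100, 0.1), (0, 0.0), (50, 0.05)])
def test_relative_activity_linear(rel, expected):
    assert score_relative_activity(rel) == pytest.approx(expected)


def test_relative_activity_above_100_clamps():
    assert score_relative_activity(130) == pytest.approx(0.1)
    rec = EvidenceRecord("P1", "F1", "biochemical", "relative_activity", 130.0)
    assert rec.value == 100.0


@SETTINGS
@given(st.tuples(st.floats(0, 1e9), st.floats(0, 1e9)))
def test_kinetic_scores_non_decreasing(pair):
    a, b = sorted(pair)
    assert score_kinetic(a) <= score_kinetic(b) + 1e-12
    assert score_pseudo_kinetic(a) <= score_pseudo_kinetic(b) + 1e-12


def _rec(subtype, value=None, category=None, protein="P1", function="F1"):
    from nudixclan.evidence import GENETIC_SUBTYPES
    if category is None:
        category = "genetic" if subtype in GENETIC_SUBTYPES else "biochemical"
    return EvidenceRecord(protein, function, category, subtype, value)


@pytest.mark.parametrize("records,expected", [
    ([_rec("knockout_predicted")], 0.99),
    ([_rec("kcat_km", 1e3), _rec("kcat_km", 1e7)], 0.99),
    ([_rec("gel_hplc_common")], 0.05),
    ([_rec("gel_rare_substrate"), _rec("xray_substrate")], 0.5),
])
def test_category_score_is_max_over_records(records, expected):
    assert score_category(records) == pytest.approx(expected)


def test_mixed_categories_rejected():
    with pytest.raises(ValueError):
        score_category([_rec("knockout_predicted"), _rec("kcat_km", 1e5)])


@SETTINGS
@given(st.floats(0, 1), st.floats(0, 1))
def test_combine_overall_noisy_or(a, b):
    s = combine_overall(a, b)
    assert s == pytest.approx(1 - (1 - a) * (1 - b))
    assert s >= max(a, b) - 1e-12
    assert combine_overall(a, 0.0) == pytest.approx(a)


def test_adjust_final_frozen_oracle():
    """[0.9, 0.1, 0.1, 0.1] with population SD: outlier boosted to
    1 - 0.1/(1 + 0.6/sqrt(0.12)), low scores damped to 0.1/(1 + 0.2/sqrt(0.12))."""
    sd = math.sqrt(0.12)
    z, f = adjust_final([0.9, 0.1, 0.1, 0.1])
    assert z[0] == pytest.approx(0.6 / sd)
    assert f[0] == pytest.approx(1 - 0.1 / (1 + 0.6 / sd))
    assert f[1:] == pytest.approx([0.1 / (1 + 0.2 / sd)] * 3)
    assert f[0] > 0.9 and all(x < 0.1 for x in f[1:])


@pytest.mark.parametrize("scores", [[0.5, 0.5, 0.5], [0.8]])
def test_adjust_final_passthrough_when_sd_zero(scores):
    z, f = adjust_final(scores)
    assert all(x == 0.0 for x in z)
    assert f == scores


@SETTINGS
@given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
def test_adjust_final_rank_and_direction(scores):
    z, f = adjust_final(scores)
    assert all(0 <= x <= 1 for x in f)
    for zi, si, fi in zip(z, scores, f):
        if zi > 0:
            assert fi >= si - 1e-12
        elif zi < 0:
            assert fi <= si + 1e-12
        else:
            assert fi == pytest.approx(si)
    order = sorted(range(len(scores)), key=lambda i: scores[i])
    ranked = [f[i] for i in order]
    assert all(b >= a - 1e-12 for a, b in zip(ranked, ranked[1:]))


def test_score_dataset_single_genetic_record():
    out = score_dataset([_rec("knockout_predicted")])
    assert len(out) == 1
    ann = out[0]
    assert ann.s_genetic == 0.99 and ann.s_biochem == 0.0
    assert ann.s_overall == pytest.approx(0.99)
    assert ann.z_score == 0.0 and ann.s_final == pytest.approx(0.99)


def test_score_dataset_empty():
    assert score_dataset([]) == []


def test_score_dataset_combines_categories_and_orders_output():
    records = [
        _rec("kcat_km", 1e5, function="F2", protein="P2"),
        _rec("knockout_related", function="F1", protein="P2"),
        _rec("kcat_km", 1e6, function="F1", protein="P2"),
    ]
    out = score_dataset(records)
    assert [(a.protein_id, a.function_id) for a in out] == [("P2", "F1"), ("P2", "F2")]
    assert out[0].s_overall == pytest.approx(combine_overall(0.7, 0.85))
    assert out[0].n_records == 2


def test_score_dataset_permutation_invariant():
    rng = random.Random(7)
    records = []
    for p in range(5):
        for f in range(4):
            for _ in range(rng.randint(1, 3)):
                records.append(_rec("kcat_km", 10 ** rng.uniform(3, 7),
                                    protein=f"P{p}", function=f"F{f}"))
    base = score_dataset(records)
    for _ in range(5):
        shuffled = records[:]
        rng.shuffle(shuffled)
        assert score_dataset(shuffled) == base


def test_all_emitted_scores_in_unit_interval():
    rng = random.Random(11)
    records = [_rec("kcat_km", 10 ** rng.uniform(0, 9),
                    protein=f"P{rng.randint(0, 3)}", function=f"F{i}")
               for i in range(30)]
    for ann in score_dataset(records):
        for s in (ann.s_genetic, ann.s_biochem, ann.s_overall, ann.s_final):
            assert 0 <= s <= 1


def test_record_invariants():
    with pytest.raises(ValueError):
        EvidenceRecord("P", "F", "biochemical", "kcat_km", None)  # value required
    with pytest.raises(ValueError):
        EvidenceRecord("P", "F", "genetic", "knockout_predicted", 5.0)
    with pytest.raises(ValueError):
        EvidenceRecord("P", "F", "genetic", "kcat_km", 1e5)  # wrong category


def test_tsv_round_trip_and_bad_row_skipping(tmp_path, caplog):
    path = tmp_path / "evidence.tsv"
    path.write_text(
        "protein_id\tfunction_id\tcategory\tsubtype\tvalue\tsource_ref\n"
        "P1\tF1\tbiochemical\tkcat_km\t5e6\tdoi:x\n"
        "P1\tF2\tgenetic\tknockout_predicted\t\t\n"
        "P1\tF3\tbiochemical\tnot_a_subtype\t\t\n"  # malformed: skipped
    )
    records = read_evidence_tsv(str(path))
    assert len(records) == 2
    out = tmp_path / "scores.tsv"
    annotations = score_dataset(records)
    write_scores_tsv(annotations, str(out))
    lines = out.read_text().splitlines()
    assert lines[0].split("\t")[:2] == ["protein_id", "function_id"]
    assert len(lines) == 3


def test_score_table_yaml_override(tmp_path):
    cfg = tmp_path / "table.yaml"
    cfg.write_text("genetic_scores:\n  knockout_predicted: 0.99\n"
                   "  knockout_related: 0.7\n  knockout_inexplicable: 0.1\n"
                   "  rescue: 0.7\nrelative_activity_max_score: 0.2\n")
    table = ScoreTable.from_yaml(str(cfg))
    assert table.genetic_scores["rescue"] == 0.7
    assert score_relative_activity(50, table) == pytest.approx(0.1)


def test_score_table_rejects_non_monotone_anchors():
    with pytest.raises(ValueError):
        ScoreTable(kinetic_anchors={3: 0.5, 4: 0.4})
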