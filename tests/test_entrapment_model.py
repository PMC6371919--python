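"""Ring-stoichiometry closed forms vs enumeration, lane stats, classification."""

import itertools
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cohesim import (
    CohesinCopy,
    StoichiometryModel,
    circularization_fraction,
    classify_stoichiometry,
    expected_species_fractions,
    five_c,
    quantify_lane,
    ratio_of_ratios,
    replicate_stats,
    six_c,
    standard_tetraploid_designs,
)
from cohesim.entrapment_model import INTERFACES


def enumerate_species_fractions(model):
    """Oracle: exhaustive enumeration over tagged-copy choice, all ordered
    partner draws, and every per-molecule interface-crosslink outcome."""
    e = model.efficiencies
    n = len(model.copies)
    tagged_idx = [i for i, c in enumerate(model.copies) if c.tagged]

    def full_circ_prob(copy):
        # P(all three interfaces crosslinked), via enumeration of outcomes
        total = 0.0
        for outcome in itertools.product([0, 1], repeat=len(INTERFACES)):
            p = 1.0
            closed = True
            for iface, crosslinked in zip(INTERFACES, outcome):
                if iface in copy.circularizable:
                    p *= e[iface] if crosslinked else 1 - e[iface]
                    closed &= bool(crosslinked)
                else:
                    if crosslinked:
                        p = 0.0
                    closed = False
            if closed:
                total += p
        return total

    cm = sum(full_circ_prob(model.copies[i]) for i in tagged_idx) / len(tagged_idx)
    cd = 0.0
    for t in tagged_idx:
        for partners in itertools.product(range(n), repeat=model.k - 1):
            p_draw = (1 / n) ** (model.k - 1)
            p_all = full_circ_prob(model.copies[t])
            for j in partners:
                p_all *= full_circ_prob(model.copies[j])
            cd += p_draw * p_all / len(tagged_idx)
    return {
        "CM_detectable": model.p_cm * cm,
        "CD_detectable": model.p_cd * cd,
    }


def model_of(copies, k=1, e=0.6, p_cm=1.0, p_cd=1.0):
    eff = {i: e for i in INTERFACES} if not isinstance(e, dict) else e
    return StoichiometryModel(eff, copies, k=k, p_cm=p_cm, p_cd=p_cd)


class TestCircularizationFraction:
    def test_certain_crosslinking(self):
        model = model_of([six_c(tagged=True)], e=1.0)
        assert circularization_fraction(model, 0) == 1.0

    def test_product_of_independent_interfaces(self):
        model = model_of([six_c(tagged=True)], e=0.6)
        assert circularization_fraction(model, 0) == pytest.approx(0.216)

    def test_five_c_copy_never_circularizes(self):
        model = model_of([six_c(tagged=True), five_c()], e=0.99)
        assert circularization_fraction(model, 1) == 0.0

    def test_index_out_of_range(self):
        model = model_of([six_c(tagged=True)])
        with pytest.raises(IndexError):
            circularization_fraction(model, 5)


class TestExpectedSpeciesFractions:
    def test_perfect_crosslinking_detects_everything(self):
        for k in (1, 2, 3):
            model = model_of([six_c(tagged=True)] * 4, k=k, e=1.0)
            fr = expected_species_fractions(model)
            assert fr == {"CM_detectable": 1.0, "CD_detectable": 1.0}

    def test_handcuff_quarter_between_tetraploid_designs(self):
        control, test = standard_tetraploid_designs(k=2, e=0.6)
        cd_control = expected_species_fractions(control)["CD_detectable"]
        cd_test = expected_species_fractions(test)["CD_detectable"]
        assert cd_test / cd_control == pytest.approx(0.25)

    def test_three_ring_unit_gives_one_sixteenth(self):
        control, test = standard_tetraploid_designs(k=3, e=0.6)
        cd_control = expected_species_fractions(control)["CD_detectable"]
        cd_test = expected_species_fractions(test)["CD_detectable"]
        assert cd_test / cd_control == pytest.approx(1 / 16)
        # and the closed form agrees with exhaustive enumeration
        assert expected_species_fractions(test)["CD_detectable"] == pytest.approx(
            enumerate_species_fractions(test)["CD_detectable"]
        )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        k=st.integers(1, 3),
        n_5c=st.integers(0, 3),
        e=st.tuples(*[st.floats(0.05, 1.0) for _ in range(3)]),
        p_cm=st.floats(0.1, 1.0),
        p_cd=st.floats(0.1, 1.0),
    )
    def test_closed_form_equals_enumeration(self, k, n_5c, e, p_cm, p_cd):
        eff = dict(zip(INTERFACES, e))
        copies = [six_c(tagged=True)] + [five_c()] * n_5c + [six_c()] * (3 - n_5c)
        model = model_of(copies, k=k, e=eff, p_cm=p_cm, p_cd=p_cd)
        closed = expected_species_fractions(model)
        enum = enumerate_species_fractions(model)
        assert closed["CM_detectable"] == pytest.approx(enum["CM_detectable"])
        assert closed["CD_detectable"] == pytest.approx(enum["CD_detectable"])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        e=st.floats(0.05, 0.95),
        bump=st.floats(0.01, 0.05),
        k=st.integers(1, 3),
    )
    def test_monotone_in_interface_efficiency(self, e, bump, k):
        copies = [six_c(tagged=True), six_c(), five_c(), five_c()]
        lo = expected_species_fractions(model_of(copies, k=k, e=e))
        hi = expected_species_fractions(model_of(copies, k=k, e=min(1.0, e + bump)))
        assert hi["CM_detectable"] >= lo["CM_detectable"]
        assert hi["CD_detectable"] >= lo["CD_detectable"]


class TestRatioOfRatios:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        e=st.tuples(*[st.floats(0.05, 1.0) for _ in range(3)]),
        n_5c_a=st.integers(0, 3),
        n_5c_b=st.integers(0, 3),
    )
    def test_single_ring_model_is_neutral(self, e, n_5c_a, n_5c_b):
        # k=1 prediction: diluting circularizable cohesin never changes CD/CM
        eff = dict(zip(INTERFACES, e))

        def design(n_5c):
            copies = [six_c(tagged=True)] + [five_c()] * n_5c + [six_c()] * (3 - n_5c)
            return model_of(copies, k=1, e=eff, p_cm=0.5, p_cd=0.5)

        assert ratio_of_ratios(design(n_5c_a), design(n_5c_b)) == pytest.approx(1.0)

    def test_handcuff_prediction_is_four(self):
        control, test = standard_tetraploid_designs(k=2, e=0.6)
        assert ratio_of_ratios(control, test) == pytest.approx(4.0)

    def test_identical_designs_give_unity(self):
        control, _ = standard_tetraploid_designs(k=3, e=0.4)
        assert ratio_of_ratios(control, control) == 1.0

    def test_zero_cm_raises(self):
        control, _ = standard_tetraploid_designs(k=1, e=0.5)
        dead = model_of([six_c(tagged=True)], e={i: 0.0 for i in INTERFACES})
        with pytest.raises(ValueError, match="ratio undefined"):
            ratio_of_ratios(control, dead)


class TestLaneQuantification:
    def test_percent_of_lane_total(self):
        lane = quantify_lane({"CM": 30.0, "CD": 70.0})
        assert lane.percent == {"CM": 30.0, "CD": 70.0}

    def test_three_band_hand_arithmetic(self):
        lane = quantify_lane({"monomer": 50.0, "CM": 25.0, "CD": 25.0})
        assert lane.percent == {"monomer": 50.0, "CM": 25.0, "CD": 25.0}

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 100.0), min_size=1, max_size=6))
    def test_percents_sum_to_hundred(self, intensities):
        lane = quantify_lane({f"b{i}": v for i, v in enumerate(intensities)})
        assert math.fsum(lane.percent.values()) == pytest.approx(100.0, abs=1e-9)

    def test_empty_lane_error(self):
        with pytest.raises(ValueError, match="empty lane"):
            quantify_lane({"CM": 0.0, "CD": 0.0})


class TestReplicateStats:
    def test_identical_lanes_have_zero_sd(self):
        lanes = [quantify_lane({"CM": 30.0, "CD": 10.0}) for _ in range(3)]
        summary = replicate_stats(lanes)
        assert summary.sd == {"CM": 0.0, "CD": 0.0}

    def test_hand_computed_sample_sd(self):
        lanes = [quantify_lane({"a": p, "b": 100.0 - p}) for p in (10.0, 20.0, 30.0)]
        summary = replicate_stats(lanes)
        assert summary.mean["a"] == pytest.approx(20.0)
        assert summary.sd["a"] == pytest.approx(10.0)

    def test_single_lane_sd_is_null(self):
        summary = replicate_stats([quantify_lane({"a": 1.0, "b": 2.0})])
        assert summary.n == 1
        assert summary.sd == {"a": None, "b": None}

    def test_mismatched_band_labels(self):
        lanes = [quantify_lane({"a": 1.0, "b": 1.0}), quantify_lane({"a": 1.0, "c": 1.0})]
        with pytest.raises(ValueError, match="b.*c|c.*b"):
            replicate_stats(lanes)


class TestClassification:
    def test_measured_near_unity_ratio_supports_single_ring(self):
        result = classify_stoichiometry(1.01, 0.100, [1, 2])
        assert result.best_k == 1 and not result.tie

    def test_fourfold_ratio_supports_handcuff(self):
        result = classify_stoichiometry(4.0, 0.1, [1, 2])
        assert result.best_k == 2

    def test_equidistant_observation_reports_tie_broken_by_parsimony(self):
        result = classify_stoichiometry(2.5, 1.0, [1, 2])
        assert result.tie
        assert result.best_k == 1
        assert result.z_per_k[1] == pytest.approx(1.5)
        assert result.z_per_k[2] == pytest.approx(1.5)

    def test_argument_errors(self):
        with pytest.raises(ValueError):
            classify_stoichiometry(1.0, 0.1, [])
        with pytest.raises(ValueError):
            classify_stoichiometry(1.0, 0.0, [1, 2])


def test_model_validation_errors():
    eff = {i: 0.5 for i in INTERFACES}
    with pytest.raises(ValueError, match="tagged"):
        StoichiometryModel(eff, [six_c()], k=1)
    with pytest.raises(ValueError, match="empty"):
        StoichiometryModel(eff, [], k=1)
    with pytest.raises(ValueError, match="k"):
        StoichiometryModel(eff, [six_c(tagged=True)], k=0)
    with pytest.raises(ValueError):
        StoichiometryModel({**eff, "hinge": 1.5}, [six_c(tagged=True)], k=1)
    with pytest.raises(ValueError):
        CohesinCopy(frozenset({"not_an_interface"}))
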