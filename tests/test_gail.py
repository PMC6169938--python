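import math

import numpy as np
import pytest

from riskcombine.gail import (
    HazardTable,
    RelativeRiskModel,
    absolute_risk,
    categorize,
    dump_risk_config,
    load_risk_config,
    relative_risk,
    score_cohort,
)
from riskcombine.io import NULLIPAROUS, SubjectRecord
from riskcombine.synthetic import default_relative_risk_model


def quadrature_oracle(age, horizon, rr, hazards, dt=1e-4):
    """Brute-force fine-grid integration of the competing-risk projection."""
    t = np.arange(age, age + horizon, dt)
    h1 = np.zeros_like(t)
    h2 = np.zeros_like(t)
    for (a, b), i1, i2 in zip(hazards.age_bands, hazards.incidence, hazards.competing_mortality):
        mask = (t >= a) & (t < b)
        h1[mask] = i1 * rr
        h2[mask] = i2
    total = h1 + h2
    # midpoint rule: cumulative hazard evaluated at the centre of each step
    cum_mid = np.cumsum(total * dt) - total * dt / 2
    return float(np.sum(h1 * np.exp(-cum_mid) * dt))


def make_hazards(bands, h1, h2):
    return HazardTable(age_bands=tuple(bands), incidence=tuple(h1), competing_mortality=tuple(h2))


class TestHazardTable:
    def test_gap_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            make_hazards([(35, 50), (55, 90)], [0.01, 0.01], [0.0, 0.0])

    def test_coverage_rejected(self):
        with pytest.raises(ValueError, match="cover"):
            make_hazards([(40, 90)], [0.01], [0.0])

    def test_negative_hazard_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            make_hazards([(35, 90)], [-0.01], [0.0])


class TestRelativeRisk:
    def test_reference_record_is_one(self, subject_reference):
        assert relative_risk(subject_reference, default_relative_risk_model()) == pytest.approx(1.0)

    def test_all_unknown_is_one(self):
        record = SubjectRecord(subject_id="u", status="case", age=60)
        assert relative_risk(record, default_relative_risk_model()) == pytest.approx(1.0)

    def test_hand_sum(self):
        model = RelativeRiskModel(
            coefficients={
                "n_first_degree_relatives": {"0": 0.0, "1": 0.30},
                "age_menarche": {">=14": 0.0, "12-13": 0.20},
                "age_first_birth": {"<20": 0.0},
                "n_biopsies": {"0": 0.0},
                "hyperplasia": {"no": 0.0},
            }
        )
        record = SubjectRecord(
            subject_id="x", status="case", age=45,
            n_first_degree_relatives="1", age_menarche=12,
            age_first_birth=18, n_biopsies=0, hyperplasia="no",
        )
        assert relative_risk(record, model) == pytest.approx(math.exp(0.5))

    def test_missing_category_named_in_error(self):
        model = RelativeRiskModel(coefficients={"n_first_degree_relatives": {"0": 0.0}})
        record = SubjectRecord(subject_id="x", status="case", age=45, n_first_degree_relatives="2+")
        with pytest.raises(KeyError, match="2\\+"):
            relative_risk(record, model)

    def test_age_split_coefficient(self):
        model = RelativeRiskModel(
            coefficients={"n_biopsies": {"1": {"lt50": 0.5, "ge50": 0.2}}}
        )
        young = SubjectRecord(subject_id="y", status="case", age=45, n_biopsies=1)
        old = SubjectRecord(subject_id="o", status="case", age=60, n_biopsies=1)
        assert relative_risk(young, model) == pytest.approx(math.exp(0.5))
        assert relative_risk(old, model) == pytest.approx(math.exp(0.2))

    def test_categorize_bins(self):
        record = SubjectRecord(
            subject_id="x", status="case", age=45,
            n_first_degree_relatives="1", age_menarche=11,
            age_first_birth=NULLIPAROUS, n_biopsies=2, hyperplasia="yes",
        )
        cats = categorize(record)
        assert cats == {
            "n_first_degree_relatives": "1",
            "age_menarche": "<12",
            "age_first_birth": NULLIPAROUS,
            "n_biopsies": ">=2",
            "hyperplasia": "yes",
        }


class TestAbsoluteRisk:
    def test_zero_incidence_gives_zero(self):
        hz = make_hazards([(35, 90)], [0.0], [0.02])
        assert absolute_risk(40, 20, 5.0, hz) == 0.0

    def test_closed_form_no_competing_risk(self):
        hz = make_hazards([(35, 90)], [0.01], [0.0])
        assert absolute_risk(50, 5, 1.0, hz) == pytest.approx(1 - math.exp(-0.05), abs=1e-12)

    def test_two_band_matches_quadrature(self):
        hz = make_hazards([(35, 52), (52, 90)], [0.004, 0.009], [0.002, 0.015])
        value = absolute_risk(48, 10, 1.3, hz)
        assert value == pytest.approx(quadrature_oracle(48, 10, 1.3, hz), abs=1e-6)

    def test_under_35_refused(self, flat_hazards):
        with pytest.raises(ValueError, match="35"):
            absolute_risk(34, 5, 1.0, flat_hazards)

    @pytest.mark.parametrize("age,horizon", [(50, 0), (50, -3), (88, 5)])
    def test_bad_horizon_refused(self, flat_hazards, age, horizon):
        with pytest.raises(ValueError):
            absolute_risk(age, horizon, 1.0, flat_hazards)

    def test_monotone_in_rr_and_horizon(self, flat_hazards):
        risks_rr = [absolute_risk(45, 20, rr, flat_hazards) for rr in (0.5, 1.0, 2.0, 4.0)]
        assert risks_rr == sorted(risks_rr)
        risks_h = [absolute_risk(45, h, 1.5, flat_hazards) for h in (5, 15, 30, 45)]
        assert risks_h == sorted(risks_h)

    def test_decreasing_in_competing_mortality(self):
        low = make_hazards([(35, 90)], [0.005], [0.001])
        high = make_hazards([(35, 90)], [0.005], [0.05])
        assert absolute_risk(40, 30, 1.0, high) < absolute_risk(40, 30, 1.0, low)

    def test_upper_bound_ignoring_competing_risk(self, flat_hazards):
        rr = 2.5
        value = absolute_risk(40, 30, rr, flat_hazards)
        bound = 1 - math.exp(-rr * sum(h * 5 for h in flat_hazards.incidence[1:7]))
        assert 0.0 <= value <= bound <= 1.0

    def test_random_configs_match_quadrature(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            edges = sorted(rng.choice(np.arange(36, 90), size=3, replace=False).tolist())
            bands = list(zip([35] + edges, edges + [90]))
            h1 = rng.uniform(1e-4, 0.02, len(bands))
            h2 = rng.uniform(0, 0.05, len(bands))
            hz = make_hazards(bands, h1, h2)
            age = int(rng.integers(35, 85))
            horizon = int(rng.integers(1, 90 - age + 1))
            rr = float(rng.uniform(0.3, 4.0))
            assert absolute_risk(age, horizon, rr, hz) == pytest.approx(
                quadrature_oracle(age, horizon, rr, hz), abs=1e-6
            )


class TestScoreCohort:
    def test_age_89_truncates_five_year_horizon(self, flat_hazards):
        subject = SubjectRecord(subject_id="e", status="control", age=89)
        pair = score_cohort([subject], default_relative_risk_model(), flat_hazards)[0]
        assert pair.five_year == pytest.approx(pair.lifetime)

    def test_zero_hazards_zero_risks(self):
        hz = make_hazards([(35, 90)], [0.0], [0.0])
        subject = SubjectRecord(subject_id="z", status="control", age=50)
        pair = score_cohort([subject], default_relative_risk_model(), hz)[0]
        assert pair.five_year == 0.0 and pair.lifetime == 0.0

    def test_five_year_never_exceeds_lifetime(self, default_cohort):
        cohort, _, model, hazards = default_cohort
        for pair in score_cohort(cohort.subjects[:50], model, hazards):
            assert 0.0 <= pair.five_year <= pair.lifetime <= 1.0

    def test_cohort_agrees_with_quadrature(self, default_cohort):
        cohort, _, model, hazards = default_cohort
        pairs = score_cohort(cohort.subjects[:10], model, hazards)
        for subject, pair in zip(cohort.subjects[:10], pairs):
            rr = relative_risk(subject, model)
            assert pair.lifetime == pytest.approx(
                quadrature_oracle(subject.age, 90 - subject.age, rr, hazards), abs=1e-6
            )


class TestConfigRoundTrip:
    def test_yaml_round_trip(self, tmp_path, flat_hazards):
        model = default_relative_risk_model()
        path = tmp_path / "hazards.yaml"
        dump_risk_config(model, flat_hazards, path)
        model2, hazards2 = load_risk_config(path)
        assert hazards2 == flat_hazards
        record = SubjectRecord(
            subject_id="x", status="case", age=45,
            n_first_degree_relatives="2+", age_menarche=11,
            age_first_birth=27, n_biopsies=1, hyperplasia="yes",
        )
        assert relative_risk(record, model2) == pytest.approx(relative_risk(record, model))
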