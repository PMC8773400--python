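"""Generator contracts: determinism, rates, path-loss calibration, recall model."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from cardtrace.card_pipeline import build_two_minute_records
from cardtrace.synthetic_data import (
    ConfigurationError,
    DataError,
    GeneratorConfig,
    WearSchedule,
    generate_population,
    generate_true_contacts,
    generate_wear_schedule,
    simulate_case_reports,
    simulate_rssi_stream,
)


def all_wearing(population, n_days):
    days = list(range(1, n_days + 1))
    wear = pd.DataFrame(
        True,
        index=pd.Index(population["participant_id"], name="participant_id"),
        columns=days,
    )
    coloc = pd.DataFrame(
        False,
        index=pd.Index(population["household_id"].unique(), name="household_id"),
        columns=days,
    )
    return WearSchedule(wear=wear, household_colocated=coloc)


def one_event(a="P1", b="P2", day=1, distance=1.0, duration=2,
              start="2020-11-09 10:00:00"):
    return pd.DataFrame(
        {
            "person_a": [a],
            "person_b": [b],
            "day": [day],
            "start_time": [pd.Timestamp(start)],
            "duration_min": [duration],
            "distance_m": [distance],
        }
    )


class TestConfigValidation:
    def test_bad_distribution_rejected(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(household_size_distribution={1: 0.5, 2: 0.4})

    def test_wear_vector_length_checked(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(n_days=3, wear_prob_by_day=[0.5, 0.5])

    def test_duration_support_checked(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(duration_distribution={1: 1.0})

    def test_distance_support_checked(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(distance_distribution={5.0: 1.0})

    def test_yaml_round_trip(self, tmp_path):
        cfg = GeneratorConfig(n_participants=50, seed=9)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert GeneratorConfig.from_yaml(path) == cfg


class TestPopulation:
    def test_trial_scale_cohort(self):
        pop = generate_population(GeneratorConfig(n_participants=1191))
        assert len(pop) == 1191
        assert pop["household_id"].notna().all()
        assert pop["participant_id"].is_unique

    def test_degenerate_singleton_households(self):
        pop = generate_population(
            GeneratorConfig(n_participants=2, household_size_distribution={1: 1.0})
        )
        assert pop["household_id"].nunique() == 2

    def test_seeded_determinism(self):
        cfg = GeneratorConfig(n_participants=100, seed=7)
        pd.testing.assert_frame_equal(
            generate_population(cfg), generate_population(cfg)
        )

    def test_household_sizes_follow_distribution(self):
        cfg = GeneratorConfig(
            n_participants=3000,
            household_size_distribution={1: 0.5, 3: 0.5},
            seed=2,
        )
        sizes = generate_population(cfg).groupby("household_id").size()
        # truncation affects at most the final household
        assert set(sizes.unique()) <= {1, 2, 3}
        frac1 = (sizes == 1).mean()
        assert abs(frac1 - 0.5) < 3 * np.sqrt(0.25 / len(sizes))


class TestTrueContacts:
    def test_zero_rate_no_households_is_empty(self):
        cfg = GeneratorConfig(
            n_participants=20, contact_rate=0.0,
            household_size_distribution={1: 1.0},
        )
        pop = generate_population(cfg)
        assert generate_true_contacts(pop, cfg).empty

    def test_event_rate_monte_carlo(self):
        """Mean events/participant/day across replicates sits within 3 SE of
        the configured rate (household process disabled)."""
        rate, n, days, reps = 2.0, 100, 5, 200
        per_rep = np.empty(reps)
        for k in range(reps):
            cfg = GeneratorConfig(
                n_participants=n, n_days=days, contact_rate=rate,
                household_size_distribution={1: 1.0},
                wear_prob_by_day=[1.0] * days, seed=k,
            )
            pop = generate_population(cfg)
            events = generate_true_contacts(pop, cfg)
            per_rep[k] = 2 * len(events) / (n * days)
        se = per_rep.std(ddof=1) / np.sqrt(reps)
        assert abs(per_rep.mean() - rate) < 3 * se

    def test_canonical_order_duration_distance_support(self, tiny_config):
        pop = generate_population(tiny_config)
        events = generate_true_contacts(pop, tiny_config)
        assert (events["person_a"] < events["person_b"]).all()
        assert (events["duration_min"] >= 2).all()
        assert ((events["distance_m"] > 0) & (events["distance_m"] <= 4)).all()

    def test_household_members_get_extra_events(self):
        cfg = GeneratorConfig(
            n_participants=40, contact_rate=0.0, household_contact_prob=1.0,
            household_size_distribution={2: 1.0},
        )
        pop = generate_population(cfg)
        events = generate_true_contacts(pop, cfg)
        # every cohabiting pair, every day
        assert len(events) == 20 * cfg.n_days


class TestRssiStream:
    def test_noiseless_one_metre_reads_calibration_constant(self):
        cfg = GeneratorConfig(n_participants=2, rssi_noise_sd=0.0)
        sched = all_wearing(pd.DataFrame(
            {"participant_id": ["P1", "P2"], "household_id": ["H1", "H2"]}
        ), cfg.n_days)
        readings = simulate_rssi_stream(one_event(distance=1.0), sched, cfg)
        assert (readings["rssi_dbm"] == -50).all()
        assert len(readings) == 2 * 8  # two directions, 2 min at 15 s

    def test_noiseless_two_metres_hits_class_boundary(self):
        cfg = GeneratorConfig(n_participants=2, rssi_noise_sd=0.0)
        sched = all_wearing(pd.DataFrame(
            {"participant_id": ["P1", "P2"], "household_id": ["H1", "H2"]}
        ), cfg.n_days)
        readings = simulate_rssi_stream(one_event(distance=2.0), sched, cfg)
        assert (readings["rssi_dbm"] == -56).all()

    @pytest.mark.parametrize("distance,expected_class", [(0.5, 0), (1.5, 1), (3.0, 2)])
    def test_noiseless_class_recovery(self, distance, expected_class):
        """classify(simulate(d)) recovers the distance band of d."""
        cfg = GeneratorConfig(n_participants=2, rssi_noise_sd=0.0)
        sched = all_wearing(pd.DataFrame(
            {"participant_id": ["P1", "P2"], "household_id": ["H1", "H2"]}
        ), cfg.n_days)
        readings = simulate_rssi_stream(one_event(distance=distance), sched, cfg)
        records = build_two_minute_records(readings)
        assert set(records["proximity_class"]) == {expected_class}

    def test_unworn_cards_emit_nothing(self):
        cfg = GeneratorConfig(n_participants=2)
        pop = pd.DataFrame({"participant_id": ["P1", "P2"], "household_id": ["H1", "H2"]})
        sched = all_wearing(pop, cfg.n_days)
        sched.wear.loc["P1", :] = False
        assert simulate_rssi_stream(one_event(), sched, cfg).empty

    def test_unknown_participant_rejected(self):
        cfg = GeneratorConfig(n_participants=2)
        pop = pd.DataFrame({"participant_id": ["P1", "P2"], "household_id": ["H1", "H2"]})
        sched = all_wearing(pop, cfg.n_days)
        with pytest.raises(DataError):
            simulate_rssi_stream(one_event(a="P1", b="P9"), sched, cfg)

    def test_household_colocation_emits_full_day_class0(self):
        cfg = GeneratorConfig(n_participants=2, rssi_noise_sd=0.0)
        pop = pd.DataFrame({"participant_id": ["P1", "P2"], "household_id": ["H1", "H1"]})
        sched = all_wearing(pop, cfg.n_days)
        sched.household_colocated.loc["H1", 2] = True
        empty_events = one_event().iloc[0:0]
        readings = simulate_rssi_stream(empty_events, sched, cfg, population=pop)
        assert len(readings) == 2 * 24 * 3600 // 15
        day = pd.to_datetime(readings["timestamp"]).dt.normalize().unique()
        assert len(day) == 1 and day[0] == pd.Timestamp("2020-11-10")
        # close-range level: class-0 territory
        assert (readings["rssi_dbm"] >= -50).all()


class TestCaseReports:
    def test_perfect_recall_reports_everything_exactly(self):
        cfg = GeneratorConfig(n_participants=4, p_report=1.0, p_date_shift=0.0)
        events = pd.concat(
            [one_event("P1", "P2", day=1), one_event("P1", "P3", day=2)],
            ignore_index=True,
        )
        reports = simulate_case_reports(events, ["P1", "P2"], cfg)
        got = set(zip(reports.reporter_id, reports.contact_id, reports.day))
        assert got == {("P1", "P2", 1), ("P2", "P1", 1), ("P1", "P3", 2)}
        assert (reports["duration_min"] >= 2).all()

    def test_zero_recall_is_empty(self):
        cfg = GeneratorConfig(n_participants=4, p_report=0.0)
        assert simulate_case_reports(one_event(), ["P1", "P2"], cfg).empty

    def test_same_day_repeats_collapse(self):
        cfg = GeneratorConfig(n_participants=4, p_report=1.0, p_date_shift=0.0)
        events = pd.concat(
            [one_event("P1", "P2", day=1, duration=2),
             one_event("P1", "P2", day=1, duration=30, start="2020-11-09 15:00:00")],
            ignore_index=True,
        )
        reports = simulate_case_reports(events, ["P1"], cfg)
        assert len(reports) == 1
        assert reports.loc[0, "duration_min"] == 30

    def test_date_shift_clamps_to_trial(self):
        cfg = GeneratorConfig(n_participants=4, n_days=3, p_report=1.0,
                              p_date_shift=1.0, wear_prob_by_day=[1, 1, 1], seed=5)
        events = pd.concat(
            [one_event("P1", f"P{k}", day=d) for k, d in
             [(2, 1), (3, 1), (4, 3), (5, 3), (6, 2)]],
            ignore_index=True,
        )
        reports = simulate_case_reports(events, ["P1"], cfg)
        assert reports["day"].between(1, 3).all()

    def test_report_reciprocity_recovers_recall_probability(self):
        """With independent recall at rate p, the report network's
        reciprocity r converges to p (here 500 disjoint dyads)."""
        from cardtrace.case_investigation import build_reported_dyads
        from cardtrace.reciprocity import dyad_census, pooled_reciprocity

        p = 0.7
        n_dyads = 500
        cfg = GeneratorConfig(n_participants=2 * n_dyads, p_report=p,
                              p_date_shift=0.0, seed=123)
        people = [f"P{i:04d}" for i in range(2 * n_dyads)]
        events = pd.DataFrame(
            {
                "person_a": people[:n_dyads],
                "person_b": people[n_dyads:],
                "day": np.tile(np.arange(1, 6), n_dyads)[:n_dyads],
                "start_time": pd.Timestamp("2020-11-09 10:00:00"),
                "duration_min": 10,
                "distance_m": 1.0,
            }
        )
        reports = simulate_case_reports(events, people, cfg)
        nets = build_reported_dyads(reports, people, days=range(1, 8))
        pool = pooled_reciprocity(
            [dyad_census(n) for n in nets.values() if n.edges]
        )
        se = np.sqrt(p * (1 - p) / (2 * n_dyads * p))
        assert abs(pool.r - p) < 2 * se

    def test_card_reciprocity_recovers_detection_probability(self):
        """With Gaussian RSSI noise, a direction is detected iff all eight
        15-s readings clear the -62 dBm floor; the card network's r equals
        that per-direction probability (computed from the normal CDF).
        The raw aggregation chain is used: the symmetric-role filter would
        preferentially remove one-sided detections."""
        from cardtrace.card_pipeline import (
            aggregate_daily, aggregate_two_hour, build_two_minute_records,
        )
        from cardtrace.reciprocity import DyadCensus, reciprocity_r

        n_dyads, sd, dist = 500, 2.0, 3.0
        cfg = GeneratorConfig(n_participants=2 * n_dyads, rssi_noise_sd=sd, seed=77)
        people = [f"P{i:04d}" for i in range(2 * n_dyads)]
        pop = pd.DataFrame(
            {"participant_id": people,
             "household_id": [f"H{i:04d}" for i in range(2 * n_dyads)]}
        )
        events = pd.DataFrame(
            {
                "person_a": people[:n_dyads],
                "person_b": people[n_dyads:],
                "day": 1,
                "start_time": pd.Timestamp("2020-11-09 10:00:00"),
                "duration_min": 2,
                "distance_m": dist,
            }
        )
        sched = all_wearing(pop, cfg.n_days)
        readings = simulate_rssi_stream(events, sched, cfg)
        daily = aggregate_daily(aggregate_two_hour(build_two_minute_records(readings)))
        edges = set(zip(daily["observer_id"], daily["observed_id"]))
        mutual = sum((b, a) in edges for a, b in edges) // 2
        r, _ = reciprocity_r(DyadCensus(mutual, len(edges) - 2 * mutual, 0))
        mu = cfg.rssi_at_1m - 20 * np.log10(dist)
        p_slot = scipy.stats.norm.sf(-62.5, loc=mu, scale=sd)
        q = p_slot**8
        se = np.sqrt(q * (1 - q) / max(len(edges), 1))
        assert abs(r - q) < 3 * se

    def test_wear_compliance_recovered_from_zero_interaction_fraction(self):
        """Fraction of focal participants with no card records on a day
        converges to 1 - wear probability when partners always wear."""
        from cardtrace.card_pipeline import (
            aggregate_daily, aggregate_two_hour, build_two_minute_records,
        )

        n_pairs, wear_p = 500, 0.7
        cfg = GeneratorConfig(n_participants=2 * n_pairs, n_days=1,
                              wear_prob_by_day=[wear_p], rssi_noise_sd=0.0, seed=21)
        focal = [f"A{i:03d}" for i in range(n_pairs)]
        partners = [f"B{i:03d}" for i in range(n_pairs)]
        pop = pd.DataFrame(
            {"participant_id": focal + partners,
             "household_id": [f"H{i:04d}" for i in range(2 * n_pairs)]}
        )
        sched = generate_wear_schedule(pop, cfg)
        sched.wear.loc[partners, :] = True  # partners compliant
        events = pd.DataFrame(
            {
                "person_a": focal,
                "person_b": partners,
                "day": 1,
                "start_time": pd.Timestamp("2020-11-09 10:00:00"),
                "duration_min": 4,
                "distance_m": 1.0,
            }
        )
        readings = simulate_rssi_stream(events, sched, cfg)
        daily = aggregate_daily(aggregate_two_hour(build_two_minute_records(readings)))
        active = set(daily["observer_id"]) | set(daily["observed_id"])
        frac_zero = sum(1 for f in focal if f not in active) / n_pairs
        se = np.sqrt(wear_p * (1 - wear_p) / n_pairs)
        assert abs(frac_zero - (1 - wear_p)) < 2 * se


def test_end_to_end_seeded_reproducibility(tiny_config):
    """The full generator chain is bit-identical across runs with one seed."""
    def run():
        pop = generate_population(tiny_config)
        events = generate_true_contacts(pop, tiny_config)
        sched = generate_wear_schedule(pop, tiny_config)
        readings = simulate_rssi_stream(events, sched, tiny_config, population=pop)
        reports = simulate_case_reports(
            events, pop["participant_id"][: tiny_config.n_interviewed], tiny_config
        )
        return pop, events, readings, reports

    first, second = run(), run()
    for a, b in zip(first, second):
        pd.testing.assert_frame_equal(a, b)
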