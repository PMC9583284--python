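"""Probabilistic linkage: candidates, comparison, EM, scoring, thresholds,
adjudication — each checked against an independent brute-force oracle where
one exists."""

import numpy as np
import pandas as pd
import pytest

from ueclink import GeneratorConfig, EntityMap
from ueclink.generate import degrade_records, generate_activity, generate_population
from ueclink.ingest import validate_records, default_code_sets
from ueclink.generate import strip_truth
from ueclink.linkage import (
    COMPARISON_FIELDS,
    FellegiSunterModel,
    FellegiSunterResults,
    adjudicate,
    compare_pairs,
    generate_candidates,
    select_threshold,
)

from conftest import VALID_NHS, rec, records_frame


# ---------------------------------------------------------------------------
# independent predicate oracle (plain-python re-statement of the rules)
# ---------------------------------------------------------------------------

def _any_pattern(a, b):
    pats = []
    if a["postcode"] and b["postcode"]:
        pats.append(a["postcode"] == b["postcode"])
    fa = a["first_name"][0] if a["first_name"] else None
    fb = b["first_name"][0] if b["first_name"] else None
    la = a["last_name"][0] if a["last_name"] else None
    lb = b["last_name"][0] if b["last_name"] else None
    if fa and fb and la and lb:
        pats.append(fa == fb and la == lb)
    age_ok = (
        a["age"] is not None
        and b["age"] is not None
        and abs(a["age"] - b["age"]) <= 10
    )
    if fa and fb:
        pats.append(fa == fb and age_ok)
    if la and lb:
        pats.append(la == lb and age_ok)
    if a["dob"] is not None and b["dob"] is not None:
        da, db = a["dob"], b["dob"]
        pats.append(abs((da - db).days) <= 31)
        pats.append(da.year == db.year and da.month == db.day and da.day == db.month)
        pats.append(da.month == db.month and da.day == db.day)
    return any(pats)


def _row(r):
    return {
        "postcode": r["postcode"] if isinstance(r["postcode"], str) else None,
        "first_name": r["first_name"] if isinstance(r["first_name"], str) else None,
        "last_name": r["last_name"] if isinstance(r["last_name"], str) else None,
        "age": None if pd.isna(r["age_at_activity"]) else int(r["age_at_activity"]),
        "dob": None if pd.isna(r["dob"]) else r["dob"],
    }


def brute_force_candidates(amb, ed, ip):
    """Exhaustive all-pairs filtering by the blocking/windowing/pattern
    predicates; the oracle for generate_candidates."""
    out = set()
    for _, a in amb.iterrows():
        arr = a["end_datetime"]
        for _, e in ed.iterrows():
            if e["site"] != a["site"] or pd.isna(e["start_datetime"]) or pd.isna(e["site"]):
                continue
            dt = e["start_datetime"] - arr
            if -pd.Timedelta(hours=1) <= dt <= pd.Timedelta(hours=3):
                if _any_pattern(_row(a), _row(e)):
                    out.add((a["record_id"], e["record_id"], "ED"))
        day = arr.normalize()
        days = {day}
        if arr.time() < pd.Timestamp("2000-01-01 01:00").time():
            days.add(day - pd.Timedelta(days=1))
        if arr.time() > pd.Timestamp("2000-01-01 21:00").time():
            days.add(day + pd.Timedelta(days=1))
        for _, i in ip.iterrows():
            if i["site"] != a["site"] or pd.isna(i["start_datetime"]) or pd.isna(i["site"]):
                continue
            if i["start_datetime"].normalize() in days:
                if _any_pattern(_row(a), _row(i)):
                    out.add((a["record_id"], i["record_id"], "IP"))
    return out


def _amb(**kw):
    base = dict(
        source="AMB", conveyed=True, site="SITE00", provider_patient_id=None,
        start_datetime="2016-06-01 13:30", end_datetime="2016-06-01 14:00",
    )
    base.update(kw)
    return rec(**base)


class TestCandidateGeneration:
    def test_window_lower_boundary_inclusive(self):
        amb = records_frame([_amb(postcode="AA1 1AA")])
        ed = records_frame(
            [rec(start_datetime="2016-06-01 13:00", postcode="AA1 1AA")]
        )
        ip = records_frame([rec(source="IP")]).iloc[:0]
        pairs = generate_candidates(amb, ed, ip)
        assert len(pairs) == 1

    def test_beyond_three_hours_no_pair(self):
        amb = records_frame([_amb(postcode="AA1 1AA")])
        ed = records_frame(
            [rec(start_datetime="2016-06-01 17:01", postcode="AA1 1AA")]
        )
        pairs = generate_candidates(amb, ed, records_frame([rec(source="IP")]).iloc[:0])
        assert len(pairs) == 0

    def test_early_morning_previous_day_admission(self):
        amb = records_frame(
            [_amb(start_datetime="2016-06-02 00:00", end_datetime="2016-06-02 00:30",
                  dob="1980-05-10")]
        )
        ip = records_frame(
            [rec(source="IP", start_datetime="2016-06-01 19:00", dob="1980-05-10",
                 admission_method="emergency")]
        )
        pairs = generate_candidates(amb, records_frame([rec()]).iloc[:0], ip)
        assert len(pairs) == 1
        assert pairs["hosp_source"].iloc[0] == "IP"

    def test_late_evening_next_day_admission(self):
        amb = records_frame(
            [_amb(start_datetime="2016-06-01 21:30", end_datetime="2016-06-01 22:00",
                  dob="1980-05-10")]
        )
        ip = records_frame(
            [rec(source="IP", start_datetime="2016-06-02 03:00", dob="1980-05-10",
                 admission_method="emergency")]
        )
        pairs = generate_candidates(amb, records_frame([rec()]).iloc[:0], ip)
        assert len(pairs) == 1

    def test_window_without_pattern_is_not_enough(self):
        amb = records_frame([_amb(postcode="AA1 1AA", dob="1980-05-10")])
        ed = records_frame(
            [rec(start_datetime="2016-06-01 14:30", postcode="BB2 2BB", dob="1955-01-20")]
        )
        pairs = generate_candidates(amb, ed, records_frame([rec(source="IP")]).iloc[:0])
        assert len(pairs) == 0

    def test_non_conveyed_rejected(self):
        amb = records_frame([_amb(conveyed=False)])
        with pytest.raises(ValueError, match="conveyed"):
            generate_candidates(amb, records_frame([rec()]), records_frame([rec(source='IP')]))

    def test_matches_bruteforce_oracle_on_synthetic_instance(self):
        cfg = GeneratorConfig(
            n_persons=120, seed=5, n_sites=2,
            period_start=pd.Timestamp("2016-06-01").date(),
            period_end=pd.Timestamp("2016-06-28").date(),
            event_rates={"NHS111": 0.2, "AMB": 0.8, "ED": 1.0, "IP": 0.6},
        )
        events = degrade_records(generate_activity(generate_population(cfg), cfg), cfg)
        clean, _ = validate_records(strip_truth(events), default_code_sets(["SITE00", "SITE01"]))
        amb = clean[(clean["source"] == "AMB") & (clean["conveyed"] == True)]  # noqa: E712
        ed = clean[clean["source"] == "ED"]
        ip = clean[clean["source"] == "IP"]
        assert len(clean) <= 500
        got = generate_candidates(amb, ed, ip)
        got_set = set(map(tuple, got[["amb_record_id", "hosp_record_id", "hosp_source"]].to_numpy()))
        assert got_set == brute_force_candidates(amb, ed, ip)
        assert len(got_set) > 0


class TestCompare:
    def _compared(self, amb_kw, hosp_kw):
        amb = records_frame([_amb(**amb_kw)])
        hosp = records_frame([rec(**hosp_kw)])
        pairs = pd.DataFrame(
            {
                "amb_record_id": [amb["record_id"].iloc[0]],
                "hosp_record_id": [hosp["record_id"].iloc[0]],
                "hosp_source": ["ED"],
            }
        )
        return compare_pairs(pairs, amb, hosp)

    def test_jaro_winkler_similarity_value(self):
        out = self._compared(
            dict(first_name="MARTHA", last_name="SMITH"),
            dict(first_name="MARHTA", last_name="SMITH"),
        )
        assert out["sim_first_name"].iloc[0] == pytest.approx(0.9611, abs=1e-4)
        assert out["cmp_first_name"].iloc[0] == 1  # above the 0.8 default

    def test_identical_records_all_agree(self):
        shared = dict(
            dob="1980-05-10", age_at_activity=36, first_name="ALICE",
            last_name="SMITH", postcode="AA1 1AA", sex="female",
        )
        out = self._compared(shared, shared)
        assert all(out[f"cmp_{f}"].iloc[0] == 1 for f in COMPARISON_FIELDS)

    def test_missing_side_codes_missing(self):
        out = self._compared(dict(postcode="AA1 1AA"), dict(postcode=None))
        assert out["cmp_postcode"].iloc[0] == -1
        assert out["cmp_sex"].iloc[0] == -1  # neither side has sex

    def test_nhs_label_columns(self):
        out = self._compared(
            dict(nhs_number=VALID_NHS[1]), dict(nhs_number=VALID_NHS[2])
        )
        assert bool(out["both_nhs_known"].iloc[0])
        assert not bool(out["nhs_agree"].iloc[0])


def _simulate_vectors(m, u, p, n, seed):
    rng = np.random.default_rng(seed)
    z = rng.random(n) < p
    probs = np.where(z[:, None], m, u)
    X = (rng.random((n, len(m))) < probs).astype(np.int8)
    df = pd.DataFrame({f"cmp_{f}": X[:, j] for j, f in enumerate(COMPARISON_FIELDS)})
    df["sim_first_name"] = np.nan
    df["sim_last_name"] = np.nan
    return df, z, X


TRUE_M = np.array([0.95, 0.9, 0.9, 0.85, 0.9, 0.9, 0.8, 0.95])
TRUE_U = np.array([0.05, 0.08, 0.03, 0.3, 0.01, 0.01, 0.001, 0.5])


class TestEM:
    def test_loglik_monotone_nondecreasing(self):
        df, _, _ = _simulate_vectors(TRUE_M, TRUE_U, 0.1, 2000, seed=4)
        res = FellegiSunterModel(df).fit()
        assert (np.diff(res.loglik_trace) >= -1e-8).all()

    def test_recovery_matches_complete_data_oracle(self):
        # EM cannot beat the complete-data MLE; it should agree with it
        # closely, and land within 3 binomial standard errors of the truth
        df, z, X = _simulate_vectors(TRUE_M, TRUE_U, 0.01, 50_000, seed=0)
        res = FellegiSunterModel(df).fit()
        oracle_m = X[z].mean(axis=0)
        oracle_u = X[~z].mean(axis=0)
        assert np.abs(res.m - oracle_m).max() < 0.01
        assert np.abs(res.u - oracle_u).max() < 0.01
        n_pos, n_neg = int(z.sum()), int((~z).sum())
        se_m = np.sqrt(TRUE_M * (1 - TRUE_M) / n_pos)
        se_u = np.sqrt(TRUE_U * (1 - TRUE_U) / n_neg)
        assert (np.abs(res.m - TRUE_M) <= 3 * se_m + 0.01).all()
        assert (np.abs(res.u - TRUE_U) <= 3 * se_u + 0.005).all()
        assert res.p == pytest.approx(z.mean(), abs=0.005)

    def test_degenerate_all_agree_flagged(self):
        df = pd.DataFrame(
            {f"cmp_{f}": np.ones(100, dtype=np.int8) for f in COMPARISON_FIELDS}
        )
        df["sim_first_name"] = 1.0
        df["sim_last_name"] = 1.0
        with pytest.warns(UserWarning, match="uninformative"):
            res = FellegiSunterModel(df).fit()
        assert res.uninformative.all()
        assert (res.agreement_weight == 0).all()

    def test_weight_signs_for_informative_fields(self):
        df, _, _ = _simulate_vectors(TRUE_M, TRUE_U, 0.2, 5000, seed=9)
        res = FellegiSunterModel(df).fit()
        assert (res.agreement_weight > 0).all()
        assert (res.disagreement_weight < 0).all()


def _single_field_results(field="postcode", m=0.9, u=0.1):
    wpos = np.log2(m / u)
    wneg = np.log2((1 - m) / (1 - u))
    return FellegiSunterResults(
        fields=(field,), m=np.array([m]), u=np.array([u]), p=0.1,
        agreement_weight=np.array([wpos]), disagreement_weight=np.array([wneg]),
        loglik_trace=np.zeros(1), converged=True,
        uninformative=np.array([False]), n_pairs=1, name_similarity_threshold=0.8,
    )


class TestScore:
    def test_single_field_closed_form(self):
        res = _single_field_results()
        df = pd.DataFrame({"cmp_postcode": np.array([1, 0, -1], dtype=np.int8)})
        w = res.score(df)
        assert w[0] == pytest.approx(np.log2(9), abs=1e-10)  # 3.1699
        assert w[1] == pytest.approx(-np.log2(9), abs=1e-10)
        assert w[2] == 0.0

    def test_all_missing_scores_zero(self):
        res = _single_field_results()
        df = pd.DataFrame({"cmp_postcode": np.array([-1, -1], dtype=np.int8)})
        assert (res.score(df) == 0).all()

    def test_name_partial_weight_monotone(self):
        res = _single_field_results(field="first_name")
        df = pd.DataFrame(
            {
                "cmp_first_name": np.array([1, 1, 0], dtype=np.int8),
                "sim_first_name": [1.0, 0.95, 0.5],
            }
        )
        w = res.score(df)
        assert w[0] == pytest.approx(np.log2(9))  # s = 1 gives full weight
        assert w[1] < w[0]
        assert w[2] == pytest.approx(-np.log2(9))  # below threshold: plain w-
        # interpolation formula w- + s (w+ - w-)
        expected = -np.log2(9) + 0.95 * (2 * np.log2(9))
        assert w[1] == pytest.approx(expected)


def brute_force_threshold(weights, labels, target):
    """Exhaustive sweep oracle for select_threshold."""
    uw = sorted(set(weights))
    cands = [uw[0] - 1.0] + [(a + b) / 2 for a, b in zip(uw[:-1], uw[1:])] + [uw[-1] + 1.0]
    best = None
    for t in cands:
        tn = sum(1 for w, y in zip(weights, labels) if not y and w < t)
        n_neg = sum(1 for y in labels if not y)
        spec = tn / n_neg
        if spec >= target and best is None:
            best = t
    return best


class TestSelectThreshold:
    FIXTURE_W = [9.0, 8.5, 7.0, 6.5, 5.0, 4.0, 3.0, 2.0, 1.0, 0.5]
    FIXTURE_Y = [True, True, True, True, False, True, False, False, False, False]

    def _scored(self, w, y, known=None):
        return pd.DataFrame(
            {
                "weight": w,
                "nhs_agree": y,
                "both_nhs_known": [True] * len(w) if known is None else known,
            }
        )

    def test_matches_bruteforce_sweep(self):
        scored = self._scored(self.FIXTURE_W, self.FIXTURE_Y)
        for target in (0.5, 0.8, 0.999):
            curve = select_threshold(scored, target_specificity=target)
            assert curve.chosen_threshold == pytest.approx(
                brute_force_threshold(self.FIXTURE_W, self.FIXTURE_Y, target)
            )
            assert curve.specificity_at_chosen >= target

    def test_perfectly_separated(self):
        w = [10.0, 9.0, 8.0, -1.0, -2.0]
        y = [True, True, True, False, False]
        curve = select_threshold(self._scored(w, y), target_specificity=0.999)
        assert curve.sensitivity_at_chosen == 1.0
        assert curve.specificity_at_chosen == 1.0
        assert curve.f_measure_at_chosen == 1.0

    def test_monotone_curve(self):
        curve = select_threshold(self._scored(self.FIXTURE_W, self.FIXTURE_Y), 0.9)
        t = curve.table.sort_values("threshold")
        assert (np.diff(t["specificity"]) >= -1e-12).all()
        assert (np.diff(t["sensitivity"]) <= 1e-12).all()

    def test_unlabelled_pairs_rejected(self):
        scored = self._scored([1.0, 2.0], [True, False], known=[False, False])
        with pytest.raises(ValueError, match="labelled"):
            select_threshold(scored)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            select_threshold(self._scored([1.0, 2.0], [True, True]))


def _adjudication_setup(nhs_h1=None, nhs_a_cluster=None):
    rows = [
        rec(record_id="A1", source="AMB", conveyed=True, site="SITE00",
            provider_patient_id=None, end_datetime="2016-06-01 14:00"),
        rec(record_id="H1", nhs_number=nhs_h1),
        rec(record_id="H2"),
        rec(record_id="A2", source="AMB", conveyed=True, site="SITE00",
            provider_patient_id=None, end_datetime="2016-06-01 15:00"),
        rec(record_id="X1", nhs_number=nhs_a_cluster),
    ]
    records = records_frame(rows)
    emap = EntityMap(
        {"A1": 0, "H1": 1, "H2": 2, "A2": 3, "X1": 0},
        {"A1": "S7", "H1": "S7", "H2": "S7", "A2": "S7", "X1": "S7"},
    )
    return records, emap


def _scored_links(rows):
    return pd.DataFrame(rows, columns=["amb_record_id", "hosp_record_id", "hosp_source", "weight"])


class TestAdjudicate:
    def test_greatest_link_kept_when_double_runner_up(self):
        records, emap = _adjudication_setup()
        scored = _scored_links([("A1", "H1", "ED", 12.0), ("A1", "H2", "ED", 5.0)])
        links, new_map = adjudicate(scored, 0.0, emap, records)
        assert links[["amb_record_id", "hosp_record_id"]].values.tolist() == [["A1", "H1"]]
        assert new_map.assignments["A1"] == new_map.assignments["H1"]
        assert new_map.provenance["A1"] == "P"

    def test_both_discarded_when_runner_up_too_close(self):
        records, emap = _adjudication_setup()
        scored = _scored_links([("A1", "H1", "ED", 12.0), ("A1", "H2", "ED", 7.0)])
        links, new_map = adjudicate(scored, 0.0, emap, records)
        assert links.empty
        assert new_map.assignments == emap.assignments

    def test_symmetric_rule_for_hospital_records(self):
        records, emap = _adjudication_setup()
        scored = _scored_links([("A1", "H1", "ED", 12.0), ("A2", "H1", "ED", 7.0)])
        links, _ = adjudicate(scored, 0.0, emap, records)
        assert links.empty  # two ambulance suitors within 2x: both dropped

    def test_below_threshold_ignored(self):
        records, emap = _adjudication_setup()
        scored = _scored_links([("A1", "H1", "ED", 12.0)])
        links, new_map = adjudicate(scored, 20.0, emap, records)
        assert links.empty

    def test_conflicting_nhs_numbers_veto_link(self):
        records, emap = _adjudication_setup(nhs_h1=VALID_NHS[1], nhs_a_cluster=VALID_NHS[2])
        scored = _scored_links([("A1", "H1", "ED", 12.0)])
        links, new_map = adjudicate(scored, 0.0, emap, records)
        assert links.empty
        assert new_map.assignments["A1"] != new_map.assignments["H1"]

    def test_agreeing_nhs_numbers_allow_link(self):
        records, emap = _adjudication_setup(nhs_h1=VALID_NHS[1], nhs_a_cluster=VALID_NHS[1])
        scored = _scored_links([("A1", "H1", "ED", 12.0)])
        links, new_map = adjudicate(scored, 0.0, emap, records)
        assert len(links) == 1
        assert new_map.assignments["A1"] == new_map.assignments["H1"]
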