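"""Probabilistic linkage of ambulance records to hospital records.

Ambulance incidents rarely carry an NHS number, but 60% of them convey the
patient to a hospital where a contemporaneous ED attendance or emergency
admission episode exists.  This module links conveyed ambulance records to
ED/inpatient records with the Fellegi-Sunter framework:

1. *Candidate generation*: blocking on the conveyance destination site;
   windowing (ED arrival within -1 h/+3 h of the ambulance's arrival at the
   destination; inpatient admission episode on the same day, extended to
   the previous day for pre-1 a.m. arrivals and the next day for post-9 p.m.
   arrivals); plus at least one of seven agreement patterns on identifiers.
2. *Comparison*: eight fields per pair (year/month/day of birth, age,
   first name, last name, postcode, sex), names via Jaro-Winkler.
3. *Weight estimation*: a two-class latent mixture over the binary
   agreement indicators, fitted by EM under conditional independence
   (``FellegiSunterModel``); agreement weight ``log2(m/u)`` and
   disagreement weight ``log2((1-m)/(1-u))`` per field.
4. *Scoring*: total match weight = sum of agreement/disagreement weights;
   names that agree contribute a Winkler-interpolated partial weight.
5. *Threshold selection*: on the subset of pairs where both records carry
   an NHS number (agreement on it taken as the "real" match label), choose
   the smallest threshold whose specificity reaches the target (99.9% by
   default).
6. *Adjudication*: one link per record (greatest weight, and only if at
   least twice the runner-up); links that would merge deterministic
   clusters with conflicting NHS numbers or dates of birth are discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._text import jaro_winkler_similarity

__all__ = [
    "COMPARISON_FIELDS",
    "generate_candidates",
    "compare_pairs",
    "FellegiSunterModel",
    "FellegiSunterResults",
    "select_threshold",
    "ThresholdCurve",
    "adjudicate",
    "plot_threshold_curve",
]

COMPARISON_FIELDS = (
    "birth_year",
    "birth_month",
    "birth_day",
    "age",
    "first_name",
    "last_name",
    "postcode",
    "sex",
)
NAME_FIELDS = ("first_name", "last_name")

_PAIR_FIELD_COLS = [
    "dob",
    "age_at_activity",
    "first_name",
    "last_name",
    "postcode",
    "sex",
    "nhs_number",
]

ED_WINDOW_BEFORE = pd.Timedelta(hours=1)
ED_WINDOW_AFTER = pd.Timedelta(hours=3)
_EARLY = pd.Timestamp("1970-01-01 01:00").time()  # before 1 a.m.
_LATE = pd.Timestamp("1970-01-01 21:00").time()  # after 9 p.m.

AGE_TOLERANCE_YEARS = 10
DOB_DIFF_DAYS = 31


def _eq(a: pd.Series, b: pd.Series) -> pd.Series:
    """Elementwise equality that is False when either side is missing."""
    return a.notna() & b.notna() & (a == b)


def _pattern_any(df: pd.DataFrame) -> pd.Series:
    """At least one of the seven additional blocking patterns holds."""
    fi_a = df["first_name_a"].str[:1]
    fi_b = df["first_name_b"].str[:1]
    li_a = df["last_name_a"].str[:1]
    li_b = df["last_name_b"].str[:1]
    fi = _eq(fi_a, fi_b)
    li = _eq(li_a, li_b)
    age_close = (
        df["age_at_activity_a"].notna()
        & df["age_at_activity_b"].notna()
        & ((df["age_at_activity_a"] - df["age_at_activity_b"]).abs() <= AGE_TOLERANCE_YEARS)
    )
    dob_both = df["dob_a"].notna() & df["dob_b"].notna()
    dob_close = dob_both & (
        (df["dob_a"] - df["dob_b"]).abs() <= pd.Timedelta(days=DOB_DIFF_DAYS)
    )
    transposed = dob_both & (
        (df["dob_a"].dt.year == df["dob_b"].dt.year)
        & (df["dob_a"].dt.month == df["dob_b"].dt.day)
        & (df["dob_a"].dt.day == df["dob_b"].dt.month)
    )
    month_day = dob_both & (
        (df["dob_a"].dt.month == df["dob_b"].dt.month)
        & (df["dob_a"].dt.day == df["dob_b"].dt.day)
    )
    p1 = _eq(df["postcode_a"], df["postcode_b"])
    p2 = fi & li
    p3 = fi & age_close
    p4 = li & age_close
    return (p1 | p2 | p3 | p4 | dob_close | transposed | month_day).fillna(False)


def _attach_fields(pairs: pd.DataFrame, amb: pd.DataFrame, hosp: pd.DataFrame) -> pd.DataFrame:
    a = amb.set_index("record_id")[_PAIR_FIELD_COLS].add_suffix("_a")
    b = hosp.set_index("record_id")[_PAIR_FIELD_COLS].add_suffix("_b")
    return pairs.join(a, on="amb_record_id").join(b, on="hosp_record_id")


def generate_candidates(
    amb: pd.DataFrame, ed: pd.DataFrame, ip: pd.DataFrame
) -> pd.DataFrame:
    """Blocked, windowed, pattern-filtered candidate pairs.

    ``amb`` must contain only conveyed ambulance records with a destination
    site and an arrival time (``end_datetime``); passing anything else is a
    contract error.  Returns one row per candidate with columns
    amb_record_id, hosp_record_id, hosp_source.
    """
    if len(amb) == 0:
        return pd.DataFrame(columns=["amb_record_id", "hosp_record_id", "hosp_source"])
    conveyed = amb["conveyed"]
    if not bool((conveyed == True).all()):  # noqa: E712  (nullable boolean)
        raise ValueError("non-conveyed ambulance record passed to candidate generation")
    if amb["site"].isna().any() or amb["end_datetime"].isna().any():
        raise ValueError("conveyed ambulance records must carry a site and arrival time")

    a = amb[["record_id", "site", "end_datetime"]].rename(
        columns={"record_id": "amb_record_id", "end_datetime": "amb_arrival"}
    )

    # ED: same site, arrival within [-1 h, +3 h] of the ambulance arrival
    e = ed.loc[
        ed["site"].notna() & ed["start_datetime"].notna(),
        ["record_id", "site", "start_datetime"],
    ].rename(columns={"record_id": "hosp_record_id", "start_datetime": "ed_arrival"})
    ed_pairs = a.merge(e, on="site")
    in_window = (ed_pairs["ed_arrival"] >= ed_pairs["amb_arrival"] - ED_WINDOW_BEFORE) & (
        ed_pairs["ed_arrival"] <= ed_pairs["amb_arrival"] + ED_WINDOW_AFTER
    )
    ed_pairs = ed_pairs.loc[in_window, ["amb_record_id", "hosp_record_id"]]
    ed_pairs["hosp_source"] = "ED"

    # IP: admission episode on the same day; previous day when the ambulance
    # arrived before 1 a.m.; following day when after 9 p.m.
    day = a["amb_arrival"].dt.normalize()
    tod = a["amb_arrival"].dt.time
    blocks = [pd.DataFrame({"amb_record_id": a["amb_record_id"], "site": a["site"], "day": day})]
    early = pd.Series([t < _EARLY for t in tod], index=a.index)
    late = pd.Series([t > _LATE for t in tod], index=a.index)
    if early.any():
        blocks.append(
            pd.DataFrame(
                {
                    "amb_record_id": a.loc[early, "amb_record_id"],
                    "site": a.loc[early, "site"],
                    "day": day[early] - pd.Timedelta(days=1),
                }
            )
        )
    if late.any():
        blocks.append(
            pd.DataFrame(
                {
                    "amb_record_id": a.loc[late, "amb_record_id"],
                    "site": a.loc[late, "site"],
                    "day": day[late] + pd.Timedelta(days=1),
                }
            )
        )
    a_days = pd.concat(blocks, ignore_index=True)
    i = ip.loc[
        ip["site"].notna() & ip["start_datetime"].notna(),
        ["record_id", "site", "start_datetime"],
    ].rename(columns={"record_id": "hosp_record_id"})
    i["day"] = i["start_datetime"].dt.normalize()
    ip_pairs = a_days.merge(i[["hosp_record_id", "site", "day"]], on=["site", "day"])[
        ["amb_record_id", "hosp_record_id"]
    ].drop_duplicates()
    ip_pairs["hosp_source"] = "IP"

    pairs = pd.concat([ed_pairs, ip_pairs], ignore_index=True)
    if pairs.empty:
        return pairs

    hosp = pd.concat([ed, ip], ignore_index=True)
    with_fields = _attach_fields(pairs, amb, hosp)
    keep = _pattern_any(with_fields)
    return pairs.loc[keep.to_numpy()].reset_index(drop=True)


def compare_pairs(
    pairs: pd.DataFrame,
    amb: pd.DataFrame,
    hosp: pd.DataFrame,
    name_similarity_threshold: float = 0.8,
) -> pd.DataFrame:
    """Agreement vectors for candidate pairs.

    Exact comparison for year/month/day of birth, age, postcode and sex;
    Jaro-Winkler for the two names, which count as agreeing when similarity
    reaches ``name_similarity_threshold``.  Each ``cmp_<field>`` column is
    coded 1 (agree), 0 (disagree) or -1 (either side missing).  The NHS
    number is *not* compared; it is carried as the evaluation label
    (``both_nhs_known``, ``nhs_agree``).
    """
    df = _attach_fields(pairs, amb, hosp)
    out = pairs.copy()

    def code(agree: pd.Series, missing: pd.Series) -> np.ndarray:
        c = np.where(agree.to_numpy(), 1, 0).astype(np.int8)
        c[missing.to_numpy()] = -1
        return c

    dob_missing = df["dob_a"].isna() | df["dob_b"].isna()
    for part in ("year", "month", "day"):
        agree = _eq(getattr(df["dob_a"].dt, part), getattr(df["dob_b"].dt, part))
        out[f"cmp_birth_{part}"] = code(agree, dob_missing)

    age_missing = df["age_at_activity_a"].isna() | df["age_at_activity_b"].isna()
    out["cmp_age"] = code(_eq(df["age_at_activity_a"], df["age_at_activity_b"]), age_missing)

    for field in NAME_FIELDS:
        a_vals = df[f"{field}_a"].to_numpy(dtype=object)
        b_vals = df[f"{field}_b"].to_numpy(dtype=object)
        sims = np.full(len(df), np.nan)
        for k, (x, y) in enumerate(zip(a_vals, b_vals)):
            if isinstance(x, str) and isinstance(y, str):
                sims[k] = jaro_winkler_similarity(x, y)
        out[f"sim_{field}"] = sims
        cmp = np.where(sims >= name_similarity_threshold, 1, 0).astype(np.int8)
        cmp[np.isnan(sims)] = -1
        out[f"cmp_{field}"] = cmp

    pc_missing = df["postcode_a"].isna() | df["postcode_b"].isna()
    out["cmp_postcode"] = code(_eq(df["postcode_a"], df["postcode_b"]), pc_missing)
    sex_missing = df["sex_a"].isna() | df["sex_b"].isna()
    out["cmp_sex"] = code(_eq(df["sex_a"], df["sex_b"]), sex_missing)

    out["both_nhs_known"] = (df["nhs_number_a"].notna() & df["nhs_number_b"].notna()).to_numpy()
    out["nhs_agree"] = _eq(df["nhs_number_a"], df["nhs_number_b"]).to_numpy()
    return out


@dataclass
class FellegiSunterResults:
    """Fitted m/u probabilities, match prior and log2 weights."""

    fields: tuple
    m: np.ndarray
    u: np.ndarray
    p: float
    agreement_weight: np.ndarray
    disagreement_weight: np.ndarray
    loglik_trace: np.ndarray
    converged: bool
    uninformative: np.ndarray
    n_pairs: int
    name_similarity_threshold: float

    def score(self, comparisons: pd.DataFrame) -> np.ndarray:
        """Total match weight per pair.

        Sum of agreement weights over agreeing fields and disagreement
        weights over disagreeing fields; missing fields contribute zero.
        A name agreement at similarity ``s`` contributes the interpolated
        ``w- + s * (w+ - w-)``, the full agreement weight only at s = 1.
        """
        X = comparisons[[f"cmp_{f}" for f in self.fields]].to_numpy(dtype=np.int8)
        wpos = self.agreement_weight
        wneg = self.disagreement_weight
        weight = np.zeros(len(X))
        for j, field in enumerate(self.fields):
            col = X[:, j]
            if field in NAME_FIELDS:
                sims = comparisons[f"sim_{field}"].to_numpy()
                agree = col == 1
                interp = wneg[j] + sims * (wpos[j] - wneg[j])
                weight += np.where(agree, np.nan_to_num(interp), 0.0)
                weight += np.where(col == 0, wneg[j], 0.0)
            else:
                weight += np.where(col == 1, wpos[j], 0.0)
                weight += np.where(col == 0, wneg[j], 0.0)
        return weight

    def summary(self) -> str:
        lines = [
            "Fellegi-Sunter latent-class model",
            f"  pairs: {self.n_pairs}   match prior p: {self.p:.4f}   "
            f"log-likelihood: {self.loglik_trace[-1]:.2f}   "
            f"iterations: {len(self.loglik_trace)}"
            + ("" if self.converged else "   (NOT converged)"),
            f"  {'field':<12} {'m':>8} {'u':>8} {'w+':>8} {'w-':>8}",
        ]
        for j, field in enumerate(self.fields):
            flag = "  (uninformative)" if self.uninformative[j] else ""
            lines.append(
                f"  {field:<12} {self.m[j]:8.4f} {self.u[j]:8.4f} "
                f"{self.agreement_weight[j]:8.3f} {self.disagreement_weight[j]:8.3f}{flag}"
            )
        return "\n".join(lines)


class FellegiSunterModel:
    """Two-class conditional-independence mixture over agreement indicators.

    One latent class is the set of true matches, the other the true
    nonmatches.  EM iterates between posterior match probabilities per pair
    and per-field agreement probabilities given match (m) and nonmatch (u);
    missing indicators are simply left out of a pair's likelihood.
    """

    def __init__(
        self,
        comparisons: pd.DataFrame,
        fields: tuple = COMPARISON_FIELDS,
        name_similarity_threshold: float = 0.8,
    ):
        self.fields = tuple(fields)
        self.comparisons = comparisons
        self.name_similarity_threshold = name_similarity_threshold
        self._X = comparisons[[f"cmp_{f}" for f in self.fields]].to_numpy(dtype=np.int8)
        if len(self._X) < 2:
            raise ValueError("need at least 2 comparison vectors to fit")

    def fit(
        self,
        m0: float = 0.9,
        u0: float = 0.1,
        p0: float = 0.01,
        tol: float = 1e-6,
        max_iter: int = 1000,
    ) -> FellegiSunterResults:
        X = self._X
        nf = len(self.fields)
        agree = X == 1
        disagree = X == 0
        observed = X >= 0
        eps = 1e-6

        m = np.full(nf, float(m0))
        u = np.full(nf, float(u0))
        p = float(p0)
        trace = []
        converged = False
        for _ in range(max_iter):
            log_lik_m = agree @ np.log(m) + disagree @ np.log1p(-m)
            log_lik_u = agree @ np.log(u) + disagree @ np.log1p(-u)
            log_num = np.log(p) + log_lik_m
            log_tot = np.logaddexp(log_num, np.log1p(-p) + log_lik_u)
            g = np.exp(log_num - log_tot)
            ll = float(log_tot.sum())
            trace.append(ll)
            if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
                converged = True
                break
            gm = g @ observed  # effective number of observed matches per field
            gu = (1.0 - g) @ observed
            m = np.clip((g @ agree) / np.maximum(gm, eps), eps, 1 - eps)
            u = np.clip(((1.0 - g) @ agree) / np.maximum(gu, eps), eps, 1 - eps)
            p = float(np.clip(g.mean(), eps, 1 - eps))

        n_agree = agree.sum(axis=0)
        n_disagree = disagree.sum(axis=0)
        uninformative = (n_agree == 0) | (n_disagree == 0)
        wpos = np.log2(m / u)
        wneg = np.log2((1 - m) / (1 - u))
        if uninformative.any():
            bad = [f for f, b in zip(self.fields, uninformative) if b]
            warnings.warn(
                f"fields with no observed variation treated as uninformative: {bad}",
                stacklevel=2,
            )
            wpos[uninformative] = 0.0
            wneg[uninformative] = 0.0
        return FellegiSunterResults(
            fields=self.fields,
            m=m,
            u=u,
            p=p,
            agreement_weight=wpos,
            disagreement_weight=wneg,
            loglik_trace=np.asarray(trace),
            converged=converged,
            uninformative=uninformative,
            n_pairs=len(X),
            name_similarity_threshold=self.name_similarity_threshold,
        )


@dataclass
class ThresholdCurve:
    """Performance sweep over match-weight thresholds on the labelled subset."""

    table: pd.DataFrame
    chosen_threshold: float
    target_specificity: float
    sensitivity_at_chosen: float
    specificity_at_chosen: float
    ppv_at_chosen: float
    f_measure_at_chosen: float
    n_labelled: int
    n_label_matches: int


def select_threshold(
    scored: pd.DataFrame, target_specificity: float = 0.999
) -> ThresholdCurve:
    """Choose the smallest match-weight threshold achieving the specificity
    target on the NHS-number-labelled pair subset.

    Only pairs where both records carry an NHS number are used; agreement
    on it defines the "real" match label.  Thresholds are swept over the
    midpoints of adjacent distinct observed weights (plus sentinels beyond
    both extremes), which makes the sweep independent of floating-point
    representation.
    """
    lab = scored[scored["both_nhs_known"]]
    if lab.empty:
        raise ValueError("no labelled pairs: no pair has both NHS numbers present")
    w = lab["weight"].to_numpy(dtype=float)
    y = lab["nhs_agree"].to_numpy(dtype=bool)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("labelled pairs contain only one class; cannot sweep thresholds")

    uw = np.unique(w)
    thresholds = np.concatenate([[uw[0] - 1.0], (uw[:-1] + uw[1:]) / 2.0, [uw[-1] + 1.0]])
    pos_sorted = np.sort(w[y])
    neg_sorted = np.sort(w[~y])
    tp = n_pos - np.searchsorted(pos_sorted, thresholds, side="left")
    fp = n_neg - np.searchsorted(neg_sorted, thresholds, side="left")
    sens = tp / n_pos
    spec = (n_neg - fp) / n_neg
    denom = tp + fp
    ppv = np.where(denom > 0, tp / np.maximum(denom, 1), 1.0)  # no predictions: PPV 1
    f_denom = ppv + sens
    f_measure = np.where(f_denom > 0, 2 * ppv * sens / np.where(f_denom > 0, f_denom, 1), 0.0)

    table = pd.DataFrame(
        {
            "threshold": thresholds,
            "sensitivity": sens,
            "specificity": spec,
            "ppv": ppv,
            "f_measure": f_measure,
        }
    )
    attainable = spec >= target_specificity
    if not attainable.any():
        raise ValueError(
            f"target specificity {target_specificity} not attainable; "
            f"maximum achievable is {spec.max():.6f}"
        )
    k = int(np.argmax(attainable))  # thresholds ascend, specificity is monotone
    return ThresholdCurve(
        table=table,
        chosen_threshold=float(thresholds[k]),
        target_specificity=target_specificity,
        sensitivity_at_chosen=float(sens[k]),
        specificity_at_chosen=float(spec[k]),
        ppv_at_chosen=float(ppv[k]),
        f_measure_at_chosen=float(f_measure[k]),
        n_labelled=len(y),
        n_label_matches=n_pos,
    )


def _greatest_2x(links: pd.DataFrame, group_col: str) -> pd.DataFrame:
    """Per group, keep the greatest-weighted link, and only when its weight
    is at least twice the runner-up's."""
    keep_rows = []
    for _, group in links.groupby(group_col, sort=False):
        if len(group) == 1:
            keep_rows.append(group.index[0])
            continue
        g = group.sort_values(
            ["weight", "amb_record_id", "hosp_record_id"], ascending=[False, True, True]
        )
        w0 = g["weight"].iloc[0]
        w1 = g["weight"].iloc[1]
        if w0 >= 2.0 * w1:
            keep_rows.append(g.index[0])
    return links.loc[keep_rows]


class _UnionFind:
    """Union-find over entity ids; roots are the smallest member id."""

    def __init__(self):
        self.parent: dict = {}

    def find(self, x):
        p = self.parent.get(x, x)
        if p == x:
            return x
        root = self.find(p)
        self.parent[x] = root
        return root

    def union(self, x, y):
        rx, ry = self.find(x), self.find(y)
        if rx == ry:
            return rx
        lo, hi = (rx, ry) if rx < ry else (ry, rx)
        self.parent[hi] = lo
        return lo


def adjudicate(
    scored: pd.DataFrame,
    threshold: float,
    entity_map,
    records: pd.DataFrame,
):
    """Accept links above threshold, resolve multiplicity, veto conflicts.

    Links below the threshold are dropped.  Each ambulance record keeps at
    most one link (greatest weight, only if at least twice the next
    greatest), and symmetrically each hospital record.  A surviving link is
    then checked against the deterministic clusters of its endpoints: if
    the two clusters carry conflicting valid NHS numbers or conflicting
    valid dates of birth, the probabilistic link is disregarded.  Accepted
    links merge the clusters (merged id = smaller entity id; the two
    endpoint records get provenance 'P').

    Returns ``(accepted_links, new_entity_map)``.
    """
    from .deterministic import EntityMap

    surv = scored.loc[scored["weight"] >= threshold].copy()
    surv = _greatest_2x(surv, "amb_record_id")
    surv = _greatest_2x(surv, "hosp_record_id")
    surv = surv.sort_values(
        ["weight", "amb_record_id", "hosp_record_id"], ascending=[False, True, True]
    )

    ent_of = entity_map.assignments
    nhs_sets: dict = {}
    dob_sets: dict = {}
    for rid, nhs, dob in zip(
        records["record_id"], records["nhs_number"], records["dob"]
    ):
        eid = ent_of.get(rid)
        if eid is None:
            continue
        if isinstance(nhs, str):
            nhs_sets.setdefault(eid, set()).add(nhs)
        if pd.notna(dob):
            dob_sets.setdefault(eid, set()).add(pd.Timestamp(dob))

    uf = _UnionFind()
    accepted = []
    for row in surv.itertuples(index=False):
        ea = ent_of.get(row.amb_record_id)
        eb = ent_of.get(row.hosp_record_id)
        if ea is None or eb is None:
            continue
        ra, rb = uf.find(ea), uf.find(eb)
        if ra == rb:
            accepted.append(row)
            continue
        na, nb = nhs_sets.get(ra, set()), nhs_sets.get(rb, set())
        da, db = dob_sets.get(ra, set()), dob_sets.get(rb, set())
        if (na and nb and na.isdisjoint(nb)) or (da and db and da.isdisjoint(db)):
            continue  # transitivity conflict: disregard the probabilistic link
        root = uf.union(ra, rb)
        other = rb if root == ra else ra
        nhs_sets[root] = na | nb
        dob_sets[root] = da | db
        nhs_sets.pop(other, None)
        dob_sets.pop(other, None)
        accepted.append(row)

    links = pd.DataFrame(accepted, columns=list(surv.columns))
    if not links.empty:
        links = links[["amb_record_id", "hosp_record_id", "hosp_source", "weight"]]
    else:
        links = pd.DataFrame(
            columns=["amb_record_id", "hosp_record_id", "hosp_source", "weight"]
        )

    new_assignments = {rid: uf.find(eid) for rid, eid in ent_of.items()}
    new_prov = dict(entity_map.provenance)
    for row in links.itertuples(index=False):
        new_prov[row.amb_record_id] = "P"
        new_prov[row.hosp_record_id] = "P"
    return links, EntityMap(new_assignments, new_prov)


def plot_threshold_curve(curve: ThresholdCurve, ax=None, path=None):
    """Plot sensitivity/specificity/PPV/F-measure against the match-weight
    threshold, with the chosen threshold marked."""
    import matplotlib

    if ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    t = curve.table
    for colname, style in [
        ("sensitivity", "-"),
        ("specificity", "--"),
        ("ppv", "-."),
        ("f_measure", ":"),
    ]:
        ax.plot(t["threshold"], t[colname], style, label=colname)
    ax.axvline(curve.chosen_threshold, color="grey", lw=0.8)
    ax.annotate(
        f"chosen = {curve.chosen_threshold:.2f}",
        (curve.chosen_threshold, 0.02),
        rotation=90,
        fontsize=8,
        va="bottom",
    )
    ax.set_xlabel("match weight threshold")
    ax.set_ylabel("performance measure")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(loc="lower left", fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
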