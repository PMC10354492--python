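"""The analysis chain over tidy session logs.

Decision-level models are random-intercept logistic regressions (player and
set intercepts) with binary predictors entering as 0/1 indicators — so
coefficients exponentiate to odds ratios — and continuous predictors
(including the round control) z-scored, so Gaussian-model coefficients are
standardized betas.  Set-level analyses count behaviours and average trust
across the eight players of a set per round, with one-round-lagged
predictors, and a product-of-coefficients mediation decomposition
(below-threshold count -> number of stealers -> next-round trust) with
set-resampling bootstrap intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .glmm import DegenerateDataError, FitResult, fit_bayes_glmm


# ---------------------------------------------------------------------------
# standardization

@dataclass
class Scaler:
    """Affine (mean, sd) transforms used to z-score an analysis frame."""

    stats: dict[str, tuple[float, float]] = field(default_factory=dict)

    def inverse(self, frame: pd.DataFrame) -> pd.DataFrame:
        out = frame.copy()
        for col, (m, s) in self.stats.items():
            zcol = col + "_z"
            if zcol in out.columns:
                out[col] = out[zcol] * s + m
        return out


def standardize(frame: pd.DataFrame, continuous: Sequence[str],
                suffix: str = "_z") -> tuple[pd.DataFrame, Scaler]:
    """Z-score continuous columns over the analysis subset (new ``_z`` cols).

    Binary 0/1 indicators should *not* be passed here; they stay on their
    natural scale so logit effects exponentiate to odds ratios.  Raises
    :class:`DegenerateDataError` naming any zero-variance column.
    """
    out = frame.copy()
    scaler = Scaler()
    for col in continuous:
        v = out[col].to_numpy(dtype=float)
        m, s = float(np.mean(v)), float(np.std(v))
        if s == 0.0:
            raise DegenerateDataError(f"column {col!r} has zero variance")
        out[col + suffix] = (v - m) / s
        scaler.stats[col] = (m, s)
    return out, scaler


# ---------------------------------------------------------------------------
# frames

def decision_frame(dataset: pd.DataFrame, threshold_level: int) -> pd.DataFrame:
    """Real-round decision-level model frame with standard indicator columns.

    ``below`` is evaluated on ``points_before`` — the state the player saw
    when deciding (payout accounting, by contrast, uses the post-round
    level).  Adds ``steal``, ``cooperate``, ``below``, ``threshold``,
    ``harsh``, ``unequal`` indicators, the interaction products used by the
    prediction suites, and z-scored ``round_z`` and ``trust_z``.
    """
    d = dataset[dataset["round_index"] >= 1].copy()
    if d.empty:
        raise DegenerateDataError("no real rounds in dataset")
    d["steal"] = (d["action"] == "steal").astype(int)
    d["cooperate"] = (d["action"] == "cooperate").astype(int)
    d["below"] = (d["points_before"] < threshold_level).astype(int)
    d["threshold"] = d["threshold_active"].astype(bool).astype(int)
    d["harsh"] = (d["punishment_level"] == "harsh").astype(int)
    d["unequal"] = (d["inequality_condition"] == "unequal").astype(int)
    d["below_x_threshold"] = d["below"] * d["threshold"]
    d["harsh_x_threshold"] = d["harsh"] * d["threshold"]
    d["unequal_x_threshold"] = d["unequal"] * d["threshold"]
    d, _ = standardize(d, ["round_index"])
    d = d.rename(columns={"round_index_z": "round_z"})
    if d["trust_rating"].std() > 0:
        d["trust_z"] = ((d["trust_rating"] - d["trust_rating"].mean())
                        / d["trust_rating"].std(ddof=0))
    return d


def first_k_rounds(dataset: pd.DataFrame, k: int = 4) -> pd.DataFrame:
    """Rows of real rounds 1..k (mock rounds are never included)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return dataset[(dataset["round_index"] >= 1)
                   & (dataset["round_index"] <= k)].copy()


# ---------------------------------------------------------------------------
# descriptive contingency table

@dataclass
class StealTable:
    counts: pd.DataFrame      # rows: below in {0,1}; cols: steal / not / rate / se
    odds_ratio: Optional[float]
    flagged: Optional[str] = None


def tabulate_steal_by_threshold(dataset: pd.DataFrame, threshold_level: int,
                                stratify_by: Optional[str] = None):
    """2x2 steal-attempt counts by current below-threshold status.

    The cross-product odds ratio is undefined (flagged) when any cell is
    empty.  With ``stratify_by`` set, returns a dict of tables per stratum.
    """
    d = decision_frame(dataset, threshold_level)
    if stratify_by is not None:
        return {
            level: _steal_table(sub)
            for level, sub in d.groupby(stratify_by)
        }
    return _steal_table(d)


def _steal_table(d: pd.DataFrame) -> StealTable:
    rows = []
    cells = {}
    for below in (0, 1):
        sub = d[d["below"] == below]
        n_steal = int(sub["steal"].sum())
        n_not = int(len(sub) - n_steal)
        n = n_steal + n_not
        rate = n_steal / n if n else np.nan
        se = np.sqrt(rate * (1 - rate) / n) if n else np.nan
        rows.append({"below": below, "steal": n_steal, "not_steal": n_not,
                     "rate": rate, "se": se})
        cells[below] = (n_steal, n_not)
    counts = pd.DataFrame(rows).set_index("below")
    (a0, b0), (a1, b1) = cells[0], cells[1]
    if min(a0, b0, a1, b1) == 0:
        return StealTable(counts, None,
                          flagged="odds ratio undefined: empty cell")
    return StealTable(counts, (a1 * b0) / (b1 * a0))


# ---------------------------------------------------------------------------
# simple effects

def simple_effects(frame: pd.DataFrame, outcome: str, factor_a: str,
                   factor_b: str, covariates: Sequence[str] = ("round_z",),
                   groups: Sequence[str] = ("player_id", "set_id"),
                   family: str = "binomial",
                   prior_sd: float = 1.0) -> dict:
    """Decompose a two-way interaction into per-stratum effects of A.

    Fits the full model ``outcome ~ A + B + A:B + covariates`` and, within
    each stratum of the binary factor B, ``outcome ~ A + covariates``.
    Returns ``{"interaction": FitResult, "strata": {level: FitResult}}``.
    Empty or outcome-degenerate strata raise :class:`DegenerateDataError`.
    """
    inter_col = f"{factor_a}_x_{factor_b}"
    work = frame.copy()
    if inter_col not in work.columns:
        work[inter_col] = work[factor_a] * work[factor_b]
    full = fit_bayes_glmm(work, outcome,
                          [factor_a, factor_b, inter_col, *covariates],
                          groups=groups, family=family, prior_sd=prior_sd)
    strata: dict = {}
    for level in (0, 1):
        sub = work[work[factor_b] == level]
        if sub.empty:
            raise DegenerateDataError(
                f"stratum {factor_b}={level} is empty")
        strata[level] = fit_bayes_glmm(
            sub, outcome, [factor_a, *covariates], groups=groups,
            family=family, prior_sd=prior_sd)
    return {"interaction": full, "strata": strata}


# ---------------------------------------------------------------------------
# set-level frame and mediation

def build_set_level(dataset: pd.DataFrame) -> pd.DataFrame:
    """Per set x real round: mean trust, steal-attempt count, below count.

    ``n_stealers`` counts attempts, not successes.  One-round-lag columns
    (``*_lag``) carry the previous round's predictors; they are missing for
    each set's first real round.  Set-constant condition indicators
    (``threshold``, ``unequal``) are carried along for between-set designs.
    """
    d = dataset[dataset["round_index"] >= 1].copy()
    d["_steal"] = (d["action"] == "steal").astype(int)
    d["_unequal"] = (d["inequality_condition"] == "unequal").astype(float)
    d["_below"] = d["below_threshold_flag"].astype(int)
    d["_thr"] = d["threshold_active"].astype(float)
    g = d.groupby(["set_id", "round_index"])
    frame = g.agg(
        mean_trust=("trust_rating", "mean"),
        n_stealers=("_steal", "sum"),
        n_below=("_below", "sum"),
        threshold=("_thr", "mean"),
        unequal=("_unequal", "mean"),
    ).reset_index()
    frame = frame.sort_values(["set_id", "round_index"]).reset_index(drop=True)
    for col in ("n_stealers", "n_below"):
        frame[col + "_lag"] = frame.groupby("set_id")[col].shift(1)
    return frame


@dataclass
class MediationResult:
    a: float                    # below_lag -> stealers_lag (standardized)
    b: float                    # stealers_lag -> trust, adjusting below_lag
    direct: float               # below_lag -> trust, adjusting stealers_lag
    total: float                # below_lag -> trust
    indirect: float             # a * b
    proportion_of_total: Optional[float]       # indirect / total
    proportion_ab_direct: Optional[float]      # indirect / (indirect + direct)
    proportion_flagged: bool
    ci: dict[str, tuple[float, float]]
    n_bootstrap: int
    n_obs: int


def _mediation_paths(frame: pd.DataFrame, prior_sd: float) -> dict[str, float]:
    z, _ = standardize(frame, ["mean_trust", "n_stealers_lag", "n_below_lag",
                               "round_index"])
    fit_a = fit_bayes_glmm(z, "n_stealers_lag_z",
                           ["n_below_lag_z", "round_index_z"],
                           groups=["set_id"], family="gaussian",
                           prior_sd=prior_sd)
    fit_b = fit_bayes_glmm(z, "mean_trust_z",
                           ["n_stealers_lag_z", "n_below_lag_z",
                            "round_index_z"],
                           groups=["set_id"], family="gaussian",
                           prior_sd=prior_sd)
    fit_t = fit_bayes_glmm(z, "mean_trust_z",
                           ["n_below_lag_z", "round_index_z"],
                           groups=["set_id"], family="gaussian",
                           prior_sd=prior_sd)
    return {
        "a": fit_a["n_below_lag_z"].estimate,
        "b": fit_b["n_stealers_lag_z"].estimate,
        "direct": fit_b["n_below_lag_z"].estimate,
        "total": fit_t["n_below_lag_z"].estimate,
        "_fits": (fit_a, fit_b, fit_t),
    }


def mediation_analysis(set_frame: pd.DataFrame, n_bootstrap: int = 1000,
                       rng: Optional[np.random.Generator] = None,
                       prior_sd: float = 1.0) -> MediationResult:
    """Lagged set-level mediation: below count -> stealers -> next-round trust.

    All three standardized models carry set random intercepts and the round
    control.  The indirect effect is the product of the two paths; the
    proportion mediated is reported both against the total effect and against
    indirect + direct (the two constructions differ whenever direct + indirect
    != total, which mode-based fits do not guarantee).  Intervals come from a
    set-resampling bootstrap.
    """
    rng = rng if rng is not None else np.random.default_rng()
    work = set_frame.dropna(subset=["n_stealers_lag", "n_below_lag"]).copy()
    set_ids = work["set_id"].unique()
    if len(set_ids) < 2:
        raise DegenerateDataError("mediation requires at least 2 sets")
    if work.groupby("set_id")["round_index"].nunique().min() < 2:
        raise DegenerateDataError(
            "mediation requires >= 2 usable lagged rounds per set")

    paths = _mediation_paths(work, prior_sd)
    a, b, direct, total = paths["a"], paths["b"], paths["direct"], paths["total"]
    indirect = a * b

    draws = {k: [] for k in ("a", "b", "direct", "total", "indirect",
                             "proportion_of_total")}
    by_set = {s: work[work["set_id"] == s] for s in set_ids}
    for _ in range(n_bootstrap):
        chosen = rng.choice(set_ids, size=len(set_ids), replace=True)
        parts = []
        for new_id, s in enumerate(chosen):
            part = by_set[s].copy()
            part["set_id"] = new_id  # relabel so repeats stay distinct clusters
            parts.append(part)
        boot = pd.concat(parts, ignore_index=True)
        try:
            bp = _mediation_paths(boot, prior_sd)
        except DegenerateDataError:
            continue
        bi = bp["a"] * bp["b"]
        draws["a"].append(bp["a"])
        draws["b"].append(bp["b"])
        draws["direct"].append(bp["direct"])
        draws["total"].append(bp["total"])
        draws["indirect"].append(bi)
        if bp["total"] != 0:
            draws["proportion_of_total"].append(bi / bp["total"])
    ci = {
        k: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
        for k, v in draws.items() if len(v) > 0
    }

    same_sign = (np.sign(indirect) == np.sign(total)) and total != 0
    prop_total = indirect / total if total != 0 else None
    denom = indirect + direct
    prop_ab = indirect / denom if denom != 0 else None
    return MediationResult(
        a=a, b=b, direct=direct, total=total, indirect=indirect,
        proportion_of_total=prop_total, proportion_ab_direct=prop_ab,
        proportion_flagged=not same_sign, ci=ci,
        n_bootstrap=n_bootstrap, n_obs=len(work),
    )


# ---------------------------------------------------------------------------
# prediction suites

def _row(prediction: str, subset: str, fit: FitResult, term: str) -> dict:
    t = fit[term]
    return {
        "prediction": prediction, "subset": subset, "term": term,
        "estimate": t.estimate, "sd": t.sd,
        "ci_low": t.ci_low, "ci_high": t.ci_high, "or_": t.or_,
        "bf": t.bf, "bf_display": t.bf_display, "category": t.category,
        "n_obs": fit.n_obs,
    }


_ID_GROUPS = ("player_id", "set_id")


def _suite_individual_trust(d: pd.DataFrame, pid: str, rows: list,
                            subset: str = "all_rounds") -> None:
    nonsteal = d[d["steal"] == 0]
    fit = fit_bayes_glmm(nonsteal, "cooperate", ["trust_z", "round_z"],
                         groups=_ID_GROUPS)
    rows.append(_row(pid, subset, fit, "trust_z"))


def _suite_interaction(d: pd.DataFrame, pid: str, rows: list,
                       subset: str = "all_rounds") -> None:
    se = simple_effects(d, "steal", "below", "threshold")
    rows.append(_row(pid, subset, se["interaction"], "below_x_threshold"))
    rows.append(_row(f"{pid}_below_in_threshold", subset,
                     se["strata"][1], "below"))
    rows.append(_row(f"{pid}_below_in_no_threshold", subset,
                     se["strata"][0], "below"))


def _set_level_fit(sl: pd.DataFrame, outcome_terms: Sequence[str],
                   subset_mask=None) -> FitResult:
    work = sl.dropna(subset=["n_stealers_lag", "n_below_lag"])
    if subset_mask is not None:
        work = work[subset_mask(work)]
    z, _ = standardize(work, ["mean_trust", "n_stealers_lag", "n_below_lag",
                              "round_index"])
    return fit_bayes_glmm(z, "mean_trust_z",
                          [*outcome_terms, "round_index_z"],
                          groups=["set_id"], family="gaussian")


def run_prediction_suite(study: int, dataset: pd.DataFrame,
                         threshold_level: Optional[int] = None,
                         n_bootstrap: int = 200,
                         rng: Optional[np.random.Generator] = None
                         ) -> tuple[pd.DataFrame, dict]:
    """Run the registered pre-registered-prediction models for one study.

    Returns ``(table, extras)`` where ``table`` has one row per prediction
    (estimate, CI, OR, BF, evidence category) and ``extras`` carries
    structured objects (the mediation decomposition for study 1).  For study
    4, every prediction is run on all rounds and again on the first four
    rounds only.
    """
    from .config import study_config
    if threshold_level is None:
        threshold_level = study_config(study)[0].threshold_level
    rng = rng if rng is not None else np.random.default_rng(0)
    d = decision_frame(dataset, threshold_level)
    rows: list[dict] = []
    extras: dict = {}

    if study == 1:
        fit = fit_bayes_glmm(d, "steal", ["below", "round_z"],
                             groups=_ID_GROUPS)
        rows.append(_row("P1.1", "all_rounds", fit, "below"))
        sl = build_set_level(dataset)
        fit2 = _set_level_fit(sl, ["n_below_lag_z"])
        rows.append(_row("P1.2", "all_rounds", fit2, "n_below_lag_z"))
        med = mediation_analysis(sl, n_bootstrap=n_bootstrap, rng=rng)
        extras["mediation"] = med
        for name, val in (("P1.2_path_a", med.a), ("P1.2_path_b", med.b),
                          ("P1.2_indirect", med.indirect)):
            ci = med.ci.get(name.split("P1.2_")[-1].replace("path_", ""),
                            (np.nan, np.nan))
            rows.append({"prediction": name, "subset": "all_rounds",
                         "term": name, "estimate": val, "sd": np.nan,
                         "ci_low": ci[0], "ci_high": ci[1], "or_": None,
                         "bf": np.nan, "bf_display": "", "category": "",
                         "n_obs": med.n_obs})
        _suite_individual_trust(d, "P1.3", rows)
    elif study == 2:
        _suite_interaction(d, "P2.1", rows)
        sl = build_set_level(dataset)
        fit2 = _set_level_fit(sl, ["n_stealers_lag_z"])
        rows.append(_row("P2.2", "all_rounds", fit2, "n_stealers_lag_z"))
        _suite_individual_trust(d, "P2.3", rows)
    elif study == 3:
        below = d[d["below"] == 1]
        se = simple_effects(below, "steal", "harsh", "threshold")
        rows.append(_row("P3.1", "all_rounds", se["interaction"],
                         "harsh_x_threshold"))
        rows.append(_row("P3.1_harsh_in_threshold", "all_rounds",
                         se["strata"][1], "harsh"))
        rows.append(_row("P3.1_harsh_in_no_threshold", "all_rounds",
                         se["strata"][0], "harsh"))
        overall = fit_bayes_glmm(below, "steal",
                                 ["harsh", "threshold", "round_z"],
                                 groups=_ID_GROUPS)
        rows.append(_row("P3.1_harsh_overall", "all_rounds", overall, "harsh"))
        _suite_interaction(d, "P3.7", rows)
        _suite_individual_trust(d, "P3.8", rows)
    elif study == 4:
        for subset, data in (("all_rounds", dataset),
                             ("first_4", first_k_rounds(dataset, 4))):
            dd = decision_frame(data, threshold_level)
            thr = dd[dd["threshold"] == 1]
            fit = fit_bayes_glmm(thr, "steal", ["unequal", "round_z"],
                                 groups=_ID_GROUPS)
            rows.append(_row("P4.1", subset, fit, "unequal"))
            sl = build_set_level(data)
            slz, _ = standardize(sl, ["mean_trust", "round_index"])
            thr_sets = slz[slz["threshold"] == 1]
            fit2 = fit_bayes_glmm(thr_sets, "mean_trust_z",
                                  ["unequal", "round_index_z"],
                                  groups=["set_id"], family="gaussian")
            rows.append(_row("P4.2", subset, fit2, "unequal"))
            fit3 = fit_bayes_glmm(thr, "cooperate", ["unequal", "round_z"],
                                  groups=_ID_GROUPS)
            rows.append(_row("P4.3", subset, fit3, "unequal"))
            se = simple_effects(dd, "steal", "unequal", "threshold")
            rows.append(_row("P4.4", subset, se["interaction"],
                             "unequal_x_threshold"))
            fit5 = fit_bayes_glmm(
                slz.assign(unequal_x_threshold=slz["unequal"] * slz["threshold"]),
                "mean_trust_z",
                ["unequal", "threshold", "unequal_x_threshold", "round_index_z"],
                groups=["set_id"], family="gaussian")
            rows.append(_row("P4.5", subset, fit5, "unequal_x_threshold"))
            se6 = simple_effects(dd, "cooperate", "unequal", "threshold")
            rows.append(_row("P4.6", subset, se6["interaction"],
                             "unequal_x_threshold"))
        _suite_interaction(d, "P4.7_replication", rows)
    else:
        raise ValueError(f"unknown study id {study!r}")

    return pd.DataFrame(rows), extras
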