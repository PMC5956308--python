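"""Cohort-level statistics: group comparisons, ROC separation, classifiers.

The clinical question is whether the six participant-level capillaroscopy
parameters separate systemic sclerosis (SSc) from primary Raynaud's (PRP)
and healthy controls (HC).  Following standard practice for this design:

* per-parameter one-way ANOVA with Tukey's range test (Tukey-Kramer for
  unequal group sizes) for pairwise group differences;
* the area under the ROC curve (A_Z) for SSc versus the pooled HC/PRP
  group, with the Hanley-McNeil standard error;
* a stepwise (bidirectional, information-criterion) logistic regression
  combining parameters, evaluated by leave-one-out cross-validation (LOOCV)
  in which the entire selection + fit procedure is re-run on each training
  fold so the out-of-fold predicted probabilities are unbiased.

Logistic fits use a compact Newton/IRLS solver (cross-checked against
statsmodels in the test suite) because LOOCV with nested selection requires
tens of thousands of small fits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import InvalidInputError, SchemaError
from .morphometry import PARAMETERS

GROUPS = ("HC", "PRP", "SSc")
#: parameters entering the structure-only classifier (density, widths, shape,
#: derangement); the full model adds flow
STRUCTURE_PARAMETERS = PARAMETERS[:5]

#: Tukey pairwise contrasts and their table-footnote symbols
PAIRS = ((("PRP", "HC"), "#"), (("SSc", "HC"), "†"), (("SSc", "PRP"), "‡"))


# ---------------------------------------------------------------------------
# cohort table
# ---------------------------------------------------------------------------

@dataclass
class CohortTable:
    """Participant-level parameter table with validated schema.

    Rows are subjects; columns are ``subject_id``, ``group`` and the six
    parameters.  Rows are kept sorted by subject id so every downstream
    computation is invariant to input row order.
    """

    df: pd.DataFrame

    def __post_init__(self):
        required = {"subject_id", "group", *PARAMETERS}
        missing = required - set(self.df.columns)
        if missing:
            raise SchemaError(f"cohort table missing columns: {sorted(missing)}")
        bad = set(self.df["group"]) - set(GROUPS)
        if bad:
            raise SchemaError(f"unknown group labels: {sorted(bad)}")
        if self.df["subject_id"].duplicated().any():
            raise SchemaError("duplicated subject_id")
        self.df = (
            self.df.sort_values("subject_id", kind="mergesort")
            .reset_index(drop=True)
        )

    @classmethod
    def from_records(cls, records) -> "CohortTable":
        rows = []
        for rec in records:
            row = {"subject_id": rec.subject_id, "group": rec.group}
            row.update(rec.participant_params)
            rows.append(row)
        return cls(pd.DataFrame(rows))

    def labels(self) -> np.ndarray:
        """Binary outcome: SSc positive, pooled HC/PRP negative."""
        return (self.df["group"] == "SSc").to_numpy(dtype=int)

    def __len__(self):
        return len(self.df)


# ---------------------------------------------------------------------------
# ANOVA + Tukey
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    parameter: str
    f_statistic: float
    p_value: float
    pairwise_significant: dict  # ("SSc","HC") -> bool
    pairwise_p: dict
    alpha: float


def anova_tukey(table: CohortTable, parameter: str, alpha: float = 0.05) -> AnovaResult:
    """One-way ANOVA plus Tukey-Kramer pairwise tests for one parameter."""
    if parameter not in PARAMETERS:
        raise SchemaError(f"unknown parameter {parameter!r}")
    groups, names = [], []
    for g in GROUPS:
        vals = table.df.loc[table.df["group"] == g, parameter].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals):
            groups.append(vals)
            names.append(g)
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise InvalidInputError("each present group needs >= 2 subjects")

    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb = len(groups) - 1
    dfw = sum(len(g) for g in groups) - len(groups)
    if ssb <= 1e-300:
        f_stat, p = 0.0, 1.0
    elif ssw <= 1e-300:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = (ssb / dfb) / (ssw / dfw)
        p = float(sps.f.sf(f_stat, dfb, dfw))

    sig, pvals = {}, {}
    if ssw > 1e-300:
        tk = sps.tukey_hsd(*groups)
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                pv = float(tk.pvalue[i, j])
                key = (names[j], names[i])  # GROUPS order makes this canonical
                pvals[key] = pv
                sig[key] = pv < alpha
    else:
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                key = (names[j], names[i])
                differ = abs(groups[i].mean() - groups[j].mean()) > 0
                pvals[key] = 0.0 if differ else 1.0
                sig[key] = differ
    return AnovaResult(parameter, float(f_stat), float(p), sig, pvals, alpha)


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    auc: float
    se: float
    curve: tuple     # (fpr, tpr) arrays
    n_pos: int
    n_neg: int
    flipped: bool = False  # True if auto-orientation negated the scores


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Standard error of the ROC area (Hanley & McNeil, binormal-free)."""
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc ** 2 / (1.0 + auc)
    var = (auc * (1 - auc) + (n_pos - 1) * (q1 - auc ** 2)
           + (n_neg - 1) * (q2 - auc ** 2)) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def roc_auc(scores, labels, direction: str = "auto") -> RocResult:
    """ROC area for binary labels with half-credit tie handling.

    The AUC is computed by the rank (Mann-Whitney) formulation, equal to
    P(score_pos > score_neg) + 0.5 P(tie).  ``direction`` "auto" negates the
    scores when the raw AUC is below 0.5 (recorded in ``flipped``);
    "greater" / "less" fix the orientation, as needed for cross-validated
    probabilities whose orientation is part of the estimate.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise InvalidInputError("scores and labels must have equal length")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise InvalidInputError("both classes must be present")
    if direction not in ("auto", "greater", "less"):
        raise InvalidInputError(f"bad direction {direction!r}")

    def _auc(s):
        ranks = sps.rankdata(s)
        return (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    flipped = False
    if direction == "less":
        scores, flipped = -scores, True
    auc = _auc(scores)
    if direction == "auto" and auc < 0.5:
        scores, auc, flipped = -scores, 1.0 - auc, True
    fpr, tpr, _ = _sk_roc_curve(labels, scores)
    return RocResult(
        auc=float(auc),
        se=hanley_mcneil_se(float(auc), n_pos, n_neg),
        curve=(fpr, tpr),
        n_pos=n_pos,
        n_neg=n_neg,
        flipped=flipped,
    )


# ---------------------------------------------------------------------------
# logistic regression (Newton/IRLS) and stepwise selection
# ---------------------------------------------------------------------------

def _logit_fit(X, y, ridge=1e-6, max_iter=40, tol=1e-10):
    """Maximum-likelihood logistic fit with a tiny ridge for stability.

    Returns (beta, loglik, converged, separated).  ``separated`` flags
    quasi-complete separation (diverging coefficients).
    """
    n, p = X.shape
    beta = np.zeros(p)
    ll_old = -np.inf
    separated = False
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        ll = float(y @ eta - np.logaddexp(0.0, eta).sum()) - 0.5 * ridge * beta @ beta
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        grad = X.T @ (y - mu) - ridge * beta
        H = (X.T * w) @ X + ridge * np.eye(p)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # halve the step until the penalised likelihood does not decrease
        t = 1.0
        for _ in range(20):
            cand = beta + t * step
            eta_c = np.clip(X @ cand, -35, 35)
            ll_c = float(y @ eta_c - np.logaddexp(0.0, eta_c).sum()) - 0.5 * ridge * cand @ cand
            if ll_c >= ll - 1e-12:
                break
            t *= 0.5
        beta = beta + t * step
        if np.abs(beta).max() > 60.0:
            separated = True
        if abs(ll_c - ll_old) < tol * (1.0 + abs(ll_c)):
            converged = True
            break
        ll_old = ll_c
    eta = np.clip(X @ beta, -35, 35)
    ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
    return beta, ll, converged, separated


@dataclass
class ModelFit:
    """Stepwise-selected logistic classifier (optionally LOOCV-evaluated)."""

    selected_terms: list
    coefficients: dict          # original-scale slopes, term -> float
    intercept: float
    flags: list = field(default_factory=list)
    loocv_scores: np.ndarray | None = None   # per-subject out-of-fold P(SSc)
    combined_roc: RocResult | None = None
    # standardised-space fit used for prediction
    _beta_std: np.ndarray | None = None
    _means: np.ndarray | None = None
    _stds: np.ndarray | None = None

    def predict_proba(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Z = (X - self._means) / self._stds
        cols = [0] + [1 + i for i in self._sel_idx]
        design = np.column_stack([np.ones(len(Z)), Z])[:, cols]
        eta = np.clip(design @ self._beta_std, -35, 35)
        return 1.0 / (1.0 + np.exp(-eta))


def _design(table_df, candidates):
    X = table_df[list(candidates)].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise InvalidInputError("candidate columns contain non-finite values")
    return X


def stepwise_logistic(table, candidates, labels=None, ridge=1e-6,
                      criterion: str = "bic") -> ModelFit:
    """Bidirectional stepwise logistic regression.

    Starts from the full main-effects model and repeatedly applies the
    single add/drop move that most lowers the information criterion, until
    no move improves it.  The default criterion is BIC: with the ~100
    subjects typical here, AIC's per-term penalty of 2 admits a pure-noise
    parameter about one time in six, which is enough to push leave-one-out
    ROC areas on null data well below 0.5 (overfitted folds anti-predict
    their held-out subject); BIC's log(n) penalty keeps null selections
    empty and the cross-validated null ROC centred on 0.5.  Pass
    ``criterion="aic"`` for the classical choice.

    Inputs are z-scored internally for numerical stability; reported
    coefficients are on the original scale.  Quasi-separated final fits are
    refit with a unit-ridge penalty and flagged ``"penalized"``.
    """
    candidates = list(candidates)
    if len(candidates) < 2:
        raise InvalidInputError("need >= 2 candidate parameters")
    df = table.df if isinstance(table, CohortTable) else table
    y = np.asarray(table.labels() if labels is None and isinstance(table, CohortTable)
                   else labels, dtype=float)
    X = _design(df, candidates)
    stds = X.std(axis=0, ddof=0)
    if np.any(stds <= 0):
        bad = [c for c, s in zip(candidates, stds) if s <= 0]
        raise InvalidInputError(f"constant candidate columns: {bad}")
    means = X.mean(axis=0)
    Z = (X - means) / stds
    ones = np.ones((len(Z), 1))
    if criterion not in ("aic", "bic"):
        raise InvalidInputError(f"unknown criterion {criterion!r}")
    penalty = 2.0 if criterion == "aic" else float(np.log(len(Z)))
    cache = {}

    def fit_subset(idx):
        key = tuple(idx)
        if key not in cache:
            design = np.hstack([ones, Z[:, idx]]) if idx else ones
            beta, ll, _, sep = _logit_fit(design, y, ridge=ridge)
            cache[key] = (beta, penalty * (len(idx) + 1) - 2.0 * ll, sep)
        return cache[key]

    current = list(range(len(candidates)))
    _, best_aic, _ = fit_subset(current)
    for _ in range(8 * len(candidates)):
        moves = []
        for i in current:
            trial = [j for j in current if j != i]
            moves.append((trial, fit_subset(trial)[1]))
        for i in range(len(candidates)):
            if i not in current:
                trial = sorted(current + [i])
                moves.append((trial, fit_subset(trial)[1]))
        if not moves:
            break
        trial, aic = min(moves, key=lambda m: (m[1], len(m[0])))
        if aic < best_aic - 1e-9:
            current, best_aic = trial, aic
        else:
            break

    flags = []
    design = np.hstack([ones, Z[:, current]]) if current else ones
    beta, ll, _, sep = _logit_fit(design, y, ridge=ridge)
    if sep:
        beta, ll, _, _ = _logit_fit(design, y, ridge=1.0)
        flags.append("penalized")

    sel_names = [candidates[i] for i in current]
    slopes = {
        name: float(beta[k + 1] / stds[i])
        for k, (i, name) in enumerate(zip(current, sel_names))
    }
    intercept = float(beta[0] - sum(
        beta[k + 1] * means[i] / stds[i] for k, i in enumerate(current)
    ))
    fit = ModelFit(
        selected_terms=sel_names,
        coefficients=slopes,
        intercept=intercept,
        flags=flags,
        _beta_std=beta,
        _means=means,
        _stds=stds,
    )
    fit._sel_idx = current
    fit._candidates = candidates
    return fit


def loocv_roc(table: CohortTable, candidates, labels=None, min_n=10,
              criterion: str = "bic") -> ModelFit:
    """Leave-one-out CV of the full stepwise + fit procedure.

    For every subject the entire selection and fit is re-run on the other
    n - 1 subjects and the held-out subject's P(SSc) recorded; the combined
    ROC is computed on these out-of-fold scores with fixed orientation.
    Folds whose training set has a single class are skipped and flagged.
    """
    df = table.df
    y = table.labels() if labels is None else np.asarray(labels, dtype=int)
    n = len(df)
    if n < min_n:
        raise InvalidInputError(f"LOOCV requires n >= {min_n} (got {n})")
    scores = np.full(n, np.nan)
    flags = []
    for i in range(n):
        keep = np.arange(n) != i
        y_tr = y[keep]
        if y_tr.min() == y_tr.max():
            flags.append(f"fold {i}: single-class training set, skipped")
            continue
        sub = df.iloc[keep]
        fit_i = stepwise_logistic(sub, candidates, labels=y_tr, criterion=criterion)
        if not fit_i.selected_terms:
            # an intercept-only model carries no subject-level information;
            # scoring it by the training prevalence would leak the held-out
            # label (the prevalence is lower exactly when the held-out
            # subject is positive), so emit the uninformative 0.5
            scores[i] = 0.5
        else:
            scores[i] = float(fit_i.predict_proba(
                df.iloc[[i]][list(candidates)].to_numpy(dtype=float)
            )[0])
    ok = np.isfinite(scores)
    combined = roc_auc(scores[ok], y[ok], direction="greater")
    fit = stepwise_logistic(df, candidates, labels=y, criterion=criterion)
    fit.flags.extend(flags)
    fit.loocv_scores = scores
    fit.combined_roc = combined
    return fit


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

@dataclass
class CohortReport:
    """Per-parameter group summaries plus single and combined ROC results."""

    parameters: dict       # name -> {group means/se/n, flags, auc, auc_se}
    combined: dict         # "structure" / "structure_flow" -> model summary
    alpha: float
    n_subjects: int

    def to_json(self, **kwargs) -> str:
        def clean(o):
            if isinstance(o, dict):
                return {str(k): clean(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [clean(v) for v in o]
            if isinstance(o, (np.floating, float)):
                return None if not np.isfinite(o) else float(o)
            if isinstance(o, (np.integer, int)):
                return int(o)
            return o
        payload = {
            "n_subjects": self.n_subjects,
            "alpha": self.alpha,
            "parameters": clean(self.parameters),
            "combined": clean(self.combined),
        }
        kwargs.setdefault("sort_keys", True)
        kwargs.setdefault("indent", 2)
        return json.dumps(payload, **kwargs)

    def to_dataframe(self) -> pd.DataFrame:
        """Rows per parameter with group means +/- SE and ROC area."""
        rows = []
        for name in PARAMETERS:
            p = self.parameters[name]
            row = {"parameter": name}
            for g in GROUPS:
                if g in p["groups"]:
                    gg = p["groups"][g]
                    row[g] = f"{gg['mean']:.3g} ± {gg['se']:.2g}"
                else:
                    row[g] = ""
            row["pairwise"] = "".join(sym for pair, sym in PAIRS
                                      if p["pairwise_significant"].get(pair, False))
            row["roc_az"] = f"{p['auc']:.3f} ± {p['auc_se']:.3f}"
            rows.append(row)
        for key, label in (("structure", "Combined structure parameters"),
                           ("structure_flow", "Structure and flow parameters")):
            m = self.combined[key]
            rows.append({
                "parameter": label, "HC": "", "PRP": "", "SSc": "", "pairwise": "",
                "roc_az": f"{m['auc']:.3f} ± {m['auc_se']:.3f}",
            })
        return pd.DataFrame(rows)


def cohort_report(table: CohortTable, alpha: float = 0.05,
                  loocv_min_n: int = 10) -> CohortReport:
    """Full cohort analysis mirroring the per-parameter summary table.

    Deterministic in the table contents (row order does not matter).  The
    combined models are LOOCV-evaluated when the cohort has at least
    ``loocv_min_n`` subjects; smaller cohorts fall back to a resubstitution
    ROC, flagged ``"validation": "resubstitution"``.
    """
    df = table.df
    y = table.labels()
    params = {}
    for name in PARAMETERS:
        res = anova_tukey(table, name, alpha=alpha)
        vals = df[name].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        roc = roc_auc(vals[ok], y[ok], direction="auto")
        groups = {}
        for g in GROUPS:
            gv = df.loc[df["group"] == g, name].to_numpy(dtype=float)
            gv = gv[np.isfinite(gv)]
            if len(gv):
                groups[g] = {
                    "mean": float(gv.mean()),
                    "se": float(gv.std(ddof=1) / np.sqrt(len(gv))) if len(gv) > 1 else float("nan"),
                    "n": int(len(gv)),
                }
        params[name] = {
            "groups": groups,
            "f_statistic": res.f_statistic,
            "p_value": res.p_value,
            "pairwise_significant": res.pairwise_significant,
            "auc": roc.auc,
            "auc_se": roc.se,
            "auc_flipped": roc.flipped,
        }

    combined = {}
    for key, cand in (("structure", STRUCTURE_PARAMETERS),
                      ("structure_flow", PARAMETERS)):
        cand = [c for c in cand]
        if len(table) >= loocv_min_n:
            fit = loocv_roc(table, cand)
            roc = fit.combined_roc
            validation = "loocv"
        else:
            fit = stepwise_logistic(table, cand)
            scores = fit.predict_proba(df[cand].to_numpy(dtype=float))
            roc = roc_auc(scores, y, direction="greater")
            validation = "resubstitution"
        combined[key] = {
            "selected_terms": fit.selected_terms,
            "coefficients": fit.coefficients,
            "intercept": fit.intercept,
            "auc": roc.auc,
            "auc_se": roc.se,
            "validation": validation,
            "flags": fit.flags,
            "roc_curve": [list(map(float, roc.curve[0])), list(map(float, roc.curve[1]))],
        }
    return CohortReport(
        parameters=params, combined=combined, alpha=alpha, n_subjects=len(df)
    )


# ---------------------------------------------------------------------------
# synthetic cohort tables (statistics-level validation fixtures)
# ---------------------------------------------------------------------------

#: group means for table simulation, matching the population anchors used by
#: the phantom presets (density /mm, widths um, scores, flow mm/s)
TABLE_MEANS = {
    "HC": dict(density=6.73, mean_width=11.8, max_width=16.5, shape=0.312,
               derangement=0.649, flow=0.311),
    "PRP": dict(density=7.28, mean_width=12.7, max_width=21.4, shape=0.325,
                derangement=0.689, flow=0.383),
    "SSc": dict(density=5.52, mean_width=15.0, max_width=27.4, shape=0.249,
                derangement=0.540, flow=0.235),
}
#: between-subject SDs (population SE * sqrt(n) from the same source)
TABLE_SDS = {
    "HC": dict(density=2.40, mean_width=1.63, max_width=6.43, shape=0.141,
               derangement=0.212, flow=0.354),
    "PRP": dict(density=1.87, mean_width=2.56, max_width=10.2, shape=0.104,
                derangement=0.173, flow=0.346),
    "SSc": dict(density=2.97, mean_width=5.02, max_width=16.8, shape=0.071,
                derangement=0.212, flow=0.283),
}


def simulate_cohort_table(n_hc=50, n_prp=12, n_ssc=50, effect=1.0,
                          rng=None) -> CohortTable:
    """Draw a synthetic participant-level cohort table.

    Group means follow the population anchors; ``effect`` scales every
    group-mean difference from the pooled HC mean (0 gives a null cohort
    with no real group differences, 1 the anchored differences, larger
    values a strongly separated cohort).
    """
    rng = np.random.default_rng(0) if rng is None else rng
    base = TABLE_MEANS["HC"]
    rows = []
    sid = 0
    for g, n in (("HC", n_hc), ("PRP", n_prp), ("SSc", n_ssc)):
        for _ in range(n):
            row = {"subject_id": f"S{sid:04d}", "group": g}
            for p in PARAMETERS:
                mean = base[p] + effect * (TABLE_MEANS[g][p] - base[p])
                val = mean + TABLE_SDS[g][p] * rng.standard_normal()
                if p in ("density", "mean_width", "max_width", "flow"):
                    val = max(val, 0.05 * base[p])
                else:
                    val = float(np.clip(val, 0.001, 1.0))
                row[p] = val
            rows.append(row)
            sid += 1
    return CohortTable(pd.DataFrame(rows))


def null_cohort_table(n=100, rng=None) -> CohortTable:
    """Cohort with labels independent of every parameter (pure noise)."""
    rng = np.random.default_rng(0) if rng is None else rng
    rows = []
    for i in range(n):
        g = "SSc" if i % 2 else ("HC" if i % 4 == 0 else "PRP")
        row = {"subject_id": f"N{i:04d}", "group": g}
        for p in PARAMETERS:
            row[p] = rng.standard_normal()
        rows.append(row)
    return CohortTable(pd.DataFrame(rows))
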