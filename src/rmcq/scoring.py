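"""Subscale, domain and overall scores for the questionnaire.

Responses are first normalized to [0, 1] by q / (c - 1); non-scored and
missing responses stay absent and are simply dropped from the sums (a
subscale with no answered item receives no score).  Two subscale scores on a
0-10 scale are produced for every respondent and factor:

* the **sum score** (SS) — unweighted, using only the *sign* of each item's
  pattern loading,

      SS = 10 * ( sum_i sgn(w_i) q_i/(c_i - 1) / n  +  sum_i 1[w_i < 0] / n ),

* the **factor score** (FS) — loading-weighted,

      FS = 10 * ( sum_i w_i q_i/(c_i - 1) / sum_j |w_j|
                  + sum_i 1[w_i < 0] |w_i| / sum_j |w_j| ),

with n the number of answered items in the subscale.  The second (shift)
term in each restores the 0-10 range when a negative loading is present
while preserving the score distribution.

The overall score and the two domain scores (responsiveness, respectful
treatment) are percentages of ideal treatment,

      OS = 10 * sum_k s_k / N,

averaging the N subscales that received a score (a missing subscale reduces
N rather than zeroing the score).

By convention the factor score is the within-study quantity (it uses the
sample's own loadings) and the sum score is the cross-study comparison
quantity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import CleanMatrix, normalize_matrix
from .schema import DomainGrouping, FactorSpec, QuestionnaireSchema


@dataclass
class SubscaleScore:
    factor_name: str
    method: str  # "sum" | "factor"
    value: float | None  # in [0, 10]; None when no item answered
    n_answered: int


def _gather(responses: dict[str, float], spec: FactorSpec):
    """Split a spec into answered weights/values; unknown responses ignored."""
    w, q = [], []
    for iid, wi in spec.loadings:
        v = responses.get(iid)
        if v is not None and not (isinstance(v, float) and np.isnan(v)):
            w.append(wi)
            q.append(v)
    return np.asarray(w), np.asarray(q)


def sum_score(responses: dict[str, float], spec: FactorSpec) -> SubscaleScore:
    """Simple-summation subscale score (0-10); ``responses`` maps item id to
    the normalized value in [0, 1], absent/NaN meaning unanswered."""
    w, q = _gather(responses, spec)
    n = len(w)
    if n == 0:
        return SubscaleScore(spec.factor_name, "sum", None, 0)
    value = 10.0 * (np.sum(np.sign(w) * q) / n + np.sum(w < 0) / n)
    return SubscaleScore(spec.factor_name, "sum", float(value), n)


def factor_score(responses: dict[str, float], spec: FactorSpec) -> SubscaleScore:
    """Loading-weighted subscale score (0-10)."""
    w, q = _gather(responses, spec)
    n = len(w)
    if n == 0:
        return SubscaleScore(spec.factor_name, "factor", None, 0)
    denom = np.sum(np.abs(w))
    value = 10.0 * (np.sum(w * q) / denom + np.sum(np.abs(w[w < 0])) / denom)
    return SubscaleScore(spec.factor_name, "factor", float(value), n)


def overall_score(subscale_values) -> float | None:
    """Percentage of ideal treatment over the subscales that have a score."""
    vals = [v for v in subscale_values if v is not None and np.isfinite(v)]
    if not vals:
        return None
    return 10.0 * float(np.mean(vals))


def domain_scores(
    scores: dict[str, float | None], grouping: DomainGrouping
) -> tuple[float | None, float | None]:
    """Responsiveness and respectful-treatment percentages (each its own
    average over the relevant scored subscales)."""
    resp = overall_score(scores.get(f) for f in grouping.responsiveness_factors)
    respect = overall_score(scores.get(f) for f in grouping.respectful_factors)
    return resp, respect


def score_cohort(
    clean: CleanMatrix,
    schema: QuestionnaireSchema,
    specs: list[FactorSpec],
    grouping: DomainGrouping | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Score every respondent by both methods and summarize the cohort.

    Returns ``(table, summary)``: a per-respondent table with one SS and FS
    column per subscale, the domain percentages and the overall percentage
    for each method, plus a cohort summary of means and standard deviations
    (per-respondent scores averaged across the cohort).  Scores are kept
    unrounded; round only at serialization.
    """
    seen = set()
    for s in specs:
        dup = seen & set(s.item_ids)
        if dup:
            raise ValueError(f"items in several factor specs: {sorted(dup)}")
        seen |= set(s.item_ids)

    ncat = clean.n_categories(schema)
    norm = normalize_matrix(clean.scoring_values, ncat)
    col = {iid: j for j, iid in enumerate(clean.item_ids)}

    rows = []
    for i in range(clean.n):
        responses = {
            iid: norm[i, col[iid]]
            for iid in clean.item_ids
            if not np.isnan(norm[i, col[iid]])
        }
        row: dict[str, object] = {"respondent_id": clean.respondent_ids[i]}
        ss_vals: dict[str, float | None] = {}
        fs_vals: dict[str, float | None] = {}
        for spec in specs:
            ss = sum_score(responses, spec)
            fs = factor_score(responses, spec)
            ss_vals[spec.factor_name] = ss.value
            fs_vals[spec.factor_name] = fs.value
            row[f"SS:{spec.factor_name}"] = ss.value
            row[f"FS:{spec.factor_name}"] = fs.value
            row[f"n:{spec.factor_name}"] = ss.n_answered
        row["SS:overall_pct"] = overall_score(ss_vals.values())
        row["FS:overall_pct"] = overall_score(fs_vals.values())
        if grouping is not None:
            r, t = domain_scores(ss_vals, grouping)
            row["SS:responsiveness_pct"], row["SS:respectful_pct"] = r, t
            r, t = domain_scores(fs_vals, grouping)
            row["FS:responsiveness_pct"], row["FS:respectful_pct"] = r, t
        rows.append(row)
    table = pd.DataFrame(rows)

    summary: dict = {"n": clean.n, "subscales": {}, "composites": {}}
    for spec in specs:
        entry = {}
        for method in ("SS", "FS"):
            colname = f"{method}:{spec.factor_name}"
            vals = table[colname].dropna()
            entry[method.lower()] = {
                "mean": float(vals.mean()) if len(vals) else None,
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else None,
            }
        summary["subscales"][spec.factor_name] = entry
    composite_cols = ["overall_pct"]
    if grouping is not None:
        composite_cols = ["responsiveness_pct", "respectful_pct", "overall_pct"]
    for comp in composite_cols:
        entry = {}
        for method in ("SS", "FS"):
            vals = table[f"{method}:{comp}"].dropna()
            entry[method.lower()] = {
                "mean": float(vals.mean()) if len(vals) else None,
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else None,
            }
        summary["composites"][comp] = entry
    return table, summary
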