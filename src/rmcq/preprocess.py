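"""Data-management rules: screening, imputation, reverse coding, splitting.

The cleaning pipeline turns a raw respondent-by-item table of ordinal codes
into two parallel substrates:

* a *factor-analysis* matrix with no missing cells — respondents with more
  than ``max_missing`` missing items are removed, every remaining absent cell
  (missing, non-scored, or flagged for imputation) is replaced by the item's
  column median; and
* a *scoring* matrix in which non-scored responses and missing cells stay
  absent (scores must be computable without knowing population medians),
  while cells explicitly flagged MEDIAN_IMPUTE by a recode rule are imputed.

Reverse-coded items are flipped at matrix level before any other step so that
a higher code always means better treatment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import QuestionnaireSchema

#: reserved CSV token for a non-scored response
NS_TOKEN = "NS"
STRATA_COLUMNS = ("country", "hospital", "round")


@dataclass
class RawResponseMatrix:
    """Respondent x item table of raw ordinal codes plus sampling strata.

    ``values`` holds raw numeric codes as floats with NaN for missing cells;
    ``non_scored`` and ``impute`` are boolean masks for cells answered with a
    non-scored label or a label recoded to the column median.  Codes are in
    the administered orientation; reverse coding happens during cleaning.
    """

    respondent_ids: np.ndarray
    item_ids: list[str]
    values: np.ndarray
    non_scored: np.ndarray
    strata: pd.DataFrame
    impute: np.ndarray | None = None

    def __post_init__(self):
        if self.impute is None:
            self.impute = np.zeros_like(self.non_scored)

    @property
    def n(self) -> int:
        return len(self.respondent_ids)

    def validate(self, schema: QuestionnaireSchema) -> list[str]:
        errs = []
        for iid in self.item_ids:
            if iid not in schema:
                errs.append(f"item {iid!r} not in schema")
        for j, iid in enumerate(self.item_ids):
            if iid in schema:
                c = schema[iid].scale.n_scored_categories
                col = self.values[:, j]
                obs = col[~np.isnan(col)]
                if obs.size and (obs.min() < 0 or obs.max() > c - 1):
                    errs.append(f"item {iid!r}: codes outside 0..{c - 1}")
        return errs

    @classmethod
    def from_csv(cls, path, schema: QuestionnaireSchema) -> "RawResponseMatrix":
        """Read the wide CSV dialect: item columns + country,hospital,round;
        empty cell = missing, ``NS`` = non-scored."""
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing_strata = [c for c in STRATA_COLUMNS if c not in df.columns]
        if missing_strata:
            raise ValueError(f"CSV lacks strata columns {missing_strata}")
        item_cols = [c for c in df.columns if c not in STRATA_COLUMNS and c != "respondent_id"]
        n = len(df)
        values = np.full((n, len(item_cols)), np.nan)
        ns = np.zeros((n, len(item_cols)), dtype=bool)
        imp = np.zeros((n, len(item_cols)), dtype=bool)
        for j, col in enumerate(item_cols):
            raw = df[col].to_numpy()
            for i, cell in enumerate(raw):
                cell = cell.strip()
                if cell == "":
                    continue
                if cell == NS_TOKEN:
                    ns[i, j] = True
                else:
                    values[i, j] = float(cell)
        ids = (
            df["respondent_id"].to_numpy()
            if "respondent_id" in df.columns
            else np.arange(n).astype(str)
        )
        raw = cls(
            respondent_ids=np.asarray(ids),
            item_ids=item_cols,
            values=values,
            non_scored=ns,
            strata=df[list(STRATA_COLUMNS)].reset_index(drop=True),
            impute=imp,
        )
        errs = raw.validate(schema)
        if errs:
            raise ValueError("; ".join(errs))
        return raw

    def to_csv(self, path) -> None:
        df = pd.DataFrame(index=range(self.n))
        df["respondent_id"] = self.respondent_ids
        for c in STRATA_COLUMNS:
            df[c] = self.strata[c].to_numpy()
        for j, iid in enumerate(self.item_ids):
            col = np.empty(self.n, dtype=object)
            for i in range(self.n):
                if self.non_scored[i, j]:
                    col[i] = NS_TOKEN
                elif np.isnan(self.values[i, j]):
                    col[i] = ""
                else:
                    col[i] = str(int(self.values[i, j]))
            df[iid] = col
        df.to_csv(path, index=False)


@dataclass
class CleanMatrix:
    """Cleaned respondent x item codes, 0-based worst -> best.

    ``fa_values`` is complete (factor-analysis path); ``scoring_values`` keeps
    NaN where the response carries no value (scoring path).
    """

    respondent_ids: np.ndarray
    item_ids: list[str]
    fa_values: np.ndarray
    scoring_values: np.ndarray
    strata: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.respondent_ids)

    def n_categories(self, schema: QuestionnaireSchema) -> np.ndarray:
        return np.array([schema[i].scale.n_scored_categories for i in self.item_ids])

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.fa_values.astype(int), columns=self.item_ids)
        df.insert(0, "respondent_id", self.respondent_ids)
        for c in STRATA_COLUMNS:
            df[c] = self.strata[c].to_numpy()
        df.to_csv(path, index=False)


@dataclass
class ExclusionReport:
    """Accounting of every screening and imputation decision."""

    n_input: int
    n_excluded: int
    excluded: dict[str, int]  # respondent id -> missing count
    n_imputed_fa: dict[str, int]  # item id -> imputed cells (FA path)
    n_imputed_scoring: dict[str, int]
    max_missing: int

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_excluded": self.n_excluded,
            "n_retained": self.n_input - self.n_excluded,
            "max_missing": self.max_missing,
            "excluded": self.excluded,
            "n_imputed_fa": self.n_imputed_fa,
            "n_imputed_scoring": self.n_imputed_scoring,
        }


@dataclass
class SampleSplit:
    """Disjoint exhaustive halves, balanced to +/-1 within each country."""

    half_a: np.ndarray
    half_b: np.ndarray
    seed: int


def lower_median(values: np.ndarray) -> int:
    """Lower-middle order statistic: always a valid observed category code."""
    obs = np.sort(values[~np.isnan(values)])
    if obs.size == 0:
        raise ValueError("no observed values to take a median of")
    return int(obs[(obs.size - 1) // 2])


def apply_reverse(raw: RawResponseMatrix, schema: QuestionnaireSchema) -> np.ndarray:
    """Matrix-level reverse coding: scored = c - 1 - raw for flagged items."""
    out = raw.values.copy()
    for j, iid in enumerate(raw.item_ids):
        item = schema[iid]
        if item.reverse_coded:
            c = item.scale.n_scored_categories
            out[:, j] = c - 1 - out[:, j]
    return out


def screen_and_impute(
    raw: RawResponseMatrix,
    schema: QuestionnaireSchema,
    max_missing: int = 5,
) -> tuple[CleanMatrix, ExclusionReport]:
    """Screen respondents by missing count, then median-impute.

    Rows with strictly more than ``max_missing`` missing cells are removed
    (non-scored responses are answers, not missingness, and do not count).
    Remaining missing cells — and, on the factor-analysis path, non-scored
    cells — are replaced by the per-item lower median of the observed scored
    codes.  Cells flagged MEDIAN_IMPUTE by a recode rule are imputed on both
    paths.

    Raises ``ValueError`` if an item has no observed value in the retained
    cohort (no median is defined).
    """
    errs = raw.validate(schema)
    if errs:
        raise ValueError("; ".join(errs))

    scored = apply_reverse(raw, schema)
    missing = np.isnan(scored) & ~raw.non_scored
    miss_count = missing.sum(axis=1)
    keep = miss_count <= max_missing

    excluded = {
        str(raw.respondent_ids[i]): int(miss_count[i])
        for i in np.where(~keep)[0]
    }
    vals = scored[keep]
    ns = raw.non_scored[keep]
    imp = raw.impute[keep]
    obs_mask = ~np.isnan(vals) & ~ns & ~imp

    medians = np.empty(vals.shape[1])
    for j, iid in enumerate(raw.item_ids):
        col = np.where(obs_mask[:, j], vals[:, j], np.nan)
        if not np.any(obs_mask[:, j]):
            raise ValueError(f"item {iid!r}: entirely unobserved, no median defined")
        medians[j] = lower_median(col)

    fa = np.where(obs_mask, vals, medians[None, :])
    scoring = np.where(obs_mask, vals, np.nan)
    scoring = np.where(imp, medians[None, :], scoring)

    n_imp_fa = {
        iid: int((~obs_mask[:, j]).sum()) for j, iid in enumerate(raw.item_ids)
    }
    n_imp_sc = {iid: int(imp[:, j].sum()) for j, iid in enumerate(raw.item_ids)}
    report = ExclusionReport(
        n_input=raw.n,
        n_excluded=int((~keep).sum()),
        excluded=excluded,
        n_imputed_fa=n_imp_fa,
        n_imputed_scoring=n_imp_sc,
        max_missing=max_missing,
    )
    clean = CleanMatrix(
        respondent_ids=raw.respondent_ids[keep],
        item_ids=list(raw.item_ids),
        fa_values=fa.astype(int),
        scoring_values=scoring,
        strata=raw.strata.loc[keep].reset_index(drop=True),
    )
    return clean, report


def normalize_response(q: float, c: int) -> float:
    """Normalize a scored code to [0, 1]: q / (c - 1)."""
    if c < 2:
        raise ValueError("need at least two response categories")
    if not 0 <= q <= c - 1:
        raise ValueError(f"code {q} outside 0..{c - 1}")
    return q / (c - 1)


def normalize_matrix(values: np.ndarray, n_categories: np.ndarray) -> np.ndarray:
    """Columnwise q/(c-1); NaN (absent responses) propagates."""
    n_categories = np.asarray(n_categories)
    if np.any(n_categories < 2):
        raise ValueError("need at least two response categories")
    return values / (n_categories[None, :] - 1)


def split_half(clean: CleanMatrix, seed: int) -> SampleSplit:
    """Random half-split, balanced within each country.

    Respondents are shuffled per country with the given seed and assigned
    alternately, guaranteeing per-country balance to +/-1 and reproducibility.
    The first half is intended for the exploratory analysis, the second for
    the confirmatory one.
    """
    if "country" not in clean.strata.columns:
        raise ValueError("clean matrix has no country stratum")
    rng = np.random.default_rng(seed)
    a_idx, b_idx = [], []
    countries = clean.strata["country"].to_numpy()
    for country in sorted(pd.unique(countries)):
        idx = np.where(countries == country)[0]
        idx = rng.permutation(idx)
        a_idx.extend(idx[0::2])
        b_idx.extend(idx[1::2])
    return SampleSplit(
        half_a=clean.respondent_ids[np.sort(np.array(a_idx, dtype=int))],
        half_b=clean.respondent_ids[np.sort(np.array(b_idx, dtype=int))],
        seed=seed,
    )


def subset(clean: CleanMatrix, respondent_ids: np.ndarray) -> CleanMatrix:
    """Restrict a clean matrix to the given respondents (split halves)."""
    mask = np.isin(clean.respondent_ids, respondent_ids)
    return CleanMatrix(
        respondent_ids=clean.respondent_ids[mask],
        item_ids=list(clean.item_ids),
        fa_values=clean.fa_values[mask],
        scoring_values=clean.scoring_values[mask],
        strata=clean.strata.loc[mask].reset_index(drop=True),
    )
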