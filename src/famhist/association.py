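"""Association between family history and first diagnosis.

Two stages mirror the usual epidemiological workflow on a merged patient
table: a Pearson chi-squared contingency test of family history against the
diagnosis group, and a multivariable stepwise binary logistic regression with
outcome MDD = 1 vs BD = 0.  The five family-history indicators are always
retained in the model; demographic covariates (age, gender, marital status,
profession) enter by bidirectional stepwise selection on an information
criterion.  Effects are reported as adjusted odds ratios with Wald 95%
confidence intervals, exp(coef +/- 1.96 * SE), and reference levels of
categorical covariates are rendered as OR = 1.00 (ref.).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .merge import patient_table_to_frame
from .types import LABEL_ORDER, PatientRecord

logger = logging.getLogger(__name__)

FH_COLUMNS = tuple(f"fh_{c}" for c in LABEL_ORDER)
DEFAULT_CANDIDATES = ("age_years", "gender", "marital_status", "profession")
Z_95 = 1.959963984540054  # standard-normal 97.5% quantile


def _as_frame(patients: Sequence[PatientRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(patients, pd.DataFrame):
        return patients.copy()
    return patient_table_to_frame(patients)


# ---------------------------------------------------------------- contingency
@dataclass
class ContingencyTable:
    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray  # (rows, cols) non-negative integers
    overlapping_rows: bool = False

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_dict(self) -> dict:
        return {
            "row_labels": self.row_labels,
            "col_labels": self.col_labels,
            "counts": self.counts.tolist(),
            "overlapping_rows": self.overlapping_rows,
        }


def build_contingency(
    patients: Sequence[PatientRecord] | pd.DataFrame,
    row_spec: str | Sequence[str] = "any_family_history",
    col_spec: str = "diagnosis_group",
) -> ContingencyTable:
    """Cross-tabulate patient fields.

    ``row_spec`` is either one field name (mutually exclusive rows, one per
    level) or a list of binary indicator fields (one possibly-overlapping row
    per indicator, flagged in the metadata).
    """
    df = _as_frame(patients)
    if col_spec not in df.columns:
        raise KeyError(f"unknown column field {col_spec!r}")
    col_labels = sorted(df[col_spec].astype(str).unique()) if len(df) else []
    if isinstance(row_spec, str):
        if row_spec not in df.columns:
            raise KeyError(f"unknown row field {row_spec!r}")
        if len(df) == 0:
            return ContingencyTable([], [], np.zeros((0, 0), dtype=int))
        tab = pd.crosstab(df[row_spec].astype(str), df[col_spec].astype(str))
        tab = tab.reindex(columns=col_labels, fill_value=0)
        return ContingencyTable(
            [str(r) for r in tab.index], col_labels, tab.to_numpy(dtype=int)
        )
    missing = [f for f in row_spec if f not in df.columns]
    if missing:
        raise KeyError(f"unknown row fields {missing}")
    if len(df) == 0:
        return ContingencyTable(list(row_spec), [], np.zeros((len(row_spec), 0), dtype=int),
                                overlapping_rows=True)
    rows = [
        [int(((df[f] == 1) & (df[col_spec].astype(str) == c)).sum()) for c in col_labels]
        for f in row_spec
    ]
    return ContingencyTable(list(row_spec), col_labels, np.array(rows, dtype=int),
                            overlapping_rows=True)


def chi_squared(table: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-squared statistic, degrees of freedom and p-value.

    No continuity correction.  Requires strictly positive margins (all
    expected counts > 0).
    """
    from scipy import stats

    O = table.counts.astype(float)
    if O.ndim != 2 or min(O.shape) < 2:
        raise ValueError("chi-squared requires at least a 2x2 table")
    r, c = table.row_margins.astype(float), table.col_margins.astype(float)
    if (r == 0).any() or (c == 0).any():
        raise ValueError("degenerate table: a row or column margin is zero")
    E = np.outer(r, c) / O.sum()
    stat = float(((O - E) ** 2 / E).sum())
    df = (O.shape[0] - 1) * (O.shape[1] - 1)
    return stat, df, float(stats.chi2.sf(stat, df))


# ------------------------------------------------------------------ logistic
@dataclass
class Term:
    name: str
    covariate: str  # the covariate this term belongs to
    coef: float
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    reference: bool = False
    separation: bool = False  # diverging coefficient: estimate unreliable

    def to_dict(self) -> dict:
        return {
            "name": self.name, "covariate": self.covariate, "coef": self.coef,
            "se": self.se, "odds_ratio": self.odds_ratio, "ci_low": self.ci_low,
            "ci_high": self.ci_high, "p_value": self.p_value, "reference": self.reference,
            "separation": self.separation,
        }


@dataclass
class RegressionResult:
    terms: list[Term]
    included_covariates: list[str]
    n: int
    log_likelihood: float
    converged: bool
    outcome: str = "MDD"
    reference_levels: dict[str, str] = field(default_factory=dict)

    def term(self, name: str) -> Term:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "terms": [t.to_dict() for t in self.terms],
            "included_covariates": self.included_covariates,
            "n": self.n,
            "log_likelihood": self.log_likelihood,
            "converged": self.converged,
            "outcome": self.outcome,
            "reference_levels": self.reference_levels,
        }


def _expand(df: pd.DataFrame, covariate: str) -> tuple[pd.DataFrame, Optional[str]]:
    """Design columns for one covariate; categorical -> dummies dropping the
    most frequent level (the reference)."""
    col = df[covariate]
    if pd.api.types.is_numeric_dtype(col):
        return col.astype(float).to_frame(covariate), None
    ref = col.value_counts().idxmax()
    levels = [lv for lv in sorted(col.astype(str).unique()) if lv != str(ref)]
    out = pd.DataFrame(
        {f"{covariate}[{lv}]": (col.astype(str) == lv).astype(float) for lv in levels},
        index=df.index,
    )
    return out, str(ref)


def _fit(y: np.ndarray, X: pd.DataFrame, max_iter: int = 100):
    """Binomial-GLM maximum likelihood via IRLS (tolerant of quasi-separation)."""
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, sm.add_constant(X, has_constant="add"),
                       family=sm.families.Binomial())
        try:
            res = model.fit(maxiter=max_iter, tol=1e-10)
        except Exception:
            return None
    return res


def _information_criterion(res, criterion: str) -> float:
    k = len(res.params)
    penalty = 2.0 * k if criterion == "aic" else k * float(np.log(res.nobs))
    return float(-2.0 * res.llf + penalty)


def fit_logistic(
    patients: Sequence[PatientRecord] | pd.DataFrame,
    outcome: str = "MDD",
    forced_terms: Sequence[str] = FH_COLUMNS,
    candidate_terms: Sequence[str] = DEFAULT_CANDIDATES,
    stepwise: str = "bidirectional",
    criterion: str = "aic",
) -> RegressionResult:
    """Stepwise-adjusted logistic regression of diagnosis group on family history.

    ``forced_terms`` (the five family-history indicators by default) are
    always retained; ``candidate_terms`` enter/leave by bidirectional
    stepwise selection minimizing the chosen information criterion ("aic" or
    "bic").  Quasi-complete separation (diverging coefficients or a failed
    fit) marks the result non-convergent.
    """
    df = _as_frame(patients)
    y = (df["diagnosis_group"].astype(str) == outcome).astype(int).to_numpy()
    if y.min() == y.max():
        raise ValueError(f"outcome {outcome!r} has a single class in these data")
    if stepwise not in ("bidirectional", "forward", "none"):
        raise ValueError(f"unknown stepwise mode {stepwise!r}")
    if criterion not in ("aic", "bic"):
        raise ValueError(f"criterion must be 'aic' or 'bic', got {criterion!r}")

    forced_X = df[list(forced_terms)].astype(float)
    blocks: dict[str, pd.DataFrame] = {}
    references: dict[str, str] = {}
    for cov in candidate_terms:
        if cov not in df.columns:
            raise KeyError(f"unknown candidate covariate {cov!r}")
        block, ref = _expand(df, cov)
        blocks[cov] = block
        if ref is not None:
            references[cov] = ref

    def ic(res) -> float:
        return _information_criterion(res, criterion)

    def design(included: list[str]) -> pd.DataFrame:
        parts = [forced_X] + [blocks[c] for c in included]
        return pd.concat(parts, axis=1)

    included: list[str] = [] if stepwise != "none" else list(candidate_terms)
    current = _fit(y, design(included))
    if current is None:
        raise RuntimeError("baseline logistic fit failed")
    if stepwise != "none":
        improved = True
        while improved:
            improved = False
            moves: list[tuple[float, str, str]] = []
            for cov in candidate_terms:
                if cov in included:
                    if stepwise == "bidirectional":
                        trial = [c for c in included if c != cov]
                        res = _fit(y, design(trial))
                        if res is not None:
                            moves.append((ic(res), "drop", cov))
                else:
                    res = _fit(y, design(included + [cov]))
                    if res is not None:
                        moves.append((ic(res), "add", cov))
            if moves:
                best_ic, action, cov = min(moves, key=lambda m: m[0])
                if best_ic < ic(current) - 1e-9:
                    included = (
                        included + [cov] if action == "add" else [c for c in included if c != cov]
                    )
                    current = _fit(y, design(included))
                    improved = True

    X = design(included)
    res = _fit(y, X)
    converged = res is not None and bool(getattr(res, "converged", True))
    if res is None:
        return RegressionResult([], included, len(df), float("nan"), False, outcome, references)
    params = res.params
    bse = res.bse
    pvals = res.pvalues

    terms: list[Term] = []
    for name in X.columns:
        cov = name.split("[")[0]
        coef, se = float(params[name]), float(bse[name])
        separated = abs(coef) > 15  # quasi-complete separation for this term
        if separated:
            logger.warning("diverging coefficient for %s suggests quasi-complete separation", name)
        terms.append(
            Term(
                name=name, covariate=cov, coef=coef, se=se,
                odds_ratio=float(np.exp(min(coef, 700))),
                ci_low=float(np.exp(min(coef - Z_95 * se, 700))),
                ci_high=float(np.exp(min(coef + Z_95 * se, 700))),
                p_value=float(pvals[name]),
                separation=separated,
            )
        )
    if any(t.separation for t in terms if t.covariate in forced_terms):
        converged = False  # a forced exposure is inestimable
    for cov, ref in references.items():
        if cov in included:
            terms.append(
                Term(
                    name=f"{cov}[{ref}]", covariate=cov, coef=0.0, se=0.0,
                    odds_ratio=1.0, ci_low=1.0, ci_high=1.0, p_value=float("nan"),
                    reference=True,
                )
            )
    return RegressionResult(
        terms=terms,
        included_covariates=included,
        n=len(df),
        log_likelihood=float(res.llf),
        converged=converged,
        outcome=outcome,
        reference_levels={c: references[c] for c in included if c in references},
    )


def report_ors(result: RegressionResult) -> str:
    """Adjusted odds-ratio table; reference rows render as '1.00 (ref.)'."""
    if not result.converged:
        raise ValueError(
            "regression did not converge (possible quasi-complete separation); "
            "refusing to report odds ratios"
        )
    lines = [f"{'term':<32}{'OR':>8}  {'95% CI':>16}  {'p':>8}"]
    for t in sorted(result.terms, key=lambda t: (t.covariate, t.reference, t.name)):
        if t.reference:
            lines.append(f"{t.name:<32}{'1.00':>8}  {'(ref.)':>16}  {'':>8}")
        else:
            ci = f"{t.ci_low:.3f}-{t.ci_high:.3f}"
            lines.append(f"{t.name:<32}{t.odds_ratio:>8.3f}  {ci:>16}  {t.p_value:>8.3g}")
    return "\n".join(lines)


def analyze(
    patients: Sequence[PatientRecord] | pd.DataFrame,
    outcome: str = "MDD",
    forced_terms: Sequence[str] = FH_COLUMNS,
    candidate_terms: Sequence[str] = DEFAULT_CANDIDATES,
    contingency_rows: str | Sequence[str] = "any_family_history",
) -> dict:
    """Contingency + chi-squared + adjusted-OR regression in one report."""
    table = build_contingency(patients, contingency_rows)
    try:
        stat, dof, p = chi_squared(table)
        chi_block = {"statistic": stat, "df": dof, "p_value": p}
    except ValueError as exc:
        chi_block = {"error": str(exc)}
    reg = fit_logistic(patients, outcome, forced_terms, candidate_terms)
    return {
        "contingency": table.to_dict(),
        "chi_squared": chi_block,
        "regression": reg.to_dict(),
    }
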