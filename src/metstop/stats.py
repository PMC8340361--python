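"""The statistical battery relating the domain indices to each other.

Simple OLS regressions and Pearson correlations among MSS, PSS, LSI and
expression, a paired t-test comparing modification proportions inside vs
outside membrane-binding sites, and categorical class summaries.  Missing
values are handled by pairwise deletion per analysis, so regressions that do
not involve LSI keep the full table while LSI-dependent ones drop the
undetermined rows — reproducing the mixed degrees-of-freedom pattern of
partially-determined feature tables.

All p-values are two-sided.  For a simple regression on n points the F
statistic is R²/((1-R²)/(n-2)) on (1, n-2) degrees of freedom, which equals
the square of the correlation's t statistic, so reported R² always equals
the matching r².
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import DegenerateInputError
from .registry import DomainRecord
from .scoring import SELECTIVITY_CLASSES, MAI_LABELS, compute_lsi, selectivity_class

#: (response, predictor) pairs of the standard battery.
BATTERY_ANALYSES = (
    ("pss", "mss"),
    ("pss", "lsi"),
    ("mss", "lsi"),
    ("expression", "mss"),
    ("expression", "pss"),
)


@dataclass(frozen=True)
class CorrelationResult:
    x: str
    y: str
    n: int
    r: float
    p: float

    @property
    def df(self) -> int:
        return self.n - 2


@dataclass(frozen=True)
class RegressionResult:
    response: str
    predictor: str
    n: int
    slope: float
    intercept: float
    r: float
    r_squared: float
    F: float
    df_model: int
    df_residual: int
    p: float


@dataclass(frozen=True)
class PairedTResult:
    n: int
    t: float
    df: int
    p: float


@dataclass(frozen=True)
class ClassCounts:
    selectivity: dict[str, int]
    mai: dict[str, int]


def _clean_pair(x, y, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DegenerateInputError("x and y must be equal-length 1-D vectors")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < min_n:
        raise DegenerateInputError(f"need at least {min_n} complete pairs, have {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero variance after pairwise deletion")
    return x, y


def pearson(x, y, x_name: str = "x", y_name: str = "y") -> CorrelationResult:
    """Sample Pearson correlation with a two-sided p-value on n-2 df.

    Undetermined entries (NaN) are removed pairwise before computing.
    """
    x, y = _clean_pair(x, y)
    res = sps.pearsonr(x, y)
    return CorrelationResult(
        x=x_name, y=y_name, n=len(x), r=float(res.statistic), p=float(res.pvalue)
    )


def ols_simple(y, x, response: str = "y", predictor: str = "x") -> RegressionResult:
    """Simple least-squares regression of ``y`` on ``x``."""
    x, y = _clean_pair(x, y)
    fit = sps.linregress(x, y)
    n = len(x)
    r2 = fit.rvalue**2
    F = np.inf if r2 >= 1.0 else r2 / ((1 - r2) / (n - 2))
    return RegressionResult(
        response=response,
        predictor=predictor,
        n=n,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        r_squared=float(r2),
        F=float(F),
        df_model=1,
        df_residual=n - 2,
        p=float(fit.pvalue),
    )


def paired_t(a, b) -> PairedTResult:
    """Paired two-sided t-test on matched vectors (t on n-1 df).

    Pairs with a missing member are dropped; identically-zero differences
    (or fewer than two usable pairs) raise :class:`DegenerateInputError`.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise DegenerateInputError("a and b must be equal-length 1-D vectors")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if len(a) < 2:
        raise DegenerateInputError(f"need at least 2 complete pairs, have {len(a)}")
    d = a - b
    if np.ptp(d) == 0 and d[0] == 0:
        raise DegenerateInputError("all paired differences are zero")
    res = sps.ttest_rel(a, b)
    return PairedTResult(n=len(a), t=float(res.statistic), df=len(a) - 1, p=float(res.pvalue))


def summarize_classes(records: Sequence[DomainRecord]) -> ClassCounts:
    """Count domains per selectivity class (from LSI recomputed off the
    ligand column) and per MAI label; undetermined rows are excluded."""
    sel = {label: 0 for label in SELECTIVITY_CLASSES}
    for rec in records:
        if rec.ligand_codes is None:
            continue
        sel[selectivity_class(compute_lsi(rec.ligand_codes).lsi)] += 1
    mai = {label: 0 for label in MAI_LABELS}
    for rec in records:
        if rec.mai is not None:
            mai[rec.mai] += 1
    return ClassCounts(selectivity=sel, mai=mai)


@dataclass
class StatReport:
    """Results of the full battery on one feature table."""

    regressions: dict[str, RegressionResult] = field(default_factory=dict)
    correlations: dict[str, CorrelationResult] = field(default_factory=dict)
    counts: ClassCounts | None = None
    paired: PairedTResult | None = None
    notes: list[str] = field(default_factory=list)
    unusable: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out: dict = {"regressions": {}, "correlations": {}}
        for name, reg in self.regressions.items():
            out["regressions"][name] = {
                "n": reg.n, "slope": reg.slope, "intercept": reg.intercept,
                "r": reg.r, "r_squared": reg.r_squared, "F": reg.F,
                "df": [reg.df_model, reg.df_residual], "p": reg.p,
            }
        for name, cor in self.correlations.items():
            out["correlations"][name] = {"n": cor.n, "r": cor.r, "p": cor.p}
        if self.counts is not None:
            out["counts"] = {"selectivity": self.counts.selectivity, "mai": self.counts.mai}
        if self.paired is not None:
            out["paired_t"] = {
                "n": self.paired.n, "t": self.paired.t,
                "df": self.paired.df, "p": self.paired.p,
            }
        out["notes"] = list(self.notes)
        out["unusable"] = dict(self.unusable)
        return out

    def to_text(self) -> str:
        lines = []
        for name, reg in self.regressions.items():
            lines.append(
                f"{name}: {reg.response} = {reg.intercept:.4f} + {reg.slope:.4f} "
                f"({reg.predictor}); F({reg.df_model},{reg.df_residual}) = {reg.F:.4f}, "
                f"P = {reg.p:.4f}, R^2 = {reg.r_squared:.6f}"
            )
        for name, cor in self.correlations.items():
            lines.append(f"{name}: r({cor.df}) = {cor.r:.4f}, P = {cor.p:.4f}")
        if self.counts is not None:
            lines.append(f"selectivity classes: {self.counts.selectivity}")
            lines.append(f"MAI classes: {self.counts.mai}")
        if self.paired is not None:
            p = self.paired
            lines.append(f"paired t-test: t = {p.t:.4f}, df = {p.df}, P = {p.p:.4f}")
        for note in self.notes:
            lines.append(f"note: {note}")
        for name, reason in self.unusable.items():
            lines.append(f"unusable: {name}: {reason}")
        return "\n".join(lines)


def _column(records: Sequence[DomainRecord], name: str) -> np.ndarray:
    vals = [getattr(r, name) for r in records]
    return np.array([np.nan if v is None else float(v) for v in vals])


def run_battery(records: Sequence[DomainRecord]) -> StatReport:
    """Run the standard regression/correlation battery on a feature table.

    Analyses: PSS~MSS, PSS~LSI, MSS~LSI, expression~MSS, expression~PSS,
    each as both a simple regression and a Pearson correlation, plus the
    selectivity and MAI class counts.  LSI-dependent analyses drop rows with
    undetermined LSI (pairwise deletion); a note records every exclusion.
    Analyses that are degenerate on the given table are listed in
    ``unusable``; if none can run at all, :class:`DegenerateInputError` is
    raised naming them.
    """
    report = StatReport()
    n_rows = len(records)
    columns = {name: _column(records, name) for name in ("mss", "pss", "lsi", "expression")}
    for response, predictor in BATTERY_ANALYSES:
        name = f"{response}~{predictor}"
        y, x = columns[response], columns[predictor]
        try:
            report.regressions[name] = ols_simple(y, x, response=response, predictor=predictor)
            report.correlations[name] = pearson(x, y, x_name=predictor, y_name=response)
        except DegenerateInputError as exc:
            report.unusable[name] = str(exc)
            continue
        used = report.regressions[name].n
        if used < n_rows:
            report.notes.append(f"{name}: {n_rows - used} row(s) excluded by pairwise deletion (n={used})")
    report.counts = summarize_classes(records)
    if not report.regressions:
        raise DegenerateInputError(
            "no analysis could run: " + "; ".join(f"{k} ({v})" for k, v in report.unusable.items())
        )
    return report
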