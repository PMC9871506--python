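"""Information-value ranking and correlation-based redundancy pruning.

Variables are scored by information value (IV), the weight-of-evidence
divergence between the positive- and negative-class distributions of a
discretised variable:

    IV = sum_i (y_i/y_T - n_i/n_T) * ln[(y_i/n_i) / (y_T/n_T)]

over the bins i of an equal-frequency (quantile) discretisation with 10
bins by default. Per-bin zero counts are raised to 1 before the term is
computed, to prevent infinite weight-of-evidence; the totals y_T/n_T keep
their original values. The higher the IV, the more the variable separates
the positive class from the rest.

The screening runs IV twice — once with the nitrogen-deficient group as the
positive class, once with the pooled phosphorus/potassium-deficient group —
ranks variables by the larger of the two IVs, and greedily drops any
variable whose absolute Pearson correlation with an already-kept variable
reaches the redundancy threshold (default |r| >= 0.9).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .canopy_features import FEATURE_COLUMNS

__all__ = [
    "discretize",
    "information_value",
    "pearson_matrix",
    "select_variables",
    "screen_features",
    "Binning",
    "IVResult",
    "ScreeningResult",
]


@dataclass
class Binning:
    """Discretisation of a numeric vector into ordered, non-overlapping bins."""

    codes: np.ndarray  # bin index per observation
    edges: np.ndarray  # bin boundaries, len = n_effective_bins + 1
    n_requested: int
    merged: bool  # True when duplicate quantile edges were merged

    @property
    def n_effective(self) -> int:
        return len(self.edges) - 1


def discretize(values, n_bins: int = 10, scheme: str = "quantile") -> Binning:
    """Bin a numeric vector for IV computation.

    ``scheme="quantile"`` (default) gives equal-frequency bins; duplicate
    quantile edges from heavy ties are merged, yielding fewer effective bins
    (recorded in ``Binning.merged``). ``scheme="width"`` gives equal-width
    bins. A constant vector collapses to a single bin with a warning — its
    IV downstream is 0.
    """
    x = np.asarray(values, float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("values must be a non-empty 1-D vector")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")

    lo, hi = x.min(), x.max()
    if lo == hi:
        warnings.warn("constant vector: single bin, IV will be 0")
        return Binning(
            codes=np.zeros(x.size, dtype=int),
            edges=np.array([lo, hi]),
            n_requested=n_bins,
            merged=True,
        )
    if scheme == "quantile":
        qs = np.linspace(0, 1, n_bins + 1)
        raw = np.quantile(x, qs)
    elif scheme == "width":
        raw = np.linspace(lo, hi, n_bins + 1)
    else:
        raise ValueError("scheme must be 'quantile' or 'width'")
    edges = np.unique(raw)
    merged = len(edges) < len(raw)
    # interior edges define bins; right-closed so the max falls in the last bin
    codes = np.searchsorted(edges[1:-1], x, side="left")
    return Binning(codes=codes, edges=edges, n_requested=n_bins, merged=merged)


@dataclass
class IVResult:
    """Information value of one variable with its full bin table."""

    variable: str
    positive_class: str
    iv: float
    bins: pd.DataFrame  # per-bin: lo, hi, y, n, y_adj, n_adj, adjusted, woe, term
    y_total: int
    n_total: int
    binning: Binning | None = None


def information_value(
    variable,
    positive,
    n_bins: int = 10,
    scheme: str = "quantile",
    variable_name: str = "",
    positive_class: str = "",
) -> IVResult:
    """Information value of one variable against a boolean positive label.

    Per-bin zero counts of either class are adjusted to 1 before the
    weight-of-evidence term is evaluated; the class totals are left at their
    observed values. Raises ``ValueError`` when only one class is present.
    """
    y = np.asarray(positive).astype(bool)
    x = np.asarray(variable, float)
    if x.shape != y.shape:
        raise ValueError("variable and labels must align")
    y_T = int(y.sum())
    n_T = int((~y).sum())
    if y_T == 0 or n_T == 0:
        raise ValueError("both positive and negative samples are required")

    binning = discretize(x, n_bins=n_bins, scheme=scheme)
    rows = []
    iv = 0.0
    for b in range(binning.n_effective):
        in_bin = binning.codes == b
        y_i = int((y & in_bin).sum())
        n_i = int((~y & in_bin).sum())
        y_adj = max(y_i, 1)
        n_adj = max(n_i, 1)
        woe = np.log((y_adj / n_adj) / (y_T / n_T))
        term = (y_adj / y_T - n_adj / n_T) * woe
        iv += term
        rows.append({
            "bin": b,
            "lo": binning.edges[b],
            "hi": binning.edges[b + 1],
            "y": y_i,
            "n": n_i,
            "y_adj": y_adj,
            "n_adj": n_adj,
            "adjusted": (y_i == 0) or (n_i == 0),
            "woe": woe,
            "term": term,
        })
    return IVResult(
        variable=variable_name,
        positive_class=positive_class,
        iv=float(iv),
        bins=pd.DataFrame(rows),
        y_total=y_T,
        n_total=n_T,
        binning=binning,
    )


def pearson_matrix(table: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Pearson correlation matrix of the feature columns.

    Zero-variance columns produce NaN rows/columns (flagged downstream as
    droppable). Requires at least 3 rows.
    """
    cols = list(columns) if columns is not None else [
        c for c in table.columns if c in FEATURE_COLUMNS
    ]
    if not cols:
        cols = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    data = table[cols]
    if len(data) < 3:
        raise ValueError("need at least 3 rows for a correlation matrix")
    if not np.all(np.isfinite(data.to_numpy(float))):
        raise ValueError("correlation input must be finite")
    return data.corr(method="pearson")


@dataclass
class ScreeningResult:
    """Outcome of IV ranking + correlation pruning."""

    selected: list[str]
    correlation: pd.DataFrame
    iv_by_variable: dict[str, dict[str, float]]  # var -> {run name -> IV}
    ranking: list[str]  # variables in descending combined-IV order
    decisions: list[dict] = field(default_factory=list)  # per-drop records

    def combined_iv(self, var: str) -> float:
        return max(self.iv_by_variable[var].values())


def select_variables(
    table: pd.DataFrame,
    iv_runs: dict[str, dict[str, float]],
    threshold: float = 0.9,
    combine: str = "max",
    columns=None,
) -> ScreeningResult:
    """Greedy redundancy pruning of IV-ranked variables.

    ``iv_runs`` maps run name (positive-class definition) to a dict of
    per-variable IVs. Variables are ranked by the combined IV (``max`` of
    the runs by default, ``sum`` as an alternative), ties broken by variable
    name; walking down the ranking, a variable is dropped when its absolute
    Pearson correlation with any already-kept variable reaches
    ``threshold``. Zero-variance variables (undefined correlations) are
    dropped. Every drop is recorded with the kept partner, |r| and the IVs.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if combine not in ("max", "sum"):
        raise ValueError("combine must be 'max' or 'sum'")

    variables = sorted(set(itertools.chain.from_iterable(iv_runs.values())))
    corr = pearson_matrix(table, columns=columns if columns is not None else variables)

    iv_by_var = {
        v: {run: ivs.get(v, 0.0) for run, ivs in iv_runs.items()} for v in variables
    }
    agg = max if combine == "max" else sum

    ranking = sorted(variables, key=lambda v: (-agg(iv_by_var[v].values()), v))
    selected: list[str] = []
    decisions: list[dict] = []
    for var in ranking:
        col = corr[var]
        if np.isnan(col[var]):
            decisions.append({
                "dropped": var, "kept": None, "abs_r": None,
                "reason": "zero variance",
                "iv_dropped": iv_by_var[var], "iv_kept": None,
            })
            continue
        clash = None
        for kept in selected:
            r = corr.loc[var, kept]
            if np.isfinite(r) and abs(r) >= threshold:
                clash = (kept, float(abs(r)))
                break
        if clash is None:
            selected.append(var)
        else:
            kept, abs_r = clash
            decisions.append({
                "dropped": var, "kept": kept, "abs_r": abs_r,
                "reason": f"|r| >= {threshold} with {kept}",
                "iv_dropped": iv_by_var[var], "iv_kept": iv_by_var[kept],
            })

    for a, b in itertools.combinations(selected, 2):
        assert abs(corr.loc[a, b]) < threshold, (a, b, corr.loc[a, b])

    return ScreeningResult(
        selected=selected,
        correlation=corr,
        iv_by_variable=iv_by_var,
        ranking=ranking,
        decisions=decisions,
    )


def screen_features(
    table: pd.DataFrame,
    threshold: float = 0.9,
    n_bins: int = 10,
    combine: str = "max",
    columns=None,
) -> ScreeningResult:
    """Full screening stage on a pooled feature table.

    Computes IV under the two positive-class definitions used for diagnosis
    — nitrogen deficiency (ND) versus the rest, and pooled
    phosphorus/potassium deficiency (PD/KD) versus the rest — then prunes at
    the correlation threshold. The table is pooled across days/altitudes as
    given; stratify upstream if needed.
    """
    cols = list(columns) if columns is not None else [
        c for c in table.columns if c in FEATURE_COLUMNS
    ]
    labels = table["label"].to_numpy()
    runs: dict[str, dict[str, float]] = {}
    for run_name, positive in (
        ("ND", np.isin(labels, ["ND"])),
        ("PD\\KD", np.isin(labels, ["PD", "KD"])),
    ):
        ivs = {}
        for col in cols:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ivs[col] = information_value(
                    table[col].to_numpy(float), positive, n_bins=n_bins,
                    variable_name=col, positive_class=run_name,
                ).iv
        runs[run_name] = ivs
    return select_variables(table, runs, threshold=threshold, combine=combine, columns=cols)
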