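"""Differential screening with the random-variance-model moderated t-test.

Small-replicate two-group designs (here 3 vs 3 arrays) leave the per-gene
variance estimate on very few degrees of freedom, so an ordinary t-test is
unstable. The random variance model (RVM) assumes the per-gene precision is
drawn from a Gamma(a, b) prior, sigma^-2 ~ Gamma(a, b), under which the
observed residual variance s^2 (on m degrees of freedom) satisfies

    s^2 * a * b  ~  F(m, 2a).

Fitting (a, b) across all genes by maximum likelihood yields a moderated
variance estimate

    s~^2 = (m * s^2 + 2/b) / (m + 2a)

and the moderated statistic is referred to a t distribution on m + 2a
degrees of freedom. As a -> 0 with 1/b -> 0 the prior flattens and the test
reduces to the classical pooled two-sample t-test.

Fold changes are ratios of raw-scale geometric means; the test itself runs
on log2 intensities. Both conventions are what intensity-scale report
tables (geometric mean per group, fold change, up/down trend) imply.

The module exposes a functional surface (``fit_rvm``, ``rvm_t_test``,
``bh_fdr``, ``select_differential``) plus a model/results pair,
:class:`DifferentialExpression` and :class:`DifferentialExpressionResults`,
in the statsmodels idiom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from hubnet import io

EXPERIMENTAL = "experimental"
CONTROL = "control"

#: p-values are floored at this value before taking -log10 for volcano plots
P_FLOOR = 1e-300

#: below this many positive-variance genes the RVM fit is not attempted
MIN_GENES_FOR_RVM = 50

RECORD_COLUMNS = [
    "gene",
    "p_value",
    "fdr",
    "geom_mean_exp",
    "geom_mean_ctrl",
    "fold_change",
    "trend",
]


class RVMFitError(RuntimeError):
    """Raised when the variance-prior hyperparameters cannot be estimated."""


# ---------------------------------------------------------------------------
# data container


@dataclass
class ExpressionMatrix:
    """Gene x sample intensity matrix with a two-level group factor.

    Parameters
    ----------
    data
        Positive intensities, genes as rows (unique ids), samples as columns.
        Expected to be already normalized (e.g. RMA output on the raw scale).
    groups
        Sample id -> group label mapping covering every column; labels must
        be exactly ``{"experimental", "control"}``.
    """

    data: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes}")
        if (self.data.to_numpy() <= 0).any() or self.data.isna().any().any():
            raise ValueError("intensities must be strictly positive and finite")
        missing = [s for s in self.data.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without group assignment: {missing}")
        self.groups = self.groups.loc[self.data.columns]
        labels = set(self.groups.unique())
        if labels != {EXPERIMENTAL, CONTROL}:
            raise ValueError(
                f"groups must be exactly {{{EXPERIMENTAL!r}, {CONTROL!r}}}, got {sorted(labels)}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    def samples_of(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def group_values(self, group: str) -> pd.DataFrame:
        return self.data[self.samples_of(group)]

    def log2(self) -> pd.DataFrame:
        return np.log2(self.data)

    def swap_groups(self) -> "ExpressionMatrix":
        """Return a copy with the experimental/control labels exchanged."""
        swapped = self.groups.map({EXPERIMENTAL: CONTROL, CONTROL: EXPERIMENTAL})
        return ExpressionMatrix(self.data.copy(), swapped)

    @classmethod
    def from_files(cls, matrix_path: str | Path, groups_path: str | Path) -> "ExpressionMatrix":
        return cls(io.read_expression_tsv(matrix_path), io.read_groups_tsv(groups_path))


# ---------------------------------------------------------------------------
# elementary operations


def geometric_mean(values) -> float:
    """exp(mean(log x)) of a non-empty sequence of positive reals."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("geometric mean of empty sequence")
    if (arr <= 0).any():
        raise ValueError("geometric mean requires strictly positive values")
    return float(np.exp(np.mean(np.log(arr))))


def fold_change(geom_exp: float, geom_ctrl: float) -> tuple[float, str]:
    """Ratio of geometric means and its trend label.

    Returns ``(ratio, trend)`` with trend ``"up"`` for ratio > 1, ``"down"``
    for ratio < 1, and ``"flat"`` for an exact tie (a tie cannot survive the
    significance filter, so "flat" never reaches a report of selected genes).
    """
    if geom_exp <= 0 or geom_ctrl <= 0:
        raise ValueError("geometric means must be positive")
    ratio = geom_exp / geom_ctrl
    if ratio > 1:
        trend = "up"
    elif ratio < 1:
        trend = "down"
    else:
        trend = "flat"
    return ratio, trend


@dataclass
class RVMModel:
    """Hyperparameters of the inverse-gamma variance prior.

    ``a`` and ``b`` are the shape and scale of the Gamma prior on the
    precision (so the prior mean precision is a*b); ``df_residual`` is the
    per-gene residual degrees of freedom m of the variances the model was
    fitted to.
    """

    a: float
    b: float
    df_residual: int
    converged: bool = True
    n_genes: int = 0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("hyperparameters a and b must be positive")

    @property
    def df_moderated(self) -> float:
        return self.df_residual + 2.0 * self.a

    def moderate(self, sample_variances) -> np.ndarray:
        """Shrink raw variances toward the prior: (m s^2 + 2/b)/(m + 2a)."""
        s2 = np.asarray(sample_variances, dtype=float)
        return (self.df_residual * s2 + 2.0 / self.b) / self.df_moderated


def _rvm_negloglik(params: np.ndarray, s2: np.ndarray, df: int) -> float:
    log_a, log_b = params
    a, b = np.exp(log_a), np.exp(log_b)
    # density of s^2 when s^2*a*b ~ F(df, 2a); the a*b factor is the Jacobian
    x = s2 * a * b
    ll = stats.f.logpdf(x, df, 2.0 * a) + np.log(a * b)
    if not np.all(np.isfinite(ll)):
        return np.inf
    return -float(np.sum(ll))


def fit_rvm(sample_variances, df: int) -> RVMModel:
    """Fit the variance-prior hyperparameters (a, b) by maximum likelihood.

    Parameters
    ----------
    sample_variances
        Per-gene residual variances; genes with non-positive variance are
        excluded from the fit (they carry no information about the prior).
    df
        Residual degrees of freedom of each variance (n1 + n2 - 2 for a
        two-sample design).

    Raises
    ------
    RVMFitError
        If fewer than ``MIN_GENES_FOR_RVM`` positive variances are available,
        the variances are degenerate (all identical), or the optimizer does
        not converge. Callers fall back to the ordinary t-test.
    """
    s2 = np.asarray(sample_variances, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < MIN_GENES_FOR_RVM:
        raise RVMFitError(
            f"need >= {MIN_GENES_FOR_RVM} positive variances, got {s2.size}"
        )
    if np.ptp(s2) == 0.0:
        raise RVMFitError("degenerate variance distribution (all variances equal)")
    if df < 1:
        raise RVMFitError("residual degrees of freedom must be >= 1")

    # moment-based start: E[s^2] = 1/((a-1) b) for a > 1
    a0 = 2.0
    b0 = 1.0 / ((a0 - 1.0) * float(np.mean(s2)))
    res = optimize.minimize(
        _rvm_negloglik,
        x0=np.log([a0, b0]),
        args=(s2, df),
        method="L-BFGS-B",
        bounds=[(np.log(1e-3), np.log(1e4)), (-40.0, 40.0)],
        options={"gtol": 1e-8, "maxiter": 500},
    )
    if not res.success and "ABNORMAL" in str(res.message).upper():
        raise RVMFitError(f"hyperparameter optimization failed: {res.message}")
    a, b = np.exp(res.x)
    return RVMModel(a=float(a), b=float(b), df_residual=int(df), n_genes=int(s2.size))


def _pooled_stats(matrix: ExpressionMatrix):
    """Per-gene group means and pooled variance of the log2 intensities."""
    log_data = matrix.log2()
    exp = log_data[matrix.samples_of(EXPERIMENTAL)].to_numpy()
    ctrl = log_data[matrix.samples_of(CONTROL)].to_numpy()
    n1, n2 = exp.shape[1], ctrl.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 samples for a variance estimate")
    m1, m2 = exp.mean(axis=1), ctrl.mean(axis=1)
    v1 = exp.var(axis=1, ddof=1)
    v2 = ctrl.var(axis=1, ddof=1)
    df = n1 + n2 - 2
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    return m1, m2, pooled, n1, n2, df


def _t_to_p(diff: np.ndarray, var: np.ndarray, scale: float, df: float):
    """Two-sided p from t = diff / sqrt(var * scale), robust to var == 0."""
    se = np.sqrt(var * scale)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0), np.where(diff == 0, 0.0, np.inf * np.sign(diff)))
    p = np.where(np.isinf(t), 0.0, 2.0 * stats.t.sf(np.abs(np.where(np.isinf(t), 0.0, t)), df))
    return t, p


def rvm_t_test(matrix: ExpressionMatrix, model: RVMModel) -> pd.DataFrame:
    """Moderated two-sample t-test on log2 intensities.

    Returns a frame indexed by gene with columns ``statistic`` and
    ``p_value``; the statistic is referred to t on ``df_residual + 2a``
    degrees of freedom.
    """
    m1, m2, pooled, n1, n2, df = _pooled_stats(matrix)
    if model.df_residual != df:
        raise ValueError(
            f"model fitted at df={model.df_residual} but matrix has df={df}"
        )
    mod_var = model.moderate(pooled)
    t, p = _t_to_p(m1 - m2, mod_var, 1.0 / n1 + 1.0 / n2, model.df_moderated)
    return pd.DataFrame({"statistic": t, "p_value": p}, index=matrix.gene_ids)


def ordinary_t_test(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Classical pooled two-sample t-test on log2 intensities (fallback)."""
    m1, m2, pooled, n1, n2, df = _pooled_stats(matrix)
    t, p = _t_to_p(m1 - m2, pooled, 1.0 / n1 + 1.0 / n2, df)
    return pd.DataFrame({"statistic": t, "p_value": p}, index=matrix.gene_ids)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any():
        raise ValueError("NaN p-value passed to bh_fdr")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_records(matrix: ExpressionMatrix, tests: pd.DataFrame) -> pd.DataFrame:
    """Assemble per-gene report rows: p, FDR, geometric means, fold, trend."""
    gm_exp = np.exp(np.mean(np.log(matrix.group_values(EXPERIMENTAL).to_numpy()), axis=1))
    gm_ctrl = np.exp(np.mean(np.log(matrix.group_values(CONTROL).to_numpy()), axis=1))
    ratio = gm_exp / gm_ctrl
    trend = np.where(ratio > 1, "up", np.where(ratio < 1, "down", "flat"))
    return pd.DataFrame(
        {
            "gene": matrix.gene_ids,
            "p_value": tests["p_value"].to_numpy(),
            "fdr": bh_fdr(tests["p_value"].to_numpy()),
            "geom_mean_exp": gm_exp,
            "geom_mean_ctrl": gm_ctrl,
            "fold_change": ratio,
            "trend": trend,
        }
    )


def select_differential(
    records: pd.DataFrame, p_cut: float = 0.05, fdr_cut: float = 0.05
) -> pd.DataFrame:
    """Keep genes with p < p_cut and FDR < fdr_cut (both strict).

    The result is sorted by p-value, then by descending \\|log2 fold change\\|,
    then gene id — a deterministic ordering for report files.
    """
    sel = records[(records["p_value"] < p_cut) & (records["fdr"] < fdr_cut)].copy()
    if sel.empty:
        return sel
    sel["_absl2fc"] = np.abs(np.log2(sel["fold_change"]))
    sel = sel.sort_values(
        ["p_value", "_absl2fc", "gene"], ascending=[True, False, True]
    ).drop(columns="_absl2fc")
    return sel.reset_index(drop=True)


def volcano_coordinates(records: pd.DataFrame) -> pd.DataFrame:
    """Per-gene (log2 fold change, -log10 p) with the p floored at 1e-300."""
    x = np.log2(records["fold_change"].to_numpy())
    y = -np.log10(np.maximum(records["p_value"].to_numpy(), P_FLOOR))
    return pd.DataFrame({"gene": records["gene"], "log2_fold_change": x, "neg_log10_p": y})


# ---------------------------------------------------------------------------
# model / results


class DifferentialExpression:
    """Two-group differential-expression model for an intensity matrix.

    Examples
    --------
    >>> model = DifferentialExpression(matrix)            # doctest: +SKIP
    >>> results = model.fit()                             # doctest: +SKIP
    >>> results.significant.head()                        # doctest: +SKIP
    """

    def __init__(self, matrix: ExpressionMatrix):
        self.matrix = matrix

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, groups: pd.Series) -> "DifferentialExpression":
        return cls(ExpressionMatrix(data, groups))

    @classmethod
    def from_files(cls, matrix_path: str | Path, groups_path: str | Path) -> "DifferentialExpression":
        return cls(ExpressionMatrix.from_files(matrix_path, groups_path))

    def fit(
        self, p_cut: float = 0.05, fdr_cut: float = 0.05, method: str = "rvm"
    ) -> "DifferentialExpressionResults":
        """Fit the variance prior and run the moderated test.

        ``method="rvm"`` fits the random variance model and falls back to the
        ordinary pooled t-test (with a warning) when the fit is degenerate;
        ``method="t"`` forces the ordinary test.
        """
        if not 0 < p_cut <= 1 or not 0 < fdr_cut <= 1:
            raise ValueError("p_cut and fdr_cut must lie in (0, 1]")
        rvm: RVMModel | None = None
        if method == "rvm":
            _, _, pooled, _, _, df = _pooled_stats(self.matrix)
            try:
                rvm = fit_rvm(pooled, df)
                tests = rvm_t_test(self.matrix, rvm)
            except RVMFitError as exc:
                warnings.warn(
                    f"RVM fit unavailable ({exc}); falling back to the ordinary t-test",
                    stacklevel=2,
                )
                tests = ordinary_t_test(self.matrix)
        elif method == "t":
            tests = ordinary_t_test(self.matrix)
        else:
            raise ValueError(f"unknown method {method!r}")
        records = differential_records(self.matrix, tests)
        return DifferentialExpressionResults(
            self, records, tests, rvm, p_cut=p_cut, fdr_cut=fdr_cut
        )


@dataclass
class DifferentialExpressionResults:
    """Fitted screening results: per-gene records plus the variance prior."""

    model: DifferentialExpression
    records: pd.DataFrame
    tests: pd.DataFrame
    rvm: RVMModel | None
    p_cut: float = 0.05
    fdr_cut: float = 0.05
    _significant: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def significant(self) -> pd.DataFrame:
        if self._significant is None:
            self._significant = select_differential(self.records, self.p_cut, self.fdr_cut)
        return self._significant

    @property
    def up(self) -> pd.DataFrame:
        sel = self.significant
        return sel[sel["trend"] == "up"].reset_index(drop=True)

    @property
    def down(self) -> pd.DataFrame:
        sel = self.significant
        return sel[sel["trend"] == "down"].reset_index(drop=True)

    @property
    def significant_genes(self) -> list[str]:
        return list(self.significant["gene"])

    def trend_of(self) -> dict[str, str]:
        return dict(zip(self.records["gene"], self.records["trend"]))

    def volcano(self) -> pd.DataFrame:
        return volcano_coordinates(self.records)

    def summary(self) -> str:
        """Human-readable summary in the spirit of a model-fit report."""
        n = len(self.records)
        sel = self.significant
        lines = [
            "Differential expression (RVM moderated t-test)"
            if self.rvm is not None
            else "Differential expression (ordinary pooled t-test)",
            "=" * 54,
            f"genes tested:            {n}",
            f"samples (exp/ctrl):      {len(self.model.matrix.samples_of(EXPERIMENTAL))}"
            f"/{len(self.model.matrix.samples_of(CONTROL))}",
        ]
        if self.rvm is not None:
            lines += [
                f"variance prior a, b:     {self.rvm.a:.4g}, {self.rvm.b:.4g}",
                f"moderated df:            {self.rvm.df_moderated:.2f}",
            ]
        lines += [
            f"selection:               p < {self.p_cut}, FDR < {self.fdr_cut}",
            f"differential genes:      {len(sel)} ({len(self.up)} up, {len(self.down)} down)",
        ]
        if len(sel):
            fc = sel["fold_change"]
            lines.append(f"fold-change range:       {fc.min():.2f} - {fc.max():.2f}")
        return "\n".join(lines)

    def to_tsv(self, path: str | Path, rounded: bool = True) -> None:
        """Write the report table (report rounding: fold 2 dp, p scientific)."""
        out = self.records[RECORD_COLUMNS].copy()
        if rounded:
            out["fold_change"] = out["fold_change"].map(lambda v: f"{v:.2f}")
            for col in ("p_value", "fdr"):
                out[col] = out[col].map(lambda v: f"{v:.4g}")
            for col in ("geom_mean_exp", "geom_mean_ctrl"):
                out[col] = out[col].map(lambda v: f"{v:.2f}")
        out.to_csv(path, sep="\t", index=False)
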