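"""Group-comparison statistics: variance-gated t-tests, ROC, sample size.

The comparison protocol for each feature at each energy is:

1. Test equality of variances between the two classes with the two-sided
   F-ratio test at alpha = 0.05.
2. If variances look equal, use the pooled two-sample t-test
   (df = n1 + n2 - 2); otherwise the Satterthwaite (Welch) test with
   effective degrees of freedom from the Welch-Satterthwaite formula.
3. Report the raw two-sided P value — no multiplicity correction by default,
   matching common radiology reporting; Benjamini-Hochberg is available as an
   option.
4. Construct the empirical ROC curve, measure the AUC by the midrank
   Mann-Whitney formula, orient so AUC >= 0.5, and pick the operating cut-off
   maximizing Youden's J (ties toward higher specificity), with the decision
   boundary inclusive on the malignant side.

The cohort-level interface follows the model/results idiom: build a
:class:`CohortComparison` from the feature and spectral tables, call
``fit()``, and read the per-feature-per-energy report off the returned
:class:`CohortComparisonResults`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError
from .texture import FEATURE_NAMES

POOLED = "pooled"
SATTERTHWAITE = "satterthwaite"


@dataclass(frozen=True)
class GroupSummary:
    """Sufficient statistics (n, mean, sd) of one feature in one class."""

    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 2:
            raise InputError(f"group needs n >= 2, got n={self.n}")
        if self.sd < 0:
            raise InputError(f"sd must be non-negative, got {self.sd}")

    @classmethod
    def from_samples(cls, x: Sequence[float]) -> "GroupSummary":
        x = np.asarray(x, dtype=float)
        if x.size < 2:
            raise InputError("need at least two observations per group")
        return cls(n=int(x.size), mean=float(x.mean()), sd=float(x.std(ddof=1)))


@dataclass(frozen=True)
class TestResult:
    t_statistic: float
    df: float
    method: str                  # pooled | satterthwaite
    p_two_sided: float
    variance_test_p: float
    significant: bool            # p <= 0.05
    feature: str = ""
    energy_keV: float | None = None


@dataclass(frozen=True)
class RocResult:
    auc: float
    orientation: str             # '>' or '<': side of the cut-off called malignant
    cutoff: float
    sensitivity: float
    specificity: float
    feature: str = ""
    energy_keV: float | None = None


def variance_equality_test(s1: float, n1: int, s2: float, n2: int) -> tuple[float, float]:
    """Two-sided F-ratio test for equality of variances.

    The statistic is the larger sample variance over the smaller, with
    degrees of freedom ordered to match.  Both variances zero is degenerate
    and returns the equal-variance verdict (F=1, p=1); exactly one zero
    variance gives F=inf, p=0.
    """
    if n1 < 2 or n2 < 2:
        raise InputError("variance test needs n >= 2 in both groups")
    if s1 < 0 or s2 < 0:
        raise InputError("standard deviations must be non-negative")
    v1, v2 = s1 * s1, s2 * s2
    if v1 == 0 and v2 == 0:
        return 1.0, 1.0
    if v1 == 0 or v2 == 0:
        return math.inf, 0.0
    if v1 >= v2:
        F, dfn, dfd = v1 / v2, n1 - 1, n2 - 1
    else:
        F, dfn, dfd = v2 / v1, n2 - 1, n1 - 1
    p = min(1.0, 2.0 * float(sps.f.sf(F, dfn, dfd)))
    return float(F), p


def choose_method(s1: float, n1: int, s2: float, n2: int,
                  alpha: float = 0.05) -> tuple[str, float]:
    """Variance gate: Satterthwaite when the F-test rejects at ``alpha``."""
    _, p = variance_equality_test(s1, n1, s2, n2)
    return (SATTERTHWAITE if p <= alpha else POOLED), p


def two_sample_t_from_summary(
    m1: float, s1: float, n1: int,
    m2: float, s2: float, n2: int,
    method: str | None = None,
) -> TestResult:
    """Two-sample t-test from group summaries.

    ``method=None`` applies the variance gate automatically.  Pooled:
    t = (m1-m2) / (sp * sqrt(1/n1 + 1/n2)) with
    sp^2 = ((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2) and df = n1+n2-2.
    Satterthwaite: t = (m1-m2) / sqrt(s1^2/n1 + s2^2/n2) with
    Welch-Satterthwaite df.
    """
    if n1 < 2 or n2 < 2:
        raise InputError("t-test needs n >= 2 in both groups")
    _, var_p = variance_equality_test(s1, n1, s2, n2)
    if method is None:
        method = SATTERTHWAITE if var_p <= 0.05 else POOLED
    if method not in (POOLED, SATTERTHWAITE):
        raise InputError(f"unknown t-test method {method!r}")

    v1, v2 = s1 * s1, s2 * s2
    if method == POOLED:
        df = float(n1 + n2 - 2)
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    else:
        a, b = v1 / n1, v2 / n2
        se = math.sqrt(a + b)
        if a + b == 0:
            df = float(n1 + n2 - 2)
        else:
            df = (a + b) ** 2 / (a * a / (n1 - 1) + b * b / (n2 - 1))
    if se == 0:
        t = 0.0 if m1 == m2 else math.copysign(math.inf, m1 - m2)
        p = 1.0 if m1 == m2 else 0.0
    else:
        t = (m1 - m2) / se
        p = 2.0 * float(sps.t.sf(abs(t), df))
    return TestResult(t_statistic=float(t), df=float(df), method=method,
                      p_two_sided=float(p), variance_test_p=float(var_p),
                      significant=p <= 0.05)


def two_sample_t_from_samples(x: Sequence[float], y: Sequence[float],
                              method: str | None = None) -> TestResult:
    """Summarize each sample (mean, sample SD) and delegate to the summary test."""
    g1 = GroupSummary.from_samples(x)
    g2 = GroupSummary.from_samples(y)
    return two_sample_t_from_summary(g1.mean, g1.sd, g1.n, g2.mean, g2.sd, g2.n,
                                     method=method)


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def rank_auc(values: np.ndarray, is_positive: np.ndarray) -> float:
    """Midrank Mann-Whitney AUC for 'higher value indicates positive'."""
    ranks = sps.rankdata(values)
    n_pos = int(is_positive.sum())
    n_neg = int(is_positive.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise InputError("both classes must be present")
    r_pos = ranks[is_positive].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_analysis(values: Sequence[float], labels: Sequence[str],
                 positive_class: str = "malignant") -> RocResult:
    """Empirical ROC analysis with Youden-optimal cut-off.

    The orientation is chosen so AUC >= 0.5 and recorded as the inequality
    that flags the positive (malignant) class; the decision rule is inclusive
    of the boundary on the malignant side (value >= cutoff for '>', value <=
    cutoff for '<').  Youden ties break toward higher specificity, then
    deterministically toward the more extreme threshold.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    is_pos = labels == positive_class
    if is_pos.all() or not is_pos.any():
        raise InputError("roc_analysis needs both classes present")
    auc_raw = rank_auc(values, is_pos)
    orientation = ">" if auc_raw >= 0.5 else "<"
    auc = auc_raw if auc_raw >= 0.5 else 1.0 - auc_raw

    n_pos = int(is_pos.sum())
    n_neg = int(is_pos.size - n_pos)
    best = None
    for t in np.unique(values):
        called_pos = values >= t if orientation == ">" else values <= t
        sens = float((called_pos & is_pos).sum() / n_pos)
        spec = float((~called_pos & ~is_pos).sum() / n_neg)
        j = sens + spec - 1.0
        key = (j, spec, t if orientation == ">" else -t)
        if best is None or key > best[0]:
            best = (key, t, sens, spec)
    _, cutoff, sens, spec = best
    return RocResult(auc=float(auc), orientation=orientation, cutoff=float(cutoff),
                     sensitivity=sens, specificity=spec)


def roc_curve_points(values: Sequence[float], labels: Sequence[str],
                     positive_class: str = "malignant",
                     orientation: str = ">") -> tuple[np.ndarray, np.ndarray]:
    """(FPR, TPR) points of the empirical ROC curve, from (0,0) to (1,1)."""
    values = np.asarray(values, dtype=float)
    is_pos = np.asarray(labels) == positive_class
    n_pos, n_neg = int(is_pos.sum()), int((~is_pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise InputError("both classes must be present")
    fpr, tpr = [0.0], [0.0]
    thresholds = np.unique(values)
    order = thresholds[::-1] if orientation == ">" else thresholds
    for t in order:
        called = values >= t if orientation == ">" else values <= t
        tpr.append(float((called & is_pos).sum() / n_pos))
        fpr.append(float((called & ~is_pos).sum() / n_neg))
    fpr.append(1.0)
    tpr.append(1.0)
    return np.array(fpr), np.array(tpr)


# ---------------------------------------------------------------------------
# sample size
# ---------------------------------------------------------------------------

def sample_size_two_means(delta: float, sd: float, alpha: float = 0.05,
                          power: float = 0.80) -> int:
    """Per-group n to detect a mean difference ``delta`` at the given SD.

    Standard normal-approximation formula
    n = ceil(2 * sd^2 * (z_{1-alpha/2} + z_{1-beta})^2 / delta^2), floored
    at 2 per group.
    """
    if delta <= 0:
        raise InputError("delta must be positive")
    if sd <= 0:
        raise InputError("sd must be positive")
    z_a = sps.norm.ppf(1.0 - alpha / 2.0)
    z_b = sps.norm.ppf(power)
    n = math.ceil(2.0 * sd * sd * (z_a + z_b) ** 2 / (delta * delta))
    return max(2, n)


# ---------------------------------------------------------------------------
# cohort-level model
# ---------------------------------------------------------------------------

SPECTRAL_ROWS = {"spectral.iodine_content": "iodine_mg_per_ml",
                 "spectral.slope": "slope"}

REPORT_COLUMNS = [
    "feature", "energy_keV",
    "benign_n", "benign_mean", "benign_sd",
    "malignant_n", "malignant_mean", "malignant_sd",
    "method", "t", "df", "p",
    "cutoff_direction", "cutoff", "sensitivity_pct", "specificity_pct", "auc",
]


class CohortComparison:
    """Benign-vs-malignant comparison of every feature at every energy.

    Parameters
    ----------
    feature_table : DataFrame
        Wide table with columns nodule_id, label, energy_keV and the 41
        feature columns (``<family>.<name>``).
    spectral_table : DataFrame, optional
        Per-nodule spectral quantities (nodule_id, label, iodine_mg_per_ml,
        slope, ...); adds the iodine-content and slope rows to the report.
    positive_class : str
        Label treated as the ROC positive class (default ``'malignant'``).
    """

    def __init__(self, feature_table: pd.DataFrame,
                 spectral_table: pd.DataFrame | None = None,
                 positive_class: str = "malignant",
                 negative_class: str = "benign"):
        self.feature_table = feature_table
        self.spectral_table = spectral_table
        self.positive_class = positive_class
        self.negative_class = negative_class
        for df, what in ((feature_table, "feature table"),):
            if df is not None and "label" not in df.columns:
                raise InputError(f"{what} needs a 'label' column")
        labels = set(feature_table["label"].unique())
        missing = {positive_class, negative_class} - labels
        if missing:
            raise InputError(f"feature table lacks class(es) {sorted(missing)}")
        counts = feature_table.groupby("label")["nodule_id"].nunique()
        if (counts.reindex([positive_class, negative_class]) < 2).any():
            raise InputError("need at least two nodules per class")

    def fit(self, alpha: float = 0.05, both_methods: bool = False,
            fdr: bool = False) -> "CohortComparisonResults":
        """Run the full per-feature-per-energy comparison.

        ``both_methods`` adds pooled and Satterthwaite P values side by side
        (the gate still picks the reported one); ``fdr`` adds a
        Benjamini-Hochberg adjusted column (off by default — the protocol
        reports raw P values).
        """
        rows = []
        for energy, sub in self.feature_table.groupby("energy_keV"):
            for feat in FEATURE_NAMES:
                if feat not in sub.columns:
                    continue
                rows.append(self._compare(feat, float(energy),
                                          sub[feat].to_numpy(float),
                                          sub["label"].to_numpy(), alpha,
                                          both_methods))
        if self.spectral_table is not None:
            for name, col in SPECTRAL_ROWS.items():
                if col not in self.spectral_table.columns:
                    continue
                vals = self.spectral_table[col].to_numpy(float)
                labs = self.spectral_table["label"].to_numpy()
                keep = np.isfinite(vals)
                rows.append(self._compare(name, None, vals[keep], labs[keep],
                                          alpha, both_methods))
        table = pd.DataFrame(rows)
        if fdr and len(table):
            table["p_fdr"] = _benjamini_hochberg(table["p"].to_numpy(float))
        return CohortComparisonResults(self, table, alpha=alpha)

    def _compare(self, feature: str, energy: float | None,
                 values: np.ndarray, labels: np.ndarray, alpha: float,
                 both_methods: bool) -> dict:
        x = values[labels == self.negative_class]
        y = values[labels == self.positive_class]
        if x.size < 2 or y.size < 2:
            raise InputError(f"{feature}: need >= 2 nodules per class")
        g_ben = GroupSummary.from_samples(x)
        g_mal = GroupSummary.from_samples(y)
        test = two_sample_t_from_summary(g_ben.mean, g_ben.sd, g_ben.n,
                                         g_mal.mean, g_mal.sd, g_mal.n)
        roc = roc_analysis(values, labels, positive_class=self.positive_class)
        row = {
            "feature": feature, "energy_keV": energy,
            "benign_n": g_ben.n, "benign_mean": g_ben.mean, "benign_sd": g_ben.sd,
            "malignant_n": g_mal.n, "malignant_mean": g_mal.mean,
            "malignant_sd": g_mal.sd,
            "method": test.method, "t": test.t_statistic, "df": test.df,
            "p": test.p_two_sided,
            "cutoff_direction": roc.orientation, "cutoff": roc.cutoff,
            "sensitivity_pct": 100.0 * roc.sensitivity,
            "specificity_pct": 100.0 * roc.specificity,
            "auc": round(roc.auc, 3),
        }
        if both_methods:
            for m in (POOLED, SATTERTHWAITE):
                row[f"p_{m}"] = two_sample_t_from_summary(
                    g_ben.mean, g_ben.sd, g_ben.n,
                    g_mal.mean, g_mal.sd, g_mal.n, method=m).p_two_sided
        return row


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = n - rank_from_end
        running = min(running, p[idx] * n / rank)
        adj[idx] = running
    return adj


class CohortComparisonResults:
    """Fitted comparison: one row per feature per energy plus spectral rows."""

    def __init__(self, model: CohortComparison, table: pd.DataFrame,
                 alpha: float = 0.05):
        self.model = model
        self.table = table
        self.alpha = alpha

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["p"] <= self.alpha]

    def row(self, feature: str, energy_keV: float | None = None) -> pd.Series:
        t = self.table
        sel = t["feature"] == feature
        if energy_keV is not None:
            sel &= t["energy_keV"] == energy_keV
        else:
            sel &= t["energy_keV"].isna()
        hit = t[sel]
        if hit.empty:
            raise KeyError(f"no report row for {feature!r} at {energy_keV}")
        return hit.iloc[0]

    def summary(self, max_rows: int | None = None) -> str:
        """Human-readable report in the style of a diagnostic-performance table."""
        t = self.table.copy()
        t = t.sort_values(["feature", "energy_keV"], na_position="first")
        if max_rows:
            t = t.head(max_rows)
        lines = [
            "Benign vs malignant group comparison "
            f"(alpha={self.alpha}; raw two-sided P)",
            f"{'feature':<22}{'keV':>5} {'benign mean(SD)':>20} "
            f"{'malig mean(SD)':>20} {'method':>14} {'P':>8} "
            f"{'cutoff':>12} {'sens%':>6} {'spec%':>6} {'AUC':>6}",
        ]
        for _, r in t.iterrows():
            kev = "" if pd.isna(r["energy_keV"]) else f"{r['energy_keV']:.0f}"
            star = "*" if r["p"] <= self.alpha else " "
            lines.append(
                f"{r['feature']:<22}{kev:>5} "
                f"{r['benign_mean']:>11.4g} ({r['benign_sd']:.4g})".ljust(49)
                + f"{r['malignant_mean']:>11.4g} ({r['malignant_sd']:.4g})".rjust(21)
                + f" {r['method']:>14} {r['p']:>7.3f}{star}"
                + f" {r['cutoff_direction']}{r['cutoff']:<11.4g}"
                + f" {r['sensitivity_pct']:>6.1f} {r['specificity_pct']:>6.1f}"
                + f" {r['auc']:>6.3f}"
            )
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.table[
            [c for c in REPORT_COLUMNS if c in self.table.columns]
            + [c for c in self.table.columns if c not in REPORT_COLUMNS]
        ].to_csv(path, index=False)


def build_report(feature_table: pd.DataFrame,
                 spectral_table: pd.DataFrame | None = None,
                 alpha: float = 0.05,
                 both_methods: bool = False) -> pd.DataFrame:
    """One-call report builder: fit a CohortComparison, return its table."""
    model = CohortComparison(feature_table, spectral_table)
    return model.fit(alpha=alpha, both_methods=both_methods).table
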