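"""ΔΔCt relative quantification and group-comparison statistics.

Relative expression follows the comparative-Ct convention: technical Ct
replicates are averaged per (experiment, condition, gene); ΔCt normalizes a
gene to a reference gene within each sample; ΔΔCt compares a test
condition's ΔCt to the control group's mean ΔCt; the fold change is
2^−ΔΔCt.  Fold changes are computed per biological replicate (each
replicate's ΔCt against the control group's mean ΔCt) and summarized as
mean ± sample SD across replicates, matching the way such tables are
conventionally reported.

The comparison harness mirrors a common wet-lab decision tree: Shapiro–Wilk
normality per group; if all groups pass, a Levene (median-centered) check on
variance homogeneity picks between the ordinary and the Welch flavour of the
t-test (two groups) or of one-way ANOVA with Dunnett-style comparisons
against the control (more groups); any non-normal group routes to the
rank-based tests (exact Mann–Whitney, or Kruskal–Wallis with Dunn's
post-hoc).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.oneway import anova_oneway

from .errors import FormatError, InsufficientDataError

logger = logging.getLogger(__name__)

CT_RANGE = (0.0, 45.0)  # plausible PCR cycle numbers, (0, 45]
DEFAULT_REFERENCE_GENE = "RPL37A"
DEFAULT_CONTROL_CONDITION = "M0"
ALPHA_NORMALITY = 0.05
ALPHA_EQUAL_VAR = 0.05

#: significance bands, most stringent first
STAR_BANDS = [(1e-4, "****"), (1e-3, "***"), (5e-3, "**"), (5e-2, "*")]


def significance_stars(p: float) -> str:
    """Map a p-value to the conventional star annotation.

    * p<0.05, ** p<0.005, *** p<0.001, **** p<0.0001.
    """
    for cutoff, stars in STAR_BANDS:
        if p < cutoff:
            return stars
    return ""


# ---------------------------------------------------------------------------
# Ct ingestion and the ΔΔCt chain


def load_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format Ct table (experiment_id, condition, gene, ct)."""
    path = Path(path)
    sep = "\t" if open(path).readline().count("\t") else ","
    df = pd.read_csv(path, sep=sep)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("experiment_id", "condition", "gene", "ct"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    df["ct"] = pd.to_numeric(df["ct"])
    return df


def aggregate_technical(records: pd.DataFrame) -> pd.DataFrame:
    """Average technical Ct replicates per (experiment, condition, gene).

    Returns a frame with columns experiment_id, condition, gene, ct_mean,
    n_technical.  Ct values outside (0, 45] are rejected; a sample with a
    single technical value is accepted with a warning.
    """
    if len(records) == 0:
        raise InsufficientDataError("empty Ct record table")
    bad = records[(records["ct"] <= CT_RANGE[0]) | (records["ct"] > CT_RANGE[1])]
    if len(bad):
        first = bad.iloc[0]
        raise ValueError(
            f"Ct {first['ct']} out of range (0, 45] "
            f"({first['experiment_id']}/{first['condition']}/{first['gene']})"
        )
    grouped = (
        records.groupby(["experiment_id", "condition", "gene"], sort=True)["ct"]
        .agg(ct_mean="mean", n_technical="size", ct_sd=lambda v: v.std(ddof=1))
        .reset_index()
    )
    singles = grouped[grouped["n_technical"] < 2]
    for row in singles.itertuples(index=False):
        logger.warning(
            "no technical replication for %s/%s/%s",
            row.experiment_id,
            row.condition,
            row.gene,
        )
    return grouped


def delta_ct(
    ct_means: pd.DataFrame, reference_gene: str = DEFAULT_REFERENCE_GENE
) -> pd.DataFrame:
    """ΔCt = Ct_mean(gene) − Ct_mean(reference) per (experiment, condition).

    The reference gene's own rows yield ΔCt = 0 exactly.  The reference gene
    must be measured in every (experiment, condition) that carries any gene.
    """
    ref = ct_means[ct_means["gene"] == reference_gene].set_index(
        ["experiment_id", "condition"]
    )["ct_mean"]
    out = ct_means.copy()
    keys = list(zip(out["experiment_id"], out["condition"]))
    missing = sorted({k for k in keys if k not in ref.index})
    if missing:
        raise InsufficientDataError(
            f"reference gene {reference_gene!r} not measured in "
            f"{missing[0][0]}/{missing[0][1]}"
        )
    out["delta_ct"] = out["ct_mean"].to_numpy() - ref.loc[keys].to_numpy()
    out.loc[out["gene"] == reference_gene, "delta_ct"] = 0.0
    return out


@dataclasses.dataclass
class FoldChangeSummary:
    """Per-replicate 2^−ΔΔCt fold changes and their mean ± SD."""

    gene: str
    condition: str
    folds: np.ndarray  # one per biological replicate of the test group
    control_condition: str = DEFAULT_CONTROL_CONDITION

    @property
    def mean(self) -> float:
        return float(np.mean(self.folds))

    @property
    def sd(self) -> float:
        return float(np.std(self.folds, ddof=1)) if len(self.folds) > 1 else float("nan")

    @property
    def n(self) -> int:
        return len(self.folds)


def fold_change(
    test_dcts: Sequence[float] | pd.Series,
    control_dcts: Sequence[float] | pd.Series,
    gene: str = "",
    condition: str = "",
    control_condition: str = DEFAULT_CONTROL_CONDITION,
) -> FoldChangeSummary:
    """2^−ΔΔCt fold changes of a test group against a control group.

    For each biological replicate r of the test group,
    fold_r = 2^−(ΔCt_r − mean ΔCt of the control group); the summary is the
    mean ± sample SD of those per-replicate folds.
    """
    test = np.asarray(test_dcts, dtype=float)
    control = np.asarray(control_dcts, dtype=float)
    if len(test) == 0 or len(control) == 0:
        raise InsufficientDataError("fold change needs non-empty test and control groups")
    ddct = test - control.mean()
    return FoldChangeSummary(
        gene=gene,
        condition=condition,
        folds=np.power(2.0, -ddct),
        control_condition=control_condition,
    )


def suppression_ratio(
    fold_vehicle: FoldChangeSummary | float, fold_compound: FoldChangeSummary | float
) -> float:
    """Ratio of the vehicle-treated to the compound-treated mean fold change.

    A value above 1 means the compound suppressed the gene's induction (e.g.
    a ratio of 110 is a 110-fold suppression); below 1 means it activated
    further.
    """
    num = fold_vehicle.mean if isinstance(fold_vehicle, FoldChangeSummary) else float(fold_vehicle)
    den = fold_compound.mean if isinstance(fold_compound, FoldChangeSummary) else float(fold_compound)
    if den == 0:
        raise ZeroDivisionError("compound mean fold change is zero")
    return num / den


# ---------------------------------------------------------------------------
# test selection and execution


@dataclasses.dataclass
class TestSpec:
    """Outcome of the test-selection decision tree."""

    test: str  # t_test | welch_t_test | anova | welch_anova | mann_whitney | kruskal_wallis
    correction: str  # none | dunnett | dunnett_t3 | dunn_holm
    all_normal: bool
    equal_variance: bool | None
    normality_p: dict[str, float]
    equal_variance_p: float | None


def select_test(groups: Mapping[str, Sequence[float]]) -> TestSpec:
    """Choose the comparison test for 2+ groups of replicate values.

    Shapiro–Wilk per group (α = 0.05) decides parametric vs rank-based;
    among parametric paths, median-centered Levene (α = 0.05) decides plain
    vs Welch.  Groups need at least 3 values for the normality assessment.
    """
    if len(groups) < 2:
        raise InsufficientDataError("need at least two groups to compare")
    for label, vals in groups.items():
        if len(vals) < 3:
            raise InsufficientDataError(
                f"insufficient replicates for normality assessment in group "
                f"{label!r} (n={len(vals)} < 3)"
            )
    normality_p: dict[str, float] = {}
    all_normal = True
    for label, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        if np.ptp(arr) == 0:
            # constant group: Shapiro is undefined; treat as non-normal
            normality_p[label] = 0.0
            all_normal = False
            continue
        p = float(stats.shapiro(arr).pvalue)
        normality_p[label] = p
        if p < ALPHA_NORMALITY:
            all_normal = False

    two = len(groups) == 2
    if not all_normal:
        return TestSpec(
            test="mann_whitney" if two else "kruskal_wallis",
            correction="none" if two else "dunn_holm",
            all_normal=False,
            equal_variance=None,
            normality_p=normality_p,
            equal_variance_p=None,
        )

    lev_p = float(stats.levene(*groups.values(), center="median").pvalue)
    equal = lev_p >= ALPHA_EQUAL_VAR
    if two:
        test = "t_test" if equal else "welch_t_test"
        corr = "none"
    else:
        test = "anova" if equal else "welch_anova"
        corr = "dunnett" if equal else "dunnett_t3"
    return TestSpec(
        test=test,
        correction=corr,
        all_normal=True,
        equal_variance=equal,
        normality_p=normality_p,
        equal_variance_p=lev_p,
    )


@dataclasses.dataclass
class ComparisonResult:
    """One tested contrast with its (corrected) p-value and stars."""

    gene: str
    groups: tuple[str, ...]
    test: str
    correction: str
    p_value: float
    stars: str
    omnibus_p: float | None = None


def _dunn_posthoc(
    groups: Mapping[str, np.ndarray], control: str
) -> dict[str, float]:
    """Dunn's rank-sum comparisons of each group against the control.

    Standard z statistic on mean ranks with tie correction; two-sided
    p-values, Holm-adjusted within the family.
    """
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    mean_ranks: dict[str, float] = {}
    start = 0
    for g in labels:
        n_g = len(groups[g])
        mean_ranks[g] = float(ranks[start : start + n_g].mean())
        start += n_g
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    raw: dict[str, float] = {}
    for g in labels:
        if g == control:
            continue
        se = np.sqrt(
            (n_total * (n_total + 1) / 12.0 - tie_term)
            * (1.0 / len(groups[g]) + 1.0 / len(groups[control]))
        )
        z = (mean_ranks[g] - mean_ranks[control]) / se
        raw[g] = 2.0 * float(stats.norm.sf(abs(z)))
    return dict(zip(raw, _holm(list(raw.values()))))


def _holm(pvals: list[float]) -> list[float]:
    """Holm step-down adjustment, preserving input order."""
    m = len(pvals)
    order = np.argsort(pvals)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted.tolist()


def run_comparison(
    groups: Mapping[str, Sequence[float]],
    spec: TestSpec | None = None,
    control: str | None = None,
    gene: str = "",
) -> list[ComparisonResult]:
    """Execute the selected test; returns one result per tested contrast.

    Two-group designs yield one contrast; multi-group designs yield one
    contrast per non-control group against ``control`` (default: the first
    group), corrected as the spec demands.  Degenerate input (all groups
    identical) reports p = 1 with a warning rather than failing.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if spec is None:
        spec = select_test(groups)
    labels = list(groups)
    if control is None:
        control = labels[0]
    others = [g for g in labels if g != control]

    pooled = np.concatenate(list(groups.values()))
    if np.ptp(pooled) == 0:
        warnings.warn("all groups identical: comparison is degenerate, p = 1")
        return [
            ComparisonResult(gene, (control, g), spec.test, spec.correction, 1.0, "")
            for g in others
        ]

    results: list[ComparisonResult] = []
    if spec.test in ("t_test", "welch_t_test"):
        p = float(
            stats.ttest_ind(
                groups[others[0]], groups[control], equal_var=spec.test == "t_test"
            ).pvalue
        )
        results.append(
            ComparisonResult(
                gene, (control, others[0]), spec.test, "none", p, significance_stars(p)
            )
        )
    elif spec.test == "mann_whitney":
        p = float(
            stats.mannwhitneyu(
                groups[others[0]], groups[control], alternative="two-sided"
            ).pvalue
        )
        results.append(
            ComparisonResult(
                gene, (control, others[0]), spec.test, "none", p, significance_stars(p)
            )
        )
    elif spec.test == "anova":
        omnibus = float(stats.f_oneway(*groups.values()).pvalue)
        # Dunnett p-values are evaluated by quasi-Monte-Carlo integration;
        # seed it so results are reproducible run to run
        dun = stats.dunnett(
            *(groups[g] for g in others),
            control=groups[control],
            rng=np.random.default_rng(0),
        )
        for g, p in zip(others, dun.pvalue):
            p = float(p)
            results.append(
                ComparisonResult(
                    gene, (control, g), spec.test, "dunnett", p,
                    significance_stars(p), omnibus_p=omnibus,
                )
            )
    elif spec.test == "welch_anova":
        omnibus = float(anova_oneway(list(groups.values()), use_var="unequal").pvalue)
        raw = [
            float(stats.ttest_ind(groups[g], groups[control], equal_var=False).pvalue)
            for g in others
        ]
        for g, p in zip(others, _holm(raw)):
            results.append(
                ComparisonResult(
                    gene, (control, g), spec.test, "dunnett_t3", p,
                    significance_stars(p), omnibus_p=omnibus,
                )
            )
    elif spec.test == "kruskal_wallis":
        omnibus = float(stats.kruskal(*groups.values()).pvalue)
        for g, p in _dunn_posthoc(groups, control).items():
            results.append(
                ComparisonResult(
                    gene, (control, g), spec.test, "dunn_holm", p,
                    significance_stars(p), omnibus_p=omnibus,
                )
            )
    else:  # pragma: no cover - spec.test is closed over the options above
        raise ValueError(f"unknown test {spec.test!r}")
    return results


# ---------------------------------------------------------------------------
# model / results surface


class RelativeExpressionModel:
    """ΔΔCt relative-quantification model for a long-format Ct table.

    Parameters
    ----------
    ct_records
        DataFrame with columns experiment_id, condition, gene, ct (one row
        per technical replicate), or a path to such a table.
    reference_gene
        Internal reference gene for ΔCt normalization (default RPL37A).
    control_condition
        Condition against which 2^−ΔΔCt fold changes are expressed
        (default M0, the unstimulated state).
    """

    def __init__(
        self,
        ct_records: pd.DataFrame | str | Path,
        reference_gene: str = DEFAULT_REFERENCE_GENE,
        control_condition: str = DEFAULT_CONTROL_CONDITION,
    ) -> None:
        if not isinstance(ct_records, pd.DataFrame):
            ct_records = load_ct_table(ct_records)
        self.ct_records = ct_records
        self.reference_gene = reference_gene
        self.control_condition = control_condition

    def fit(self) -> "RelativeExpressionResults":
        means = aggregate_technical(self.ct_records)
        dct = delta_ct(means, self.reference_gene)
        summaries: dict[tuple[str, str], FoldChangeSummary] = {}
        dct_groups: dict[tuple[str, str], pd.Series] = {}
        for (gene, condition), grp in dct.groupby(["gene", "condition"], sort=True):
            dct_groups[(gene, condition)] = grp.set_index("experiment_id")["delta_ct"]
        for (gene, condition), test in dct_groups.items():
            if gene == self.reference_gene:
                continue
            control = dct_groups.get((gene, self.control_condition))
            if control is None:
                raise InsufficientDataError(
                    f"control condition {self.control_condition!r} missing for "
                    f"gene {gene!r}"
                )
            summaries[(gene, condition)] = fold_change(
                test, control, gene=gene, condition=condition,
                control_condition=self.control_condition,
            )
        return RelativeExpressionResults(self, dct, summaries)


class RelativeExpressionResults:
    """Fitted fold changes with comparison and suppression accessors."""

    def __init__(
        self,
        model: RelativeExpressionModel,
        delta_ct_table: pd.DataFrame,
        summaries: dict[tuple[str, str], FoldChangeSummary],
    ) -> None:
        self.model = model
        self.delta_ct_table = delta_ct_table
        self.summaries = summaries

    @property
    def fold_changes(self) -> pd.DataFrame:
        rows = [
            {
                "gene": s.gene,
                "condition": s.condition,
                "mean_fold": s.mean,
                "sd_fold": s.sd,
                "n": s.n,
            }
            for s in self.summaries.values()
        ]
        return (
            pd.DataFrame(rows)
            .sort_values(["gene", "condition"])
            .reset_index(drop=True)
        )

    def fold(self, gene: str, condition: str) -> FoldChangeSummary:
        return self.summaries[(gene, condition)]

    def suppression(self, gene: str, vehicle: str, compound: str) -> float:
        """Fold-suppression ratio of ``compound`` relative to ``vehicle``."""
        return suppression_ratio(self.fold(gene, vehicle), self.fold(gene, compound))

    def compare(
        self, gene: str, conditions: Sequence[str], control: str | None = None
    ) -> list[ComparisonResult]:
        """Select and run the comparison across conditions for one gene."""
        groups = {c: self.summaries[(gene, c)].folds for c in conditions}
        spec = select_test(groups)
        return run_comparison(groups, spec, control=control, gene=gene)

    def summary(self) -> str:
        lines = [
            "Relative expression (2^-ddCt vs "
            f"{self.model.control_condition}, reference "
            f"{self.model.reference_gene})",
            "=" * 64,
            f"{'gene':<14}{'condition':<18}{'mean fold':>12}{'SD':>10}{'n':>4}",
        ]
        for row in self.fold_changes.itertuples(index=False):
            lines.append(
                f"{row.gene:<14}{row.condition:<18}{row.mean_fold:>12.2f}"
                f"{row.sd_fold:>10.2f}{row.n:>4d}"
            )
        return "\n".join(lines)
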