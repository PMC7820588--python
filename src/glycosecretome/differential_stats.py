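"""Differential testing of glycoform and protein quantitation.

Glycoform-level comparisons use a plain two-sided Student's t-test on
log2-transformed intensities (the convention for intact glycopeptide
quantitation); proteome-level comparisons use an F-test-gated t-test
(pooled variance when the F-test does not reject equal variances, Welch
otherwise), with per-batch p-values combined by Fisher's method and fold
changes averaged on the log2 scale across batches.  Set enrichment uses
the upper-tail hypergeometric test with Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "QuantTable",
    "DifferentialRecord",
    "glycoform_differential",
    "variance_gated_ttest",
    "fisher_combine",
    "batch_fold_change",
    "benjamini_hochberg",
    "enrich_sets",
    "select_secretory_cluster",
    "records_to_frame",
]

logger = logging.getLogger(__name__)

META_COLUMNS = ("genotype", "sex", "region", "batch")


@dataclass
class QuantTable:
    """A feature x sample intensity matrix with sample metadata.

    ``values`` is indexed by feature id (a string or a (protein, site,
    composition) tuple) with one column per sample id; ``meta`` is indexed
    by sample id and carries at least genotype, sex, region and batch.
    Intensities are positive or missing (NaN); zeros are legal but unusual.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids in quantitation table")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate feature ids in quantitation table")
        missing = [s for s in self.values.columns if s not in self.meta.index]
        if missing:
            raise ValueError(f"samples without metadata: {missing}")

    def select_samples(self, selector: "SampleSelector") -> list[str]:
        """Resolve a selector to sample ids.

        A selector is a mapping of metadata column to required value
        (e.g. ``{"genotype": "sTg", "region": "cortex"}``), an explicit
        list of sample ids, or a predicate over metadata rows.
        """
        if callable(selector):
            return [s for s in self.values.columns if selector(self.meta.loc[s])]
        if isinstance(selector, Mapping):
            mask = pd.Series(True, index=self.meta.index)
            for column, value in selector.items():
                mask &= self.meta[column] == value
            return [s for s in self.values.columns if mask.get(s, False)]
        return [s for s in selector]


SampleSelector = Mapping[str, object] | Sequence[str] | Callable[[pd.Series], bool]


@dataclass(frozen=True)
class DifferentialRecord:
    """Per-feature differential test result."""

    feature: object
    log2_fold_change: float
    p_value: float
    significant: bool
    direction: str  # "up", "down", or "none"

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down", "none"):
            raise ValueError(f"invalid direction {self.direction!r}")
        if self.significant and self.direction == "none":
            raise ValueError("significant records must have a direction")


def _student_t_pvalue(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided pooled-variance Student's t p-value with degenerate handling.

    Zero pooled variance: equal means -> p = 1; unequal means -> p = 0
    with a logged warning (an infinitely confident call on noiseless data).
    """
    var_a = np.var(a, ddof=1)
    var_b = np.var(b, ddof=1)
    if var_a == 0.0 and var_b == 0.0:
        if np.mean(a) == np.mean(b):
            return 1.0
        logger.warning("zero variance in both groups with unequal means; p set to 0")
        return 0.0
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)


def glycoform_differential(
    table: QuantTable,
    group_a: SampleSelector,
    group_b: SampleSelector,
    alpha: float = 0.05,
    log_transform: bool = True,
) -> list[DifferentialRecord]:
    """Two-sided Student's t-test per feature between two sample groups.

    Intensities are log2-transformed before testing (set
    ``log_transform=False`` if the table already holds log values);
    ``log2_fold_change = mean(log2 a) - mean(log2 b)``.  Features with
    fewer than two non-missing values in either group are skipped with a
    logged warning.  A record is significant iff ``p < alpha``, and its
    direction follows the sign of the fold change.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    cols_a = table.select_samples(group_a)
    cols_b = table.select_samples(group_b)
    if not cols_a or not cols_b:
        raise ValueError("both sample groups must be non-empty")

    mat_a = table.values[cols_a].to_numpy(dtype=float)
    mat_b = table.values[cols_b].to_numpy(dtype=float)
    if log_transform:
        with np.errstate(divide="ignore", invalid="ignore"):
            mat_a = np.log2(mat_a)
            mat_b = np.log2(mat_b)

    records: list[DifferentialRecord] = []
    ok_a = np.isfinite(mat_a)
    ok_b = np.isfinite(mat_b)
    complete = ok_a.all(axis=1) & ok_b.all(axis=1)

    # vectorised fast path for features with no missing values
    pvals = np.full(len(table.values), np.nan)
    lfcs = np.full(len(table.values), np.nan)
    if complete.any():
        with np.errstate(divide="ignore", invalid="ignore"):
            pvals[complete] = stats.ttest_ind(
                mat_a[complete], mat_b[complete], axis=1, equal_var=True
            ).pvalue
        lfcs[complete] = mat_a[complete].mean(axis=1) - mat_b[complete].mean(axis=1)

    for i, feature in enumerate(table.values.index):
        if complete[i]:
            # nan (0/0 statistic) and exact 0 (infinite t) mark degenerate features
            if np.isfinite(pvals[i]) and pvals[i] > 0.0:
                p = pvals[i]
            else:
                p = _student_t_pvalue(mat_a[i], mat_b[i])
            records.append(_make_record(feature, float(lfcs[i]), float(p), alpha))
            continue
        a = mat_a[i][ok_a[i]]
        b = mat_b[i][ok_b[i]]
        if len(a) < 2 or len(b) < 2:
            logger.warning(
                "feature %r skipped: fewer than 2 values in a group (%d vs %d)",
                feature, len(a), len(b),
            )
            continue
        p = _student_t_pvalue(a, b)
        records.append(_make_record(feature, float(a.mean() - b.mean()), p, alpha))
    return records


def _make_record(feature: object, lfc: float, p: float, alpha: float) -> DifferentialRecord:
    significant = bool(p < alpha)
    if significant:
        direction = "up" if lfc > 0 else "down"
    else:
        direction = "none"
    return DifferentialRecord(feature, lfc, p, significant, direction)


def variance_gated_ttest(
    a: Sequence[float], b: Sequence[float], f_alpha: float = 0.05
) -> float:
    """F-test-gated two-sided t-test p-value.

    A two-sided F-test on the variance ratio decides between the
    pooled-variance Student's t-test (F-test p >= ``f_alpha``) and the
    unequal-variance Welch t-test.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    var_a = np.var(a, ddof=1)
    var_b = np.var(b, ddof=1)
    if var_a == 0.0 and var_b == 0.0:
        return _student_t_pvalue(a, b)
    if var_b == 0.0 or var_a == 0.0:
        f_p = 0.0  # infinite (or zero) variance ratio: clearly unequal
    else:
        f_stat = var_a / var_b
        cdf = stats.f.cdf(f_stat, len(a) - 1, len(b) - 1)
        f_p = 2.0 * min(cdf, 1.0 - cdf)
    equal_var = f_p >= f_alpha
    return float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)


def fisher_combine(pvals: Iterable[float]) -> float:
    """Combine independent p-values by Fisher's method.

    ``X^2 = -2 * sum(ln p_i)`` referred to a chi-square distribution with
    ``2k`` degrees of freedom; returns the upper-tail probability.
    """
    pvals = np.asarray(list(pvals), dtype=float)
    if pvals.size == 0:
        raise ValueError("cannot combine an empty list of p-values")
    if np.any(pvals <= 0.0) or np.any(pvals > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    x2 = -2.0 * np.sum(np.log(pvals))
    return float(stats.chi2.sf(x2, df=2 * pvals.size))


def batch_fold_change(fc_batch1: float, fc_batch2: float) -> float:
    """Combine two batches' fold changes by arithmetic mean on the log2 scale."""
    if not (np.isfinite(fc_batch1) and np.isfinite(fc_batch2)):
        raise ValueError("fold changes must be finite")
    return (fc_batch1 + fc_batch2) / 2.0


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped to [0, 1]."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    if np.any(pvals < 0.0) or np.any(pvals > 1.0):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def enrich_sets(
    foreground: Iterable[object],
    background: Iterable[object],
    annotation_sets: Mapping[str, Iterable[object]],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of annotation sets.

    Each annotation set is intersected with the background universe before
    testing; p-values are BH-adjusted across sets.  Returns a DataFrame
    indexed by set name with columns ``overlap``, ``set_size``, ``p`` and
    ``p_adjusted``.
    """
    background = set(background)
    if not background:
        raise ValueError("background universe is empty")
    foreground = set(foreground)
    if not foreground <= background:
        raise ValueError("foreground must be a subset of the background")

    names, overlaps, sizes, pvals = [], [], [], []
    M, N = len(background), len(foreground)
    for name, members in annotation_sets.items():
        members = set(members) & background
        k = len(foreground & members)
        # P(X >= k) under sampling N of M with len(members) successes
        p = float(stats.hypergeom.sf(k - 1, M, len(members), N))
        names.append(name)
        overlaps.append(k)
        sizes.append(len(members))
        pvals.append(min(p, 1.0))
    adjusted = benjamini_hochberg(pvals) if names else np.array([])
    return pd.DataFrame(
        {"overlap": overlaps, "set_size": sizes, "p": pvals, "p_adjusted": adjusted},
        index=pd.Index(names, name="set"),
    )


def select_secretory_cluster(
    diff_results: Mapping[str, Sequence[DifferentialRecord]],
    pathway_members: Mapping[str, Iterable[object]],
) -> set:
    """Select the secretory protein cluster.

    A protein qualifies when it belongs to at least one of the supplied
    pathways AND is significant in at least one dataset at either level
    (proteome or acetyl stoichiometry).  Feature ids that are (protein,
    site, ...) tuples contribute their protein component.
    """
    in_pathways: set = set()
    for members in pathway_members.values():
        in_pathways |= set(members)
    significant: set = set()
    for records in diff_results.values():
        for record in records:
            if record.significant:
                feat = record.feature
                significant.add(feat[0] if isinstance(feat, tuple) else feat)
    return in_pathways & significant


def records_to_frame(records: Sequence[DifferentialRecord]) -> pd.DataFrame:
    """Tabulate differential records.

    Tuple feature ids of the form (protein, site, composition) are split
    into columns; plain ids go into a single ``feature_id`` column.
    """
    rows = []
    for r in records:
        if isinstance(r.feature, tuple) and len(r.feature) == 3:
            base = {"protein_id": r.feature[0], "site": r.feature[1],
                    "composition": r.feature[2]}
        else:
            base = {"feature_id": r.feature}
        base.update(
            log2fc=r.log2_fold_change, p=r.p_value,
            significant=r.significant, direction=r.direction,
        )
        rows.append(base)
    return pd.DataFrame(rows)
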