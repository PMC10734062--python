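"""Per-contrast fold change, t-tests, DE calling and the 7-region Venn.

DE criteria follow the microarray convention used throughout this package:
a feature is differentially expressed in a contrast when its linear fold
change is >= 2 (up) or <= 0.5 (down) with a two-tailed t-test P < 0.05.
Fold changes are ratios of linear group means; tests run on log2 values.

Differentiation contrasts (CM vs iPSC within a genotype) are paired on cell
line; genotype contrasts (TS vs WT) have no natural pairing and use Welch's
unequal-variance test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import UserError, ValidationError
from .io import ExpressionMatrix

#: smallest representable positive double; reported when a test statistic is
#: infinite (zero within-group variance with a non-zero effect).
MIN_P = float(np.nextafter(0.0, 1.0))


# ---------------------------------------------------------------------------
# Contrasts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Contrast:
    """Group A vs group B over named samples; ``paired`` pairs on line_id."""

    label: str
    group_a: tuple
    group_b: tuple
    paired: bool

    @property
    def samples(self) -> tuple:
        return tuple(self.group_a) + tuple(self.group_b)


def standard_contrasts(m: ExpressionMatrix) -> dict:
    """The three standard two-group comparisons of the study design.

    A: WT-CM vs WT-iPSC (paired on line), B: TS-CM vs TS-iPSC (paired),
    C: TS-CM vs WT-CM (unpaired Welch; genotypes share no lines).
    """
    return {
        "WT_CM_vs_WT_iPSC": Contrast(
            "WT_CM_vs_WT_iPSC",
            tuple(m.samples("WT", "CM")), tuple(m.samples("WT", "iPSC")), True,
        ),
        "TS_CM_vs_TS_iPSC": Contrast(
            "TS_CM_vs_TS_iPSC",
            tuple(m.samples("TS", "CM")), tuple(m.samples("TS", "iPSC")), True,
        ),
        "TS_CM_vs_WT_CM": Contrast(
            "TS_CM_vs_WT_CM",
            tuple(m.samples("TS", "CM")), tuple(m.samples("WT", "CM")), False,
        ),
    }


def _check_groups(m: ExpressionMatrix, group_a, group_b) -> None:
    if not group_a or not group_b:
        raise UserError("both groups must be non-empty")
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise UserError(f"groups overlap: {sorted(overlap)[:3]}")
    missing = [s for s in (*group_a, *group_b) if s not in m.values.columns]
    if missing:
        raise UserError(f"samples not in matrix: {missing[:3]}")


# ---------------------------------------------------------------------------
# Fold change and t-tests
# ---------------------------------------------------------------------------


def fold_change(m: ExpressionMatrix, group_a, group_b) -> pd.Series:
    """Linear fold change mean(A)/mean(B) per feature.

    Log2 matrices are anti-logged first. Post-normalization intensities are
    positive, so a zero denominator mean signals pipeline misuse.
    """
    _check_groups(m, group_a, group_b)
    lin = m.to_linear().values
    mean_a = lin[list(group_a)].mean(axis=1)
    mean_b = lin[list(group_b)].mean(axis=1)
    zero = mean_b.index[mean_b == 0]
    if len(zero):
        raise UserError(f"zero mean intensity in denominator group: {zero[0]!r}")
    return (mean_a / mean_b).rename("fc")


def _pair_by_line(m: ExpressionMatrix, group_a, group_b):
    g = m.sample_groups
    by_line_b = {g.loc[s, "line_id"]: s for s in group_b}
    if len(group_a) != len(group_b) or len(by_line_b) != len(group_b):
        raise UserError("paired test requires equal-size groups with unique lines")
    try:
        ordered_b = [by_line_b[g.loc[s, "line_id"]] for s in group_a]
    except KeyError as exc:
        raise UserError(f"no pairing partner for line {exc.args[0]!r}") from exc
    return list(group_a), ordered_b


def de_test(m: ExpressionMatrix, group_a, group_b, paired: bool) -> pd.Series:
    """Two-tailed Student's t-test P per feature, on log2 values.

    Paired: t on within-line differences, df = n - 1. Unpaired: Welch.
    Degenerate zero-variance features: P = 1 when the observed effect is
    exactly zero, else the smallest representable P.
    """
    _check_groups(m, group_a, group_b)
    if min(len(group_a), len(group_b)) < 2:
        raise UserError("each group needs at least 2 samples for a t-test")
    x = m.to_log2().values
    if paired:
        a_ids, b_ids = _pair_by_line(m, group_a, group_b)
        d = x[a_ids].to_numpy() - x[b_ids].to_numpy()
        n = d.shape[1]
        mean = d.mean(axis=1)
        sd = d.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / (sd / np.sqrt(n))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
        p = np.where(sd == 0, np.where(mean == 0, 1.0, MIN_P), p)
    else:
        a = x[list(group_a)].to_numpy()
        b = x[list(group_b)].to_numpy()
        with warnings.catch_warnings():
            # zero-variance features are handled explicitly below
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
        degenerate = (a.std(axis=1, ddof=1) == 0) & (b.std(axis=1, ddof=1) == 0)
        equal_means = np.isclose(a.mean(axis=1), b.mean(axis=1))
        p = np.where(degenerate, np.where(equal_means, 1.0, MIN_P), p)
    return pd.Series(p, index=x.index, name="p_value")


# ---------------------------------------------------------------------------
# DE calling
# ---------------------------------------------------------------------------


@dataclass
class DEResult:
    """Per-feature fold change, P and call direction for one contrast."""

    contrast: str
    table: pd.DataFrame  # index: feature_id; columns: fc, p_value, direction

    @property
    def features(self) -> pd.Index:
        return self.table.index

    @property
    def up(self) -> set:
        return set(self.table.index[self.table["direction"] == "up"])

    @property
    def down(self) -> set:
        return set(self.table.index[self.table["direction"] == "down"])

    @property
    def called(self) -> set:
        return set(self.table.index[self.table["direction"] != "none"])

    def volcano_data(self) -> pd.DataFrame:
        """log2 FC and -log10 P, the axes of a volcano plot."""
        out = pd.DataFrame(index=self.table.index)
        out["log2_fc"] = np.log2(self.table["fc"])
        out["neg_log10_p"] = -np.log10(self.table["p_value"].clip(lower=MIN_P))
        out["direction"] = self.table["direction"]
        return out


def call_de(
    fc: pd.Series,
    p: pd.Series,
    contrast: str = "",
    fc_hi: float = 2.0,
    fc_lo: float = 0.5,
    alpha: float = 0.05,
    adjust: bool = False,
) -> DEResult:
    """Apply the fold-change + P criteria (inclusive on FC, strict on P).

    up: FC >= fc_hi and P < alpha; down: FC <= fc_lo and P < alpha.
    ``adjust=True`` applies Benjamini-Hochberg before thresholding (off by
    default; the conventional microarray criterion uses raw P).
    """
    if not fc.index.equals(p.index):
        raise UserError("fold-change and p-value vectors are not aligned")
    if (fc <= 0).any():
        raise ValidationError("fold changes must be positive")
    pv = pd.Series(multipletests(p.to_numpy(), method="fdr_bh")[1], index=p.index) if adjust else p
    direction = np.where(
        (fc >= fc_hi) & (pv < alpha), "up",
        np.where((fc <= fc_lo) & (pv < alpha), "down", "none"),
    )
    table = pd.DataFrame(
        {"fc": fc.to_numpy(), "p_value": pv.to_numpy(), "direction": direction},
        index=fc.index,
    )
    table.index.name = "feature_id"
    return DEResult(contrast, table)


def de_analysis(
    m: ExpressionMatrix,
    contrast: Contrast,
    fc_hi: float = 2.0,
    fc_lo: float = 0.5,
    alpha: float = 0.05,
    adjust: bool = False,
) -> DEResult:
    """fold_change + de_test + call_de in one step."""
    fc = fold_change(m, contrast.group_a, contrast.group_b)
    p = de_test(m, contrast.group_a, contrast.group_b, contrast.paired)
    return call_de(fc, p, contrast.label, fc_hi=fc_hi, fc_lo=fc_lo, alpha=alpha, adjust=adjust)


# ---------------------------------------------------------------------------
# Venn partition
# ---------------------------------------------------------------------------

#: lexicographic order of (in A, in B, in C) membership bit-vectors
REGION_ORDER = (
    (False, False, True),
    (False, True, False),
    (False, True, True),
    (True, False, False),
    (True, False, True),
    (True, True, False),
    (True, True, True),
)

DEFAULT_LABELS = {bits: f"Set{i + 1}" for i, bits in enumerate(REGION_ORDER)}


@dataclass
class VennPartition:
    """The seven disjoint regions of three DE sets A, B, C.

    Region keys are membership bit-vectors (in A, in B, in C); ``labels``
    maps them to display names (defaults to lexicographic Set1..Set7 and is
    user-overridable, since any semantic naming of the regions is a
    presentation choice).
    """

    regions: dict  # (bool, bool, bool) -> set of features
    labels: dict = field(default_factory=lambda: dict(DEFAULT_LABELS))

    def named_regions(self) -> dict:
        return {self.labels[bits]: members for bits, members in self.regions.items()}

    def sizes(self) -> dict:
        return {self.labels[bits]: len(self.regions[bits]) for bits in REGION_ORDER}

    def union(self) -> set:
        return set().union(*self.regions.values()) if self.regions else set()


def venn_partition(
    de_a: DEResult, de_b: DEResult, de_c: DEResult, labels: dict | None = None
) -> VennPartition:
    """Partition A∪B∪C into the 7 disjoint Venn regions of three DE calls."""
    if not (de_a.features.equals(de_b.features) and de_a.features.equals(de_c.features)):
        raise UserError("DE results cover different feature universes")
    sets = (de_a.called, de_b.called, de_c.called)
    regions: dict = {bits: set() for bits in REGION_ORDER}
    for f in set().union(*sets):
        bits = tuple(f in s for s in sets)
        regions[bits].add(f)
    if labels is not None:
        missing = set(REGION_ORDER) - set(labels)
        if missing:
            raise UserError(f"label map missing regions: {sorted(missing)}")
        return VennPartition(regions, dict(labels))
    return VennPartition(regions)
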