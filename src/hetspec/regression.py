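"""Binomial regression of class proportions on heterozygosity bin.

For every (mutation class, region, copy number) cell, the count of variants
falling in the class is modelled as a binomial response out of *all* focal
variants in each heterozygosity bin, with the bin index entered as a single
numeric covariate on the logit scale:

    logit P(class | bin b) = intercept + slope · b

The slope is the quantity of interest: it says whether a class becomes
relatively more (positive) or less (negative) likely as local
heterozygosity rises. Because each class is modelled against "everything
else", the 96 fits per (region, copy) are not independent; p-values are
reported raw with no multiplicity correction.

The module follows the statsmodels shape: :class:`TripletSpectrumModel`
is built from a :class:`ClassCountTable` (or directly from focal variants)
and ``fit()`` returns a :class:`TripletSpectrumResults` carrying the slope
estimates, with the cross-region concordance summary and the GC-content
meta-analysis hanging off it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .classes import (
    BASE_CHANGE_TYPES,
    MutationClass,
    class_labels,
    enumerate_classes,
    gc_content,
)
from .selection import FocalVariant

__all__ = [
    "ClassCountTable",
    "SlopeEstimate",
    "GCTrend",
    "ConcordanceSummary",
    "TripletSpectrumModel",
    "TripletSpectrumResults",
    "tabulate_counts",
    "fit_class_regression",
    "slope_table",
    "cross_region_concordance",
    "gc_trend",
]


# ---------------------------------------------------------------------------
# Count table
# ---------------------------------------------------------------------------


@dataclass
class ClassCountTable:
    """Counts of each mutation class per (region, copy_number, het_bin).

    ``counts`` has a (region, copy_number, het_bin) MultiIndex and one column
    per canonical class label (all 96 present, zeros allowed); ``margins``
    are the row totals.
    """

    counts: pd.DataFrame
    n_bins: int = 30

    def __post_init__(self) -> None:
        missing = [c for c in class_labels() if c not in self.counts.columns]
        if missing:
            raise ValueError(f"count table missing class columns: {missing[:5]}")
        self.counts = self.counts[list(class_labels())]

    @property
    def margins(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.counts.index.get_level_values("region")))

    @property
    def copy_numbers(self) -> tuple[int, ...]:
        return tuple(
            sorted(set(self.counts.index.get_level_values("copy_number")))
        )

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def bin_series(
        self, region: str, copy_number: int | None
    ) -> tuple[np.ndarray, pd.DataFrame]:
        """(bins with non-zero margin, per-bin class counts) for one stratum.

        ``copy_number=None`` pools all copy numbers.
        """
        df = self.counts.xs(region, level="region")
        if copy_number is None:
            df = df.groupby(level="het_bin").sum()
        else:
            if copy_number not in df.index.get_level_values("copy_number"):
                return np.array([], dtype=int), df.iloc[0:0]
            df = df.xs(copy_number, level="copy_number")
        margins = df.sum(axis=1)
        df = df.loc[margins > 0]
        return df.index.to_numpy(dtype=int), df

    def proportions_x1000(self) -> pd.DataFrame:
        """Long-form table: proportion of all mutating triplets × 1000."""
        margins = self.margins
        long = (
            self.counts.stack()
            .rename("count")
            .reset_index()
            .rename(columns={"level_3": "class"})
        )
        long.columns = ["region", "copy_number", "het_bin", "class", "count"]
        long["margin"] = margins.loc[
            list(zip(long["region"], long["copy_number"], long["het_bin"]))
        ].to_numpy()
        long["proportion_x1000"] = 1000.0 * long["count"] / long["margin"]
        return long


def tabulate_counts(
    variants: Iterable[FocalVariant], n_bins: int = 30
) -> ClassCountTable:
    """Exact contingency counts of class per (region, copy_number, het_bin)."""
    rows = []
    for v in variants:
        if v.mutation_class is None or v.het_bin is None:
            raise ValueError(
                f"variant {v.chrom}:{v.pos} lacks class or het_bin annotation"
            )
        rows.append((v.region, v.copy_number, v.het_bin, v.mutation_class.label))
    labels = list(class_labels())
    if not rows:
        idx = pd.MultiIndex.from_arrays(
            [[], [], []], names=["region", "copy_number", "het_bin"]
        )
        return ClassCountTable(pd.DataFrame(0, index=idx, columns=labels), n_bins)
    df = pd.DataFrame(rows, columns=["region", "copy_number", "het_bin", "class"])
    pivot = (
        df.groupby(["region", "copy_number", "het_bin", "class"])
        .size()
        .unstack("class", fill_value=0)
        .reindex(columns=labels, fill_value=0)
        .sort_index()
    )
    return ClassCountTable(pivot.astype(np.int64), n_bins)


# ---------------------------------------------------------------------------
# Per-class binomial fits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SlopeEstimate:
    """Per-class logit slope of class proportion on heterozygosity bin."""

    mutation_class: str
    region: str
    copy_number: int | None  # None = pooled over copy numbers
    slope: float
    std_err: float
    intercept: float
    n_trials: int
    status: str = "ok"  # ok | no_successes | all_successes | separation


_SEPARATION_SLOPE = 1e2


def _fit_binomial(bins: np.ndarray, successes: np.ndarray, trials: np.ndarray):
    endog = np.column_stack([successes, trials - successes]).astype(float)
    exog = sm.add_constant(bins.astype(float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(endog, exog, family=sm.families.Binomial())
        return model.fit()


def _fit_gaussian(bins: np.ndarray, successes: np.ndarray, trials: np.ndarray):
    # comparison-only variant: weighted least squares on raw proportions
    props = successes / trials
    exog = sm.add_constant(bins.astype(float))
    return sm.WLS(props, exog, weights=trials.astype(float)).fit()


def fit_class_regression(
    table: ClassCountTable,
    mutation_class: MutationClass | str,
    region: str,
    copy_number: int | None,
    family: str = "binomial",
) -> SlopeEstimate:
    """Maximum-likelihood slope of one class's proportion on bin index.

    Successes are the class counts per bin, trials the bin margins (all
    focal variants in the bin); requires ≥ 2 bins with non-zero margin.
    Degenerate inputs (class never observed, class being every observation,
    or complete separation) are flagged through ``status`` with missing
    estimates rather than silent zeros.
    """
    label = (
        mutation_class.label
        if isinstance(mutation_class, MutationClass)
        else str(mutation_class)
    )
    if label not in table.counts.columns:
        raise KeyError(f"unknown mutation class {label!r}")
    bins, df = table.bin_series(region, copy_number)
    if bins.size < 2:
        raise ValueError(
            f"need ≥ 2 heterozygosity bins with non-zero margin for "
            f"{label}/{region}/copy={copy_number}, got {bins.size}"
        )
    successes = df[label].to_numpy(dtype=np.int64)
    trials = df.sum(axis=1).to_numpy(dtype=np.int64)
    n_trials = int(trials.sum())

    def degenerate(status: str) -> SlopeEstimate:
        return SlopeEstimate(
            label, region, copy_number, float("nan"), float("nan"), float("nan"),
            n_trials, status,
        )

    if successes.sum() == 0:
        return degenerate("no_successes")
    if (successes == trials).all():
        return degenerate("all_successes")
    if family == "binomial":
        try:
            res = _fit_binomial(bins, successes, trials)
        except Exception:
            return degenerate("separation")
        intercept, slope = res.params
        se = res.bse[1]
        if not (np.isfinite(slope) and np.isfinite(se)) or abs(slope) > _SEPARATION_SLOPE:
            return degenerate("separation")
    elif family == "gaussian":
        res = _fit_gaussian(bins, successes, trials)
        intercept, slope = res.params
        se = res.bse[1]
    else:
        raise ValueError(f"unknown family {family!r}")
    return SlopeEstimate(
        label, region, copy_number, float(slope), float(se), float(intercept),
        n_trials, "ok",
    )


def slope_table(
    table: ClassCountTable,
    regions: Sequence[str] | None = None,
    copy_numbers: Sequence[int | None] | None = None,
    family: str = "binomial",
) -> list[SlopeEstimate]:
    """All (class × region × copy number) slope estimates, in deterministic
    order (class, region, copy); per-fit degeneracies propagate as flagged
    rows rather than being dropped."""
    regions = list(regions if regions is not None else table.regions)
    copies: list[int | None] = list(
        copy_numbers if copy_numbers is not None else table.copy_numbers
    )
    out: list[SlopeEstimate] = []
    for label in class_labels():
        for region in regions:
            for copy in copies:
                try:
                    out.append(
                        fit_class_regression(table, label, region, copy, family)
                    )
                except ValueError:
                    out.append(
                        SlopeEstimate(
                            label, region, copy, float("nan"), float("nan"),
                            float("nan"), 0, "too_few_bins",
                        )
                    )
    return out


def slopes_to_frame(slopes: Iterable[SlopeEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "class": s.mutation_class,
                "region": s.region,
                "copy_number": -1 if s.copy_number is None else s.copy_number,
                "slope": s.slope,
                "std_err": s.std_err,
                "intercept": s.intercept,
                "n_trials": s.n_trials,
                "status": s.status,
            }
            for s in slopes
        ]
    )


# ---------------------------------------------------------------------------
# Cross-region concordance
# ---------------------------------------------------------------------------


@dataclass
class ConcordanceSummary:
    """Agreement of per-class slopes across geographical regions."""

    copy_number: int | None
    per_class: pd.DataFrame  # class, n_regions, slope_sd, slope_mean
    pairwise_r: pd.DataFrame  # region × region Pearson r of 96-slope vectors

    @property
    def mean_pairwise_r(self) -> float:
        vals = self.pairwise_r.to_numpy()
        iu = np.triu_indices_from(vals, k=1)
        return float(np.nanmean(vals[iu]))


def cross_region_concordance(
    slopes: Iterable[SlopeEstimate], copy_number: int | None
) -> ConcordanceSummary:
    """Across-region dispersion of each class's slope, plus pairwise Pearson
    correlation of the per-region 96-slope vectors (pairwise-complete)."""
    df = slopes_to_frame(
        [s for s in slopes if s.copy_number == copy_number and s.status == "ok"]
    )
    if df.empty or df["region"].nunique() < 2:
        raise ValueError("need ok slopes from ≥ 2 regions")
    wide = df.pivot(index="class", columns="region", values="slope")
    per_class = pd.DataFrame(
        {
            "n_regions": wide.notna().sum(axis=1),
            "slope_mean": wide.mean(axis=1),
            "slope_sd": wide.std(axis=1, ddof=1),
        }
    ).reset_index()
    pairwise = wide.corr(method="pearson", min_periods=3)
    return ConcordanceSummary(copy_number, per_class, pairwise)


# ---------------------------------------------------------------------------
# GC-content meta-analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GCTrend:
    """Relationship between class slopes and triplet GC content, one per
    central base-change type (16 classes each)."""

    base_change: str
    pearson_r: float
    p_value: float
    intercept: float
    slope_per_gc: float
    n_classes: int


def gc_trend(
    slopes: Iterable[SlopeEstimate],
    copy_number: int | None,
    aggregation: str = "mean",
) -> list[GCTrend]:
    """For each of the six base-change types: average each class's slope
    across regions (unweighted), then correlate the 16 averaged slopes with
    triplet GC content (0–3). Two-sided p-value from the t-distribution with
    n − 2 df; missing class slopes are dropped pairwise-complete with the
    class count reported."""
    if aggregation != "mean":
        raise ValueError("only mean aggregation across regions is supported")
    df = slopes_to_frame(
        [s for s in slopes if s.copy_number == copy_number and s.status == "ok"]
    )
    mean_by_class = (
        df.groupby("class")["slope"].mean() if not df.empty else pd.Series(dtype=float)
    )
    out: list[GCTrend] = []
    for change in BASE_CHANGE_TYPES:
        classes = [c for c in enumerate_classes() if c.base_change == change]
        gc = np.array([gc_content(c) for c in classes], dtype=float)
        vals = np.array(
            [mean_by_class.get(c.label, np.nan) for c in classes], dtype=float
        )
        ok = np.isfinite(vals)
        n = int(ok.sum())
        if n < 3 or np.unique(gc[ok]).size < 2:
            out.append(
                GCTrend(change, float("nan"), float("nan"), float("nan"),
                        float("nan"), n)
            )
            continue
        if np.allclose(vals[ok], vals[ok][0]):
            r, p = 0.0, 1.0
        else:
            r, p = scipy.stats.pearsonr(gc[ok], vals[ok])
        b, a = np.polyfit(gc[ok], vals[ok], 1)  # slope, intercept
        out.append(GCTrend(change, float(r), float(p), float(a), float(b), n))
    return out


def gc_trend_frame(trends: Iterable[GCTrend]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "base_change": t.base_change,
                "n_classes": t.n_classes,
                "pearson_r": t.pearson_r,
                "p_value": t.p_value,
                "intercept": t.intercept,
                "slope_per_gc": t.slope_per_gc,
            }
            for t in trends
        ]
    )


# ---------------------------------------------------------------------------
# Model / Results facade
# ---------------------------------------------------------------------------


class TripletSpectrumModel:
    """Binned binomial model of the 96-class mutation spectrum.

    Parameters
    ----------
    counts :
        Contingency table of class counts per (region, copy number,
        heterozygosity bin).
    family :
        ``"binomial"`` (logit link; the default) or ``"gaussian"`` — a
        weighted least-squares fit on raw proportions retained for
        comparison only.
    """

    def __init__(self, counts: ClassCountTable, family: str = "binomial"):
        if family not in ("binomial", "gaussian"):
            raise ValueError(f"unknown family {family!r}")
        self.counts = counts
        self.family = family

    @classmethod
    def from_variants(
        cls,
        variants: Iterable[FocalVariant],
        n_bins: int = 30,
        family: str = "binomial",
    ) -> "TripletSpectrumModel":
        return cls(tabulate_counts(variants, n_bins), family)

    def fit(
        self,
        regions: Sequence[str] | None = None,
        copy_numbers: Sequence[int | None] | None = None,
    ) -> "TripletSpectrumResults":
        """Fit every per-class regression; ``copy_numbers`` may include
        ``None`` for copies pooled."""
        estimates = slope_table(
            self.counts, regions=regions, copy_numbers=copy_numbers,
            family=self.family,
        )
        return TripletSpectrumResults(self, estimates)


class TripletSpectrumResults:
    """Slope estimates plus the derived summaries."""

    def __init__(self, model: TripletSpectrumModel, slopes: list[SlopeEstimate]):
        self.model = model
        self.slopes = slopes

    @property
    def frame(self) -> pd.DataFrame:
        return slopes_to_frame(self.slopes)

    def cross_region_concordance(
        self, copy_number: int | None = 1
    ) -> ConcordanceSummary:
        return cross_region_concordance(self.slopes, copy_number)

    def gc_trend(self, copy_number: int | None = 1) -> list[GCTrend]:
        return gc_trend(self.slopes, copy_number)

    def mean_slopes(self, copy_number: int | None = None) -> pd.Series:
        """Per-class slope averaged (unweighted) across regions."""
        df = self.frame
        key = -1 if copy_number is None else copy_number
        df = df[(df["copy_number"] == key) & (df["status"] == "ok")]
        return df.groupby("class")["slope"].mean()

    def sign_pattern(self, copy_number: int | None = None) -> pd.DataFrame:
        """Counts of positive/negative mean slopes per base-change type —
        the transition/transversion sign summary."""
        means = self.mean_slopes(copy_number)
        rows = []
        for change in BASE_CHANGE_TYPES:
            labels = [
                c.label for c in enumerate_classes() if c.base_change == change
            ]
            vals = means.reindex(labels).dropna()
            rows.append(
                {
                    "base_change": change,
                    "is_transition": change in ("A>G", "C>T"),
                    "n_classes": len(vals),
                    "n_positive": int((vals > 0).sum()),
                    "n_negative": int((vals < 0).sum()),
                    "mean_slope": float(vals.mean()) if len(vals) else float("nan"),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.frame
        ok = df[df["status"] == "ok"]
        lines = [
            "Triplet mutation spectrum ~ heterozygosity bin "
            f"({self.model.family} family)",
            "=" * 66,
            f"strata fitted: {len(df)}   ok: {len(ok)}   "
            f"flagged: {len(df) - len(ok)}",
            f"total variants in table: {self.model.counts.total}",
            "",
            "Largest positive slopes (pooled mean across regions):",
        ]
        means = self.mean_slopes(
            None if -1 in set(df["copy_number"]) else int(df["copy_number"].min())
        )
        top = means.sort_values(ascending=False)
        for label, val in top.head(5).items():
            lines.append(f"  {label}  {val:+.4f}")
        lines.append("Largest negative slopes:")
        for label, val in top.tail(5).sort_values().items():
            lines.append(f"  {label}  {val:+.4f}")
        lines.append("")
        lines.append(self.sign_pattern(
            None if -1 in set(df["copy_number"]) else int(df["copy_number"].min())
        ).to_string(index=False))
        return "\n".join(lines)
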