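"""Label-free quantitative comparisons of peptide peak areas.

Covers XIC-style peak integration, the prevalence filter (a peptide must
be matched in at least 70 % of samples of one group), lean-vs-DIO
differential statistics with the sign convention that a POSITIVE log2
fold change means a DECREASE in the diet-induced-obese group, and the
fold-over-basal statistic for stimulated-secretion experiments (>2-fold
indicates regulated, vesicular release).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

GROUP_A = "lean"
GROUP_B = "DIO"


@dataclass
class AbundanceMatrix:
    """Peptides x samples peak areas with group and region labels.

    ``areas``: DataFrame indexed by peptide id, one column per sample,
    NaN for missing (not detected).  ``samples``: DataFrame indexed by
    sample id with ``group`` and ``region`` columns.
    """

    areas: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not set(self.areas.columns) <= set(self.samples.index):
            missing = set(self.areas.columns) - set(self.samples.index)
            raise ValueError(f"samples missing from sample sheet: {sorted(missing)}")
        if (self.areas.to_numpy() < 0).any():
            raise ValueError("negative peak areas")

    def regions(self) -> list[str]:
        return sorted(self.samples.loc[self.areas.columns, "region"].unique())

    def subset_region(self, region: str) -> "AbundanceMatrix":
        cols = [c for c in self.areas.columns if self.samples.at[c, "region"] == region]
        return AbundanceMatrix(self.areas[cols], self.samples.loc[cols])

    def group_columns(self, group: str) -> list[str]:
        return [c for c in self.areas.columns if self.samples.at[c, "group"] == group]


def integrate_xic(
    times: np.ndarray,
    mzs: np.ndarray,
    intensities: np.ndarray,
    mz_window: tuple[float, float],
    rt_window: tuple[float, float],
) -> float:
    """Trapezoidal peak area over an m/z and retention-time window.

    Points whose m/z lies outside ``mz_window`` are discarded; the
    remaining intensity trace is integrated over ``rt_window``.  Returns
    0 when fewer than two points remain in the window.
    """
    times = np.asarray(times, dtype=float)
    mzs = np.asarray(mzs, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    keep = (mzs >= mz_window[0]) & (mzs <= mz_window[1])
    keep &= (times >= rt_window[0]) & (times <= rt_window[1])
    t, y = times[keep], intensities[keep]
    if t.size < 2:
        return 0.0
    return float(np.trapezoid(y, t))


def prevalence_filter(m: AbundanceMatrix, min_frac: float = 0.7) -> AbundanceMatrix:
    """Keep peptides matched in >= ``min_frac`` of samples of one group.

    Applied within the matrix as given (one region at a time in the
    standard workflow).  Missing values are absences, not zeros.
    """
    groups = sorted(_groups(m))
    if len(groups) != 2:
        raise ValueError(f"expected exactly two groups, found {groups}")
    keep = pd.Series(False, index=m.areas.index)
    for g in groups:
        cols = m.group_columns(g)
        frac = m.areas[cols].notna().mean(axis=1)
        keep |= frac >= min_frac
    return AbundanceMatrix(m.areas.loc[keep], m.samples)


def _groups(m: AbundanceMatrix) -> list[str]:
    return list(m.samples.loc[m.areas.columns, "group"].unique())


def dio_differential(
    m: AbundanceMatrix,
    group_a: str = GROUP_A,
    group_b: str = GROUP_B,
    test: str = "mannwhitney",
) -> pd.DataFrame:
    """Per-peptide differential statistics between two groups, per region.

    ``log2fc = log2(mean_a / mean_b)`` so that a decrease in group B
    (DIO by default) is POSITIVE.  Group means are arithmetic means of
    the natural-scale areas over non-missing samples.  P-values come
    from a Mann–Whitney U test (or Welch t on log areas with
    ``test='welch'``); Benjamini–Hochberg q-values are computed across
    peptides within each region.  Peptides with fewer than two finite
    values in a group get no p-value; a group that is entirely missing
    yields a NaN log2fc with ``degenerate=True``.
    """
    if test not in ("mannwhitney", "welch"):
        raise ValueError(f"unknown test {test!r}")
    rows = []
    for region in m.regions():
        sub = m.subset_region(region)
        cols_a = sub.group_columns(group_a)
        cols_b = sub.group_columns(group_b)
        for pep in sub.areas.index:
            a = sub.areas.loc[pep, cols_a].dropna().to_numpy(dtype=float)
            b = sub.areas.loc[pep, cols_b].dropna().to_numpy(dtype=float)
            degenerate = a.size == 0 or b.size == 0
            if degenerate:
                log2fc = np.nan
            else:
                log2fc = float(np.log2(a.mean() / b.mean()))
            if a.size >= 2 and b.size >= 2:
                if test == "mannwhitney":
                    p = float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)
                else:
                    p = float(sps.ttest_ind(np.log(a), np.log(b), equal_var=False).pvalue)
            else:
                p = np.nan
            rows.append(
                {
                    "peptide_id": pep,
                    "region": region,
                    "log2fc": log2fc,
                    "p_value": p,
                    "degenerate": degenerate,
                }
            )
    out = pd.DataFrame(rows)
    out["q_value"] = np.nan
    for region in out["region"].unique():
        mask = (out["region"] == region) & out["p_value"].notna()
        if mask.any():
            out.loc[mask, "q_value"] = multipletests(
                out.loc[mask, "p_value"].to_numpy(), method="fdr_bh"
            )[1]
    return out


def fold_over_basal(basal_area: float | None, stimulated_area: float | None) -> float:
    """Stimulated / basal peak-area ratio; NaN when basal is undetected.

    Basal-undetected peptides (common for low-abundance hormones in
    supernatants) yield NaN — a value, not an error.
    """
    if basal_area is None or not np.isfinite(basal_area) or basal_area <= 0:
        return float("nan")
    if stimulated_area is None or not np.isfinite(stimulated_area):
        return float("nan")
    return float(stimulated_area / basal_area)


def secretion_table(records: pd.DataFrame) -> pd.DataFrame:
    """Add a ``fold_over_basal`` column to a basal/stimulated table.

    Expects columns ``peptide_id``, ``region``, ``basal_area``,
    ``stimulated_area`` (NaN for undetected).
    """
    out = records.copy()
    out["fold_over_basal"] = [
        fold_over_basal(b, s)
        for b, s in zip(out["basal_area"], out["stimulated_area"])
    ]
    return out
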