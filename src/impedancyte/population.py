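"""Group-level summaries, transparency-vs-size curves, outlier gating and
group comparisons.

Reproduces the structure of the study's population figures: bar/line charts
of group-mean transparency, per-cell scatter of low- vs high-frequency peak
intensity with outliers circled, and the binned mean-transparency-vs-size
curve overlaid on the scatter.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .features import transparency_column

logger = logging.getLogger(__name__)


def _robust_z(x: np.ndarray) -> np.ndarray | None:
    """Median/MAD z-scores; None when the MAD degenerates to zero."""
    med = np.median(x)
    mad = 1.4826 * np.median(np.abs(x - med))
    if mad == 0:
        return None
    return (x - med) / mad


def summarize_groups(
    features: pd.DataFrame,
    group_col: str = "group",
    transparency_cols: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """One summary row per group: n, mean/median transparency, dispersion,
    mean size proxy and mean estimated diameter.  Group sizes sum to the
    number of accepted events."""
    if features.empty:
        raise ParameterError("no features to summarize")
    if group_col not in features.columns:
        raise ParameterError(f"unknown group column {group_col!r}")
    if transparency_cols is None:
        transparency_cols = tuple(
            c for c in features.columns if c.startswith("transparency_")
        )
    rows = []
    for g, sub in features.groupby(group_col, sort=True):
        row: dict = {"group": g, "n": int(len(sub))}
        for col in transparency_cols:
            x = sub[col].to_numpy(dtype=float)
            x = x[np.isfinite(x)]
            row[f"{col}_mean"] = float(x.mean()) if x.size else np.nan
            row[f"{col}_median"] = float(np.median(x)) if x.size else np.nan
            row[f"{col}_sd"] = float(x.std(ddof=1)) if x.size > 1 else 0.0
            row[f"{col}_iqr"] = (
                float(np.subtract(*np.percentile(x, [75, 25]))) if x.size else np.nan
            )
        row["size_proxy_mean"] = float(sub["size_proxy"].mean())
        d = sub["diameter_um"].to_numpy(dtype=float)
        d = d[np.isfinite(d)]
        row["diameter_um_mean"] = float(d.mean()) if d.size else np.nan
        row["diameter_um_median"] = float(np.median(d)) if d.size else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def transparency_vs_size_curve(
    features: pd.DataFrame,
    n_bins: int = 10,
    transparency_col: str | None = None,
    size_col: str = "size_proxy",
) -> pd.DataFrame:
    """Mean transparency in equal-count (quantile) bins of the size proxy.

    Bins partition the accepted events exactly; if there are fewer events
    than bins the bin count is reduced with a logged warning.  Returns
    ``bin, size_lo, size_hi, size_mean, mean_transparency, n``.
    """
    if transparency_col is None:
        transparency_col = transparency_column(2e7)
    if features.empty:
        raise ParameterError("no features to bin")
    n = len(features)
    if n < n_bins:
        logger.warning("only %d events for %d bins; reducing to %d bins", n, n_bins, n)
        n_bins = n
    size = features[size_col].to_numpy(dtype=float)
    t = features[transparency_col].to_numpy(dtype=float)
    order = np.argsort(size, kind="stable")
    bins = np.array_split(order, n_bins)
    rows = []
    for i, idx in enumerate(bins):
        rows.append(
            {
                "bin": i,
                "size_lo": float(size[idx].min()),
                "size_hi": float(size[idx].max()),
                "size_mean": float(size[idx].mean()),
                "mean_transparency": float(np.nanmean(t[idx])),
                "n": int(idx.size),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class OutlierRule:
    """Quantile gate for interesting phenotypes: large cells (size proxy above
    ``size_quantile`` within their group) that keep a permeable membrane
    (high-frequency transparency below ``permeability_quantile``).  Quantile
    gating within groups makes the rule invariant to global amplitude
    rescaling."""

    size_quantile: float = 0.90
    permeability_quantile: float = 0.10
    min_events: int = 20

    def __post_init__(self) -> None:
        if not (0 < self.size_quantile < 1 and 0 < self.permeability_quantile < 1):
            raise ParameterError("quantiles must lie strictly inside (0, 1)")


def detect_outliers(
    features: pd.DataFrame,
    rule: OutlierRule | None = None,
    transparency_col: str | None = None,
    group_col: str = "group",
) -> pd.DataFrame:
    """Flag events meeting *all* configured criteria within their group.

    Returns the feature rows augmented with ``size_z``, ``permeability_z``
    (robust median/MAD z-scores), per-criterion booleans and the combined
    ``is_outlier_flag``.  Deterministic given data and rule.  A zero-MAD
    feature disables that z-score with a logged warning (the quantile gate
    still applies).
    """
    rule = rule or OutlierRule()
    if transparency_col is None:
        transparency_col = transparency_column(5e6)
    if len(features) < rule.min_events:
        raise ParameterError(
            f"need >= {rule.min_events} accepted events for robust outlier statistics, "
            f"got {len(features)}"
        )
    out = features.copy()
    out["size_z"] = np.nan
    out["permeability_z"] = np.nan
    out["size_criterion"] = False
    out["permeability_criterion"] = False
    for g, sub in features.groupby(group_col, sort=False):
        idx = sub.index
        size = sub["size_proxy"].to_numpy(dtype=float)
        perm = sub[transparency_col].to_numpy(dtype=float)
        for name, x in (("size", size), ("permeability", perm)):
            z = _robust_z(x)
            if z is None:
                logger.warning("zero MAD for %s in group %r; z-scores skipped", name, g)
            else:
                out.loc[idx, f"{name}_z"] = z
        out.loc[idx, "size_criterion"] = size > np.quantile(size, rule.size_quantile)
        out.loc[idx, "permeability_criterion"] = perm < np.quantile(
            perm, rule.permeability_quantile
        )
    out["is_outlier_flag"] = out["size_criterion"] & out["permeability_criterion"]
    return out


def compare_groups(
    features: pd.DataFrame,
    group_a: str,
    group_b: str,
    feature_name: str,
    group_col: str = "group",
    n_boot: int = 2000,
    seed: int = 0,
) -> dict:
    """Two-sided Wilcoxon rank-sum comparison of one feature between groups.

    Returns the two-sided Mann-Whitney p-value, the difference of medians
    (a - b), its seeded percentile-bootstrap 95% CI, and the rank-biserial
    effect size.  Rank-based because per-cell amplitude distributions are
    right-skewed.
    """
    if feature_name not in features.columns:
        raise ParameterError(f"unknown feature {feature_name!r}")
    a = features.loc[features[group_col] == group_a, feature_name].dropna().to_numpy()
    b = features.loc[features[group_col] == group_b, feature_name].dropna().to_numpy()
    if a.size == 0 or b.size == 0:
        raise ParameterError("both groups must be non-empty")
    if np.array_equal(a, b):
        p = 1.0
        u = a.size * b.size / 2.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    diff = float(np.median(a) - np.median(b))
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = np.median(rng.choice(a, a.size)) - np.median(rng.choice(b, b.size))
    ci = tuple(float(v) for v in np.percentile(boots, [2.5, 97.5]))
    effect = float(2.0 * u / (a.size * b.size) - 1.0)  # rank-biserial
    return {
        "group_a": group_a,
        "group_b": group_b,
        "feature": feature_name,
        "n_a": int(a.size),
        "n_b": int(b.size),
        "p_value": float(p),
        "median_difference": diff,
        "median_difference_ci": ci,
        "rank_biserial": effect,
    }


def compare_all_groups(
    features: pd.DataFrame,
    feature_names: tuple[str, ...],
    group_col: str = "group",
    seed: int = 0,
) -> pd.DataFrame:
    """All group pairs x features, with Benjamini-Hochberg adjusted p-values."""
    groups = sorted(features[group_col].unique())
    rows = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1 :]:
            for feat in feature_names:
                res = compare_groups(features, ga, gb, feat, group_col, seed=seed)
                rows.append(res)
    df = pd.DataFrame(rows)
    if not df.empty:
        df["p_adj_bh"] = _benjamini_hochberg(df["p_value"].to_numpy())
    return df


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def scatter_export(
    features: pd.DataFrame,
    x_feature: str = "size_proxy",
    y_feature: str | None = None,
    outliers: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Plot-ready tidy table: group, x, y, outlier flag and diameter per event.

    Defaults reproduce the per-cell scatter axes: x = peak intensity at the
    500 kHz reference (size), y = peak intensity at 5 MHz (membrane
    permeability) when a 5 MHz amplitude column is present.
    """
    if features.empty:
        raise ParameterError("no features to export")
    if y_feature is None:
        y_feature = "amp_rel_2"  # 5 MHz channel in the default panel
    for name in (x_feature, y_feature):
        if name not in features.columns:
            raise ParameterError(f"unknown feature {name!r}")
    out = pd.DataFrame(
        {
            "event_id": features["event_id"].to_numpy(),
            "group": features["group"].to_numpy(),
            "x": features[x_feature].to_numpy(dtype=float),
            "y": features[y_feature].to_numpy(dtype=float),
            "diameter_um": features["diameter_um"].to_numpy(dtype=float),
        }
    )
    if outliers is not None and "is_outlier_flag" in outliers.columns:
        flag_map = dict(zip(outliers["event_id"], outliers["is_outlier_flag"]))
        out["is_outlier_flag"] = [bool(flag_map.get(e, False)) for e in out["event_id"]]
    else:
        out["is_outlier_flag"] = False
    out["x_feature"] = x_feature
    out["y_feature"] = y_feature
    return out
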