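"""Annotation, QC and the statistics layer of a morphometric screen.

The central readout is a heatmap of standardized median differences: for each
(treatment, feature) cell, the difference in medians between the treatment
and the vehicle control, with each feature column scaled to unit variance
across treatments so the colour scale is comparable between features of very
different units.  Significance is assessed per cell with a two-sided
Mann-Whitney U test against the control, Bonferroni-corrected by multiplying
with the number of treatments T (capped at 1).  Supporting views are a
Spearman parameter-correlation map, complete-linkage Euclidean clustering of
heatmap rows/columns, and a Wells/Positions variance-component fit used as a
robustness QC: on a reproducible platform both the well-to-well and the
position-to-position standard deviation stay below the residual noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage

ANNOTATION_COLUMNS = (
    "well",
    "position",
    "cell_line",
    "treatment",
    "concentration",
    "time_point",
)


def annotate(records: pd.DataFrame, plate_map: pd.DataFrame) -> pd.DataFrame:
    """Join per-structure records with the plate annotation by image id.

    Every image id in the records must map to exactly one plate-map row;
    missing or duplicated mappings raise with the offending ids listed.
    """
    if "image_id" not in records.columns or "image_id" not in plate_map.columns:
        raise ValueError("both tables need an 'image_id' column")
    dup = plate_map["image_id"][plate_map["image_id"].duplicated()].unique()
    if len(dup):
        raise ValueError(f"ambiguous plate map: duplicated image ids {sorted(dup)}")
    missing = sorted(set(records["image_id"]) - set(plate_map["image_id"]))
    if missing:
        raise ValueError(f"images missing from plate map: {missing}")
    return records.merge(plate_map, on="image_id", how="left", validate="m:1")


@dataclass
class QCRules:
    """Numeric limits used to discard mis-segmented structures and debris."""

    min_size: float = 0.0
    excluded: list[tuple[str, int]] = field(default_factory=list)  # (image_id, structure_id)
    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.min_size < 0:
            raise ValueError("min_size must be >= 0")


def qc_filter(table: pd.DataFrame, rules: QCRules) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split the table into accepted rows and rejected rows with reason codes.

    A structure is kept when Area >= min_size, every configured feature lies
    inside its [lo, hi] range, and it is not on the excluded-features list.
    """
    reasons = pd.Series("", index=table.index, dtype=object)
    if rules.min_size > 0 and "Area" in table.columns:
        reasons[table["Area"] < rules.min_size] = "min_size"
    for feat, (lo, hi) in rules.ranges.items():
        bad = (table[feat] < lo) | (table[feat] > hi)
        reasons[bad & (reasons == "")] = f"range:{feat}"
    if rules.excluded:
        key = list(zip(table["image_id"], table["structure_id"]))
        excluded = {tuple(e) for e in rules.excluded}
        bad = pd.Series([k in excluded for k in key], index=table.index)
        reasons[bad & (reasons == "")] = "excluded_list"
    rejected = table[reasons != ""].copy()
    rejected["reject_reason"] = reasons[reasons != ""]
    return table[reasons == ""].copy(), rejected


@dataclass
class HeatmapResult:
    """Standardized median differences with Mann-Whitney/Bonferroni filtering."""

    diff: pd.DataFrame            # treatments x features, standardized
    raw_diff: pd.DataFrame        # unstandardized median differences
    p_raw: pd.DataFrame
    p_corrected: pd.DataFrame
    significant: pd.DataFrame     # corrected p < alpha
    alpha: float
    flags: dict[str, str] = field(default_factory=dict)
    row_order: list[int] | None = None
    col_order: list[int] | None = None


def mann_whitney_p(x: np.ndarray, y: np.ndarray, exact_max_n: int = 8) -> float:
    """Two-sided Mann-Whitney U p-value; exact for small tie-free samples."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) <= exact_max_n and len(y) <= exact_max_n and not ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def median_diff_heatmap(
    table: pd.DataFrame,
    features: list[str],
    control_label: str,
    treatment_col: str = "treatment",
    alpha: float = 0.05,
) -> HeatmapResult:
    """Standardized median-difference matrix with Bonferroni-filtered p-values.

    Each feature column of the (treatment x feature) median-difference matrix
    is divided by its sample standard deviation across treatments; corrected
    p = min(1, raw p * T) with T the number of treatments.
    """
    groups = table.groupby(treatment_col, sort=True)
    if control_label not in groups.groups:
        raise ValueError(f"control label {control_label!r} not present")
    control = groups.get_group(control_label)
    if len(control) < 2:
        raise ValueError("control needs at least 2 observations")
    treatments = [t for t in groups.groups if t != control_label]
    if not treatments:
        raise ValueError("no treatments besides the control")
    t_count = len(treatments)

    raw = pd.DataFrame(index=treatments, columns=features, dtype=float)
    p_raw = pd.DataFrame(index=treatments, columns=features, dtype=float)
    flags: dict[str, str] = {}
    for t in treatments:
        g = groups.get_group(t)
        for f in features:
            raw.loc[t, f] = float(g[f].median() - control[f].median())
            p_raw.loc[t, f] = mann_whitney_p(g[f].to_numpy(), control[f].to_numpy())
    diff = raw.copy()
    for f in features:
        sd = float(raw[f].std(ddof=1)) if t_count > 1 else float(abs(raw[f].iloc[0]))
        if sd > 0:
            diff[f] = raw[f] / sd
        else:
            diff[f] = 0.0
            flags[f] = "zero_variance"
    p_corr = (p_raw * t_count).clip(upper=1.0)
    return HeatmapResult(
        diff=diff,
        raw_diff=raw,
        p_raw=p_raw,
        p_corrected=p_corr,
        significant=p_corr < alpha,
        alpha=alpha,
        flags=flags,
    )


def spearman_map(table: pd.DataFrame, features: list[str]) -> pd.DataFrame:
    """Pairwise Spearman rank correlations (average ranks for ties).

    Constant features get correlation 0 against everything (flagged by the
    zero column) but keep a unit diagonal.
    """
    data = table[features].to_numpy(dtype=np.float64)
    if data.shape[0] < 3:
        raise ValueError("need at least 3 observations")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.spearmanr(data, axis=0).statistic
    rho = np.atleast_2d(np.asarray(rho, dtype=np.float64))
    if rho.shape != (len(features), len(features)):  # spearmanr collapses 2 features
        r = rho.item() if rho.size == 1 else rho[0, 1]
        rho = np.array([[1.0, r], [r, 1.0]])
    rho = np.nan_to_num(rho, nan=0.0)
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=features, columns=features)


def cluster(matrix: pd.DataFrame | np.ndarray, axis: int = 0):
    """Complete-linkage Euclidean clustering of rows (axis=0) or columns.

    Returns (leaf order, linkage matrix); a single row clusters trivially.
    """
    arr = matrix.to_numpy(dtype=np.float64) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, dtype=np.float64)
    if axis == 1:
        arr = arr.T
    if arr.shape[0] < 2:
        return list(range(arr.shape[0])), None
    z = linkage(arr, method="complete", metric="euclidean")
    return [int(i) for i in leaves_list(z)], z


@dataclass
class VarianceComponents:
    """REML standard deviations of the Wells / Positions / residual terms."""

    feature: str
    sigma_well: float
    sigma_position: float
    sigma_residual: float
    n_wells: int
    n_positions: int
    n_obs: int

    @property
    def well_to_residual(self) -> float:
        return self.sigma_well / self.sigma_residual if self.sigma_residual > 0 else np.inf

    @property
    def position_to_residual(self) -> float:
        return self.sigma_position / self.sigma_residual if self.sigma_residual > 0 else np.inf


def variance_components(
    table: pd.DataFrame,
    feature: str,
    well_col: str = "well",
    position_col: str = "position",
) -> VarianceComponents:
    """Fit a linear mixed model with Wells and Positions as random effects.

    The model is  y = mu + well + position(well) + noise  with positions
    nested in wells; REML estimation keeps the variance estimates
    non-negative.  Needs >= 3 wells, >= 2 positions per well and >= 2
    observations per position.
    """
    import statsmodels.formula.api as smf

    data = pd.DataFrame(
        {
            "y": table[feature].to_numpy(dtype=np.float64),
            "well": table[well_col].astype(str).to_numpy(),
            "position": table[position_col].astype(str).to_numpy(),
        }
    ).dropna()
    n_wells = data["well"].nunique()
    if n_wells < 3:
        raise ValueError(f"need >= 3 wells, got {n_wells}")
    pos_per_well = data.groupby("well")["position"].nunique()
    if (pos_per_well < 2).any():
        raise ValueError("need >= 2 positions in every well")
    obs_per_pos = data.groupby(["well", "position"]).size()
    if (obs_per_pos < 2).any():
        raise ValueError("need >= 2 observations in every position")

    if float(data["y"].var(ddof=0)) == 0.0:
        return VarianceComponents(
            feature, 0.0, 0.0, 0.0, n_wells, int(pos_per_well.iloc[0]), len(data)
        )

    model = smf.mixedlm(
        "y ~ 1",
        data,
        groups=data["well"],
        re_formula="1",
        vc_formula={"position": "0 + C(position)"},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=True)
    sigma_well = float(np.sqrt(max(0.0, float(res.cov_re.iloc[0, 0]))))
    sigma_pos = float(np.sqrt(max(0.0, float(res.vcomp[0]))))
    sigma_res = float(np.sqrt(max(0.0, float(res.scale))))
    return VarianceComponents(
        feature,
        sigma_well,
        sigma_pos,
        sigma_res,
        n_wells,
        int(pos_per_well.median()),
        len(data),
    )


def plot_heatmap(result: HeatmapResult, path, mask_nonsignificant: bool = False) -> None:
    """Write the standardized median-difference heatmap as a PNG/PDF."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = result.diff.copy()
    if mask_nonsignificant:
        data = data.where(result.significant, 0.0)
    fig, ax = plt.subplots(
        figsize=(1 + 0.5 * data.shape[1], 1 + 0.35 * data.shape[0])
    )
    vmax = float(np.nanmax(np.abs(data.to_numpy()))) or 1.0
    im = ax.imshow(data.to_numpy(dtype=float), cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(data.shape[1]), data.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(data.shape[0]), data.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="standardized median difference")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
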