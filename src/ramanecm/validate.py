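"""Statistical comparison of Raman depth profiles with sectioned assays.

The spectroscopic profile (quasi-continuous in depth) is linearly
interpolated at the biochemical sections' mid-depths, then compared
with the assay values in matching normalization through:

* the squared Pearson correlation R^2;
* the root mean square error of prediction, RMSEP, expressed as a
  percentage of the mean observed value;
* a two-way ANOVA with factors *technique* (Raman vs assay) and
  *depth* (section), type-II sums of squares, alpha = 0.05 — agreement
  between the techniques shows up as a non-significant technique
  effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .phantom import SectionedAssay
from .quantify import DepthProfile, normalize_profile

__all__ = [
    "ValidationReport",
    "pair_profiles",
    "r_squared",
    "rmsep",
    "two_way_anova",
    "validate_constituent",
]

ALPHA = 0.05


@dataclass
class ValidationReport:
    constituent: str
    r_squared: float
    rmsep_percent: float
    anova: pd.DataFrame  # rows: technique, depth, (interaction,) residual
    paired_points: np.ndarray  # (n, 3): depth_mm, raman, assay

    def p_value(self, factor: str) -> float:
        return float(self.anova.loc[factor, "p"])

    def to_row(self) -> dict:
        row = {
            "constituent": self.constituent,
            "r2": self.r_squared,
            "rmsep_percent": self.rmsep_percent,
            "p_technique": self.p_value("technique"),
            "p_depth": self.p_value("depth"),
        }
        row["p_interaction"] = (
            self.p_value("interaction") if "interaction" in self.anova.index
            else float("nan")
        )
        return row


def pair_profiles(raman: DepthProfile, assay: SectionedAssay,
                  constituent: str) -> np.ndarray:
    """Interpolate the Raman profile at assay section mid-depths.

    Returns an (n_sections, 3) array of (depth_mm, raman, assay).
    Section depths outside the profile's depth range are clamped to the
    nearest profile endpoint with a warning.
    """
    if assay.n_sections < 2:
        raise ValueError("need at least two assay sections")
    if constituent not in assay.concentrations:
        raise KeyError(f"assay has no constituent {constituent!r}")
    mids = assay.section_mid_depths_mm
    lo, hi = raman.depths_mm[0], raman.depths_mm[-1]
    if mids[0] < lo or mids[-1] > hi:
        warnings.warn(
            f"assay depths [{mids[0]:.3g}, {mids[-1]:.3g}] mm extend beyond "
            f"the Raman profile range [{lo:.3g}, {hi:.3g}]; clamping",
            stacklevel=2,
        )
    raman_vals = raman.interpolate(mids)
    return np.column_stack([mids, raman_vals, assay.concentrations[constituent]])


def r_squared(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length series of at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant series")
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def rmsep(pred: np.ndarray, obs: np.ndarray) -> float:
    """Root mean square error of prediction as % of the mean observation."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.size < 1:
        raise ValueError("series must be non-empty and of equal length")
    mean_obs = float(obs.mean())
    if mean_obs <= 0:
        raise ValueError("mean of observations must be positive")
    return 100.0 * float(np.sqrt(np.mean((pred - obs) ** 2))) / mean_obs


def two_way_anova(values: np.ndarray, technique: np.ndarray, depth: np.ndarray,
                  include_interaction: bool | None = None) -> pd.DataFrame:
    """Two-factor ANOVA with type-II sums of squares.

    By default the interaction is included only when replicates exist
    (more than one observation in some cell); requesting it explicitly
    on a design with empty cells raises. All-equal responses yield zero
    sums of squares everywhere and p = 1.
    """
    values = np.asarray(values, dtype=float)
    technique = np.asarray(technique)
    depth = np.asarray(depth)
    if not (values.shape == technique.shape == depth.shape):
        raise ValueError("values and factor arrays must have equal shape")
    df = pd.DataFrame({"value": values, "technique": technique, "depth": depth})
    counts = df.groupby(["technique", "depth"], observed=True).size()
    n_cells = df["technique"].nunique() * df["depth"].nunique()
    if df["technique"].nunique() < 2 or df["depth"].nunique() < 2:
        raise ValueError("each factor needs at least two levels")
    has_replicates = bool((counts > 1).any()) and len(counts) == n_cells
    if include_interaction is None:
        include_interaction = has_replicates
    elif include_interaction and len(counts) < n_cells:
        raise ValueError("empty cells: interaction not estimable")

    if np.ptp(values) == 0:
        rows = ["technique", "depth"] + (
            ["interaction"] if include_interaction else []) + ["residual"]
        return pd.DataFrame(
            {"sum_sq": 0.0, "df": np.nan, "F": np.nan, "p": 1.0}, index=rows
        )

    formula = ("value ~ C(technique) * C(depth)" if include_interaction
               else "value ~ C(technique) + C(depth)")
    model = smf.ols(formula, data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # F on zero-SS terms
        table = sm.stats.anova_lm(model, typ=2)
    rename = {
        "C(technique)": "technique",
        "C(depth)": "depth",
        "C(technique):C(depth)": "interaction",
        "Residual": "residual",
    }
    table = table.rename(index=rename).rename(
        columns={"sum_sq": "sum_sq", "df": "df", "F": "F", "PR(>F)": "p"}
    )
    table["p"] = table["p"].fillna(1.0)
    return table[["sum_sq", "df", "F", "p"]]


def validate_constituent(
    raman: DepthProfile,
    assay: SectionedAssay,
    constituent: str,
    scheme: str | None = None,
    anchor_depth_mm: float | None = None,
) -> ValidationReport:
    """Full Raman-vs-assay comparison for one constituent.

    If *scheme* is given, both the Raman profile and the assay sections
    are normalized under it before comparison; the anchor depth is
    resolved to the nearest assay section mid-depth first, since the
    sectioning protocol defines the positions both series share.
    Otherwise both are assumed to be in matching normalization already.
    """
    if assay.n_sections < 2:
        raise ValueError("need at least two assay sections")
    assay_profile = DepthProfile(
        assay.section_mid_depths_mm, assay.concentrations[constituent],
        constituent=constituent,
    )
    if scheme is not None:
        if anchor_depth_mm is not None:
            mids = assay.section_mid_depths_mm
            anchor_depth_mm = float(mids[np.argmin(np.abs(mids - anchor_depth_mm))])
        raman = normalize_profile(raman, scheme, anchor_depth_mm)
        assay_profile = normalize_profile(assay_profile, scheme, anchor_depth_mm)
        assay = SectionedAssay(
            assay.section_mid_depths_mm,
            {constituent: assay_profile.values},
            assay.n_sections,
        )
    paired = pair_profiles(raman, assay, constituent)
    depth, raman_vals, assay_vals = paired.T
    r2 = r_squared(raman_vals, assay_vals)
    err = rmsep(raman_vals, assay_vals)
    values = np.concatenate([raman_vals, assay_vals])
    technique = np.array(["raman"] * len(raman_vals) + ["assay"] * len(assay_vals))
    depth_factor = np.concatenate([np.arange(len(depth))] * 2)
    anova = two_way_anova(values, technique, depth_factor)
    return ValidationReport(constituent, r2, err, anova, paired)
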