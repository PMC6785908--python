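"""Volume/overlap metrics and the statistical comparisons of the pipeline.

Standard tests delegate to scipy.stats; the paired ratio comparison runs on
log-ratios so in-vivo and ex-vivo enter symmetrically, reporting the
geometric mean ratio with its 95% CI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from scipy.spatial import cKDTree

from .core import LabelMap
from .mesh import SurfaceMesh


@dataclass
class CompartmentVolumes:
    """LV compartment volumes in ml (wall = myocardium including scar)."""

    cavity_ml: float
    wall_ml: float
    scar_ml: float

    @property
    def scar_fraction(self) -> float:
        return self.scar_ml / self.wall_ml if self.wall_ml > 0 else 0.0


def voxel_dice(a: np.ndarray, b: np.ndarray) -> float:
    """DICE = 2|A∩B| / (|A|+|B|); both-empty returns 1 with a warning."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a grid")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        warnings.warn("both masks empty; DICE defined as 1")
        return 1.0
    return float(2.0 * np.sum(a & b) / denom)


def compartment_volumes(labels: LabelMap) -> CompartmentVolumes:
    """Voxel counts times voxel volume, in ml."""
    v = labels.voxel_volume_mm3() / 1000.0
    return CompartmentVolumes(
        cavity_ml=float(labels.cavity_mask().sum() * v),
        wall_ml=float(labels.wall_mask().sum() * v),
        scar_ml=float(labels.scar_mask().sum() * v),
    )


def paired_ratio_test(
    x_in: np.ndarray, x_ex: np.ndarray
) -> tuple[float, tuple[float, float], float]:
    """Paired ratio comparison of ex-vivo/in-vivo quantities.

    Per-subject ratios are tested on the log scale (one-sample t against 0);
    returns (geometric mean ratio, 95% CI on the ratio scale, two-tailed p).
    Identical inputs have zero log-ratio variance: the mean ratio is 1 and
    the p-value is returned as NaN with a warning.
    """
    x_in = np.asarray(x_in, dtype=float)
    x_ex = np.asarray(x_ex, dtype=float)
    if x_in.shape != x_ex.shape or x_in.ndim != 1 or len(x_in) < 2:
        raise ValueError("need paired 1-D samples of equal length >= 2")
    if np.any(x_in <= 0) or np.any(x_ex <= 0):
        raise ValueError("ratios require positive quantities")
    logr = np.log(x_ex / x_in)
    n = len(logr)
    mean = logr.mean()
    sd = logr.std(ddof=1)
    ratio = float(np.exp(mean))
    if sd == 0:
        warnings.warn("zero variance of log-ratios; p undefined")
        return ratio, (ratio, ratio), float("nan")
    se = sd / np.sqrt(n)
    tcrit = sps.t.ppf(0.975, n - 1)
    ci = (float(np.exp(mean - tcrit * se)), float(np.exp(mean + tcrit * se)))
    t, p = sps.ttest_1samp(logr, 0.0)
    return ratio, ci, float(p)


def anova_tukey(groups: dict[str, np.ndarray]):
    """One-way ANOVA with Tukey HSD post-hoc comparisons.

    Returns ``(F, (df_between, df_within), p, tukey)`` where ``tukey`` is a
    DataFrame of pairwise mean differences with 95% CIs and p-values.
    All-constant input follows the degenerate path F = 0, p = 1.
    """
    names = list(groups)
    data = [np.asarray(groups[k], dtype=float) for k in names]
    if len(data) < 2 or any(len(d) < 2 for d in data):
        raise ValueError("need >= 2 groups with >= 2 values each")
    k = len(data)
    n = sum(len(d) for d in data)
    dof = (k - 1, n - k)
    if np.ptp(np.concatenate(data)) == 0:
        rows = [
            {"group1": a, "group2": b, "diff": 0.0, "low": 0.0, "high": 0.0, "p": 1.0}
            for i, a in enumerate(names)
            for b in names[i + 1 :]
        ]
        return 0.0, dof, 1.0, pd.DataFrame(rows)
    F, p = sps.f_oneway(*data)
    res = sps.tukey_hsd(*data)
    ci = res.confidence_interval(0.95)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            rows.append(
                {
                    "group1": names[i],
                    "group2": names[j],
                    "diff": float(res.statistic[i, j]),
                    "low": float(ci.low[i, j]),
                    "high": float(ci.high[i, j]),
                    "p": float(res.pvalue[i, j]),
                }
            )
    return float(F), dof, float(p), pd.DataFrame(rows)


def regression(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Simple linear regression: (slope, intercept, R^2, p).

    A constant response returns slope 0 and R^2 = 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        return 0.0, float(y.mean()), 0.0, 1.0
    res = sps.linregress(x, y)
    return (
        float(res.slope),
        float(res.intercept),
        float(res.rvalue**2),
        float(res.pvalue),
    )


def shapiro_wilk(x: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk normality test (W, p); requires n >= 3."""
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("Shapiro-Wilk requires at least 3 observations")
    w, p = sps.shapiro(x)
    return float(w), float(p)


THICKNESS_BINS = ("healthy", "low", "high")


def bin_nodes(scar_flag: np.ndarray, transmurality: np.ndarray) -> np.ndarray:
    """Transmurality bins: healthy (no scar), low (0,0.5], high (0.5,1]."""
    flag = np.asarray(scar_flag, dtype=bool)
    tau = np.asarray(transmurality, dtype=float)
    out = np.where(~flag, "healthy", np.where(tau <= 0.5, "low", "high"))
    return out


def thickness_change_by_bin(
    endo_in: SurfaceMesh,
    endo_ex: SurfaceMesh,
    align=None,
) -> pd.DataFrame:
    """Per-bin proportional wall-thickness change between conditions.

    In-vivo nodes pair to the nearest ex-vivo node after mapping through
    ``align`` (e.g. the landmark rigid transform; None for meshes already in
    a common space); the per-node change is 100 (t_ex - t_in)/t_in and is
    aggregated over the transmurality bins of the *in-vivo* mesh.
    """
    for m, which in ((endo_in, "in-vivo"), (endo_ex, "ex-vivo")):
        for a in ("thickness_mm", "scar_flag", "transmurality"):
            if a not in m.attrs:
                raise ValueError(f"{which} mesh lacks attribute {a!r}")
    pts = endo_in.vertices if align is None else align.apply(endo_in.vertices)
    _, idx = cKDTree(endo_ex.vertices).query(pts)
    t_in = np.asarray(endo_in.attrs["thickness_mm"], dtype=float)
    t_ex = np.asarray(endo_ex.attrs["thickness_mm"], dtype=float)[idx]
    ok = t_in > 0
    delta = np.full(len(t_in), np.nan)
    delta[ok] = 100.0 * (t_ex[ok] - t_in[ok]) / t_in[ok]
    bins = bin_nodes(endo_in.attrs["scar_flag"], endo_in.attrs["transmurality"])
    rows = []
    for b in THICKNESS_BINS:
        sel = (bins == b) & ok
        rows.append(
            {
                "bin": b,
                "n": int(sel.sum()),
                "mean_pct": float(np.mean(delta[sel])) if sel.any() else np.nan,
                "sd_pct": float(np.std(delta[sel], ddof=1)) if sel.sum() > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("bin")
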