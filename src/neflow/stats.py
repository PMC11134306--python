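"""Per-cell encoding models and population/condition-level statistics.

Each cell's standardized Ca trace is regressed (ordinary least squares —
a Gaussian identity-link GLM, forced entry) on four standardized
predictors: local NE, global NE, population (global) Ca, and the
local x global NE interaction:

    Ca_i(t) ~ b1 localNE_i(t) + b2 globalNE_i(t) + b3 globalCa_i(t)
              + b4 localNE_i(t) * globalNE_i(t)

Fits are repeated on all frames and on high/low NE-synchrony frame masks,
and across expanding local-field radii. Cell-level coefficients are tested
against zero (one-sample t) or across drug conditions (two-sample t), and
correlation tables are compared across conditions with a linear mixed model
carrying uncorrelated random intercepts and drug slopes for mouse and cell.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .preprocess import FieldGeometry, TraceSet, TwoChannelMovie, build_fields, extract_traces
from .synchrony import RegimeSegmentation

logger = logging.getLogger(__name__)

COEF_NAMES = ("local_ne", "global_ne", "global_ca", "local_x_global")


@dataclass
class CellModelFit:
    cell: int
    regime: str  # "all" | "high" | "low"
    beta: np.ndarray  # (4,) in COEF_NAMES order
    se: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    n_frames: int
    r2: float
    condition: str = "saline"

    def coef(self, name: str) -> float:
        return float(self.beta[COEF_NAMES.index(name)])

    def pvalue(self, name: str) -> float:
        return float(self.pvalues[COEF_NAMES.index(name)])


@dataclass
class PopulationTest:
    coefficient: str
    kind: str  # "one-sample" | "two-sample"
    mean: float
    se: float
    t: float
    df: int
    p: float


@dataclass
class LMEResult:
    fixed_effect: float
    se: float
    t: float
    df: int
    p: float
    vc: dict[str, float]


def _zs(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def design_matrix(traceset: TraceSet, cell: int) -> np.ndarray:
    """Predictor matrix [localNE, globalNE, globalCa, z(localNE*globalNE)].

    The interaction column is the product of the standardized local and
    global NE traces, itself z-scored over the full run so its scale matches
    the other predictors regardless of the frame mask used in a fit.
    """
    zl = traceset.local_ne[cell]
    zg = traceset.global_ne[cell]
    zp = traceset.pop_ca[cell]
    inter = _zs(zl * zg)
    return np.column_stack([zl, zg, zp, inter])


def fit_cell_glm(
    traceset: TraceSet,
    cell: int,
    frame_mask: np.ndarray | None = None,
    condition: str = "saline",
    regime: str = "all",
) -> CellModelFit:
    """OLS fit of one cell's Ca trace on the four standardized predictors.

    All predictors are always included (forced entry). Raises on fewer than
    40 masked frames or on a rank-deficient design, naming the collinear
    predictor pair.
    """
    X = design_matrix(traceset, cell)
    y = traceset.ca[cell]
    if frame_mask is not None:
        mask = np.asarray(frame_mask, bool)
        X, y = X[mask], y[mask]
    if y.size < 40:
        raise ValueError(f"cell {cell}: only {y.size} frames selected (< 40)")
    Xc = sm.add_constant(X)
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        cmat = np.corrcoef(X.T)
        np.fill_diagonal(cmat, 0)
        i, j = np.unravel_index(np.nanargmax(np.abs(cmat)), cmat.shape)
        raise ValueError(
            f"cell {cell}: rank-deficient design; predictors "
            f"'{COEF_NAMES[i]}' and '{COEF_NAMES[j]}' are collinear "
            f"(r = {cmat[i, j]:.6f})"
        )
    fit = sm.OLS(y, Xc).fit()
    return CellModelFit(
        cell=cell, regime=regime,
        beta=np.asarray(fit.params[1:]),
        se=np.asarray(fit.bse[1:]),
        tvalues=np.asarray(fit.tvalues[1:]),
        pvalues=np.asarray(fit.pvalues[1:]),
        n_frames=int(y.size), r2=float(fit.rsquared),
        condition=condition,
    )


def regime_split_fits(
    traceset: TraceSet,
    regimes: RegimeSegmentation,
    cell: int,
    condition: str = "saline",
    min_frames: int = 40,
) -> dict[str, CellModelFit | None]:
    """Fits on all frames and on the high-/low-synchrony frame masks.

    A regime with fewer than ``min_frames`` frames yields None for that
    regime (logged), never an exception.
    """
    out: dict[str, CellModelFit | None] = {}
    out["all"] = fit_cell_glm(traceset, cell, condition=condition, regime="all")
    for name, mask in (("high", regimes.high), ("low", regimes.low)):
        if mask.sum() < min_frames:
            logger.info("cell %d: %s-synchrony regime has %d frames; fit "
                        "marked missing", cell, name, int(mask.sum()))
            out[name] = None
        else:
            out[name] = fit_cell_glm(traceset, cell, frame_mask=mask,
                                     condition=condition, regime=name)
    return out


def radius_sweep(
    movie: TwoChannelMovie,
    soma_masks: np.ndarray,
    radii_um: np.ndarray,
    frame_mask: np.ndarray | None = None,
    kernel_s: float = 1.0,
) -> pd.DataFrame:
    """Refit the cell GLM with the local field rebuilt at each radius.

    For every radius the annuli (and hence each cell's global field) are
    rebuilt and traces re-extracted; the population mean and SE of the
    local-NE coefficient are tabulated per radius. Radii whose annulus
    cannot be built (smaller than the soma extent) are skipped and logged.

    Returns a tidy frame with columns (radius_um, cell, beta_local, p_local).
    """
    radii = np.asarray(radii_um, float)
    if np.any(np.diff(radii) <= 0):
        raise ValueError("radii must be strictly increasing")
    rows = []
    for r in radii:
        try:
            geom = build_fields(soma_masks, radius_um=r, px_um=movie.px_um)
        except ValueError as e:
            logger.info("radius %.1f um skipped: %s", r, e)
            continue
        ts = extract_traces(movie, geom, kernel_s=kernel_s)
        for i in range(ts.n_cells):
            try:
                fit = fit_cell_glm(ts, i, frame_mask=frame_mask)
            except ValueError as e:
                logger.info("radius %.1f um, cell %d skipped: %s", r, i, e)
                continue
            rows.append({"radius_um": r, "cell": i,
                         "beta_local": fit.coef("local_ne"),
                         "p_local": fit.pvalue("local_ne")})
    return pd.DataFrame(rows)


def radius_profile(sweep: pd.DataFrame) -> pd.DataFrame:
    """Population mean and SE of beta_local per radius."""
    g = sweep.groupby("radius_um")["beta_local"]
    return pd.DataFrame({
        "mean_beta": g.mean(),
        "se_beta": g.std(ddof=1) / np.sqrt(g.count()),
        "n": g.count(),
    }).reset_index()


def population_tests(
    values: np.ndarray,
    coefficient: str = "beta",
    other: np.ndarray | None = None,
) -> PopulationTest:
    """One-sample t vs 0, or pooled two-sample t across conditions.

    Degrees of freedom follow the cell-level convention: n - 1 for the
    one-sample test and n1 + n2 - 2 for the two-sample test. A zero-variance
    sample yields t = NaN (flagged by warning), not an exception downstream.
    """
    a = np.asarray(values, float)
    if a.size < 3:
        raise ValueError("need at least 3 fits per group")
    if other is None:
        if a.std(ddof=1) == 0:
            warnings.warn("zero variance: one-sample t undefined")
            return PopulationTest(coefficient, "one-sample", float(a.mean()),
                                  0.0, float("nan"), a.size - 1, float("nan"))
        t, p = sps.ttest_1samp(a, 0.0)
        se = a.std(ddof=1) / np.sqrt(a.size)
        return PopulationTest(coefficient, "one-sample", float(a.mean()),
                              float(se), float(t), a.size - 1, float(p))
    b = np.asarray(other, float)
    if b.size < 3:
        raise ValueError("need at least 3 fits per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        warnings.warn("zero variance in both groups: two-sample t undefined")
        return PopulationTest(coefficient, "two-sample",
                              float(a.mean() - b.mean()), 0.0, float("nan"),
                              a.size + b.size - 2, float("nan"))
    t, p = sps.ttest_ind(a, b)
    sp = np.sqrt(((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
                 / (a.size + b.size - 2))
    se = sp * np.sqrt(1 / a.size + 1 / b.size)
    return PopulationTest(coefficient, "two-sample",
                          float(a.mean() - b.mean()), float(se), float(t),
                          a.size + b.size - 2, float(p))


def lme_condition_compare(table: pd.DataFrame) -> LMEResult:
    """Mixed model: correlation ~ drug + (drug || mouse) + (drug || cell).

    ``table`` needs columns (value, drug, mouse, cell); ``drug`` is coded 0/1
    or as two labels (the second level in sorted order is the treatment).
    Random effects are uncorrelated intercepts and drug slopes for mouse and
    for cell, fitted as variance components of a single-group mixed model by
    REML. With a single mouse the mouse components are dropped with a
    warning. The reported df uses the observation-level convention n - 2.
    """
    df = table.copy()
    required = {"value", "drug", "mouse", "cell"}
    if not required.issubset(df.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    levels = sorted(df["drug"].unique())
    if len(levels) != 2:
        raise ValueError("need exactly 2 drug conditions")
    df["drug_num"] = (df["drug"] == levels[1]).astype(float)
    n_mice = df["mouse"].nunique()
    vc = {"cell": "0 + C(cell)", "cell_drug": "0 + C(cell):drug_num"}
    if n_mice >= 2:
        vc.update({"mouse": "0 + C(mouse)",
                   "mouse_drug": "0 + C(mouse):drug_num"})
    else:
        warnings.warn("single mouse: mouse-level random effects dropped")
    groups = np.ones(len(df))
    model = sm.MixedLM.from_formula(
        "value ~ drug_num", groups=groups, vc_formula=vc, data=df)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True, method="lbfgs", maxiter=200)
    est = float(fit.fe_params["drug_num"])
    se = float(fit.bse_fe["drug_num"])
    dof = len(df) - 2
    tval = est / se
    p = 2 * sps.t.sf(abs(tval), dof)
    vcomp = {k: float(v) for k, v in
             zip(fit.model.exog_vc.names, np.asarray(fit.vcomp))}
    return LMEResult(fixed_effect=est, se=se, t=float(tval), df=dof,
                     p=float(p), vc=vcomp)


def fits_to_frame(fits: list[CellModelFit]) -> pd.DataFrame:
    """Tidy per-coefficient table of a list of cell fits."""
    rows = []
    for f in fits:
        for k, name in enumerate(COEF_NAMES):
            rows.append({
                "cell": f.cell, "regime": f.regime, "condition": f.condition,
                "coefficient": name, "beta": f.beta[k], "se": f.se[k],
                "t": f.tvalues[k], "p": f.pvalues[k], "n_frames": f.n_frames,
            })
    return pd.DataFrame(rows)
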