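"""The general linear relaxometry model of R1.

Under fast exchange between water pools, the observed longitudinal
relaxation rate is a pool-fraction-weighted sum of pool relaxation rates.
Replacing the unobservable pool fractions with imaging surrogates — MT
saturation for macromolecular content, R2* for iron — gives the voxelwise
linear model

    R1(r) = b0 + b1 * MT(r) + b2 * R2*(r) + eps(r),

with a single set of global coefficients b per subject, estimated by least
squares over all pooled brain voxels (gray or white matter probability
above threshold, CSF probability below threshold).  b0 is the relaxation
rate of free water; b1 carries the macromolecular bound-fraction-times-
relaxivity product; b2 the iron contribution.  A synthetic R1 map is the
model prediction M @ b, and the residuals eps = R1 - M @ b localize what
the global model does not explain (iron-rich deep gray matter, artifacts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .errors import CollinearityError, ValidationError

logger = logging.getLogger(__name__)

#: Condition-number threshold beyond which the design is treated as
#: rank deficient (silent pseudo-inverse answers would mask degenerate input).
CONDITION_LIMIT = 1e8

DEFAULT_COLUMNS = ("intercept", "mt_sat", "r2s")


@dataclass
class ModelMatrix:
    """Design matrix over masked voxels with the spatial bookkeeping.

    Rows are ordered by C-order flat voxel index (deterministic); the first
    column is identically one.  ``index`` maps each row back to its flat
    voxel position on ``grid_shape``.
    """

    X: np.ndarray
    index: np.ndarray                 # flat C-order voxel indices, one per row
    grid_shape: tuple[int, ...]
    column_names: tuple[str, ...] = DEFAULT_COLUMNS
    n_dropped: int = 0

    @property
    def n_voxels(self) -> int:
        return self.X.shape[0]


@dataclass
class FitReport:
    """Agreement between measured and synthesized R1 over a mask."""

    pearson: float
    bias_mean_pct: float              # mean of 100*(measured - synth)/measured
    bias_sd_pct: float
    n_voxels: int
    per_class: dict[str, tuple[float, float, int]] = field(default_factory=dict)
    degenerate: bool = False          # zero-variance input, Pearson undefined


@dataclass
class ModelFit:
    """Least-squares solution of R1 = M @ beta with residual diagnostics."""

    beta: np.ndarray                  # (intercept s^-1, s^-1/p.u., dimensionless)
    column_names: tuple[str, ...]
    matrix: ModelMatrix = field(repr=False)
    residual_map: np.ndarray = field(repr=False)       # s^-1, NaN outside mask
    residual_pct_map: np.ndarray = field(repr=False)   # 100*eps/measured
    pearson: float = np.nan
    n_voxels: int = 0

    @property
    def beta0(self) -> float:
        return float(self.beta[0])


def make_mask(gm_prob: np.ndarray, wm_prob: np.ndarray, csf_prob: np.ndarray,
              gmwm_threshold: float = 0.5, csf_threshold: float = 0.5,
              ) -> np.ndarray:
    """Brain mask for pooling voxels into the fit.

    A voxel is included when its gray *or* white matter probability exceeds
    ``gmwm_threshold`` and its CSF probability is below ``csf_threshold``
    (defaults 0.5; 0.3 reproduces the common display convention and yields
    a superset of the 0.5 mask).
    """
    for name, t in (("gmwm_threshold", gmwm_threshold),
                    ("csf_threshold", csf_threshold)):
        if not (0.0 <= t <= 1.0):
            raise ValidationError(f"{name} must be in [0, 1], got {t}")
    gm = np.asarray(gm_prob, float)
    wm = np.asarray(wm_prob, float)
    csf = np.asarray(csf_prob, float)
    if not (gm.shape == wm.shape == csf.shape):
        raise ValidationError("probability maps must share a grid")
    for arr, name in ((gm, "gm"), (wm, "wm"), (csf, "csf")):
        if np.any(arr < 0) or np.any(arr > 1):
            raise ValidationError(f"{name} probabilities must lie in [0, 1]")
    return ((gm > gmwm_threshold) | (wm > gmwm_threshold)) & (csf < csf_threshold)


def design_from_maps(columns: dict[str, np.ndarray], mask: np.ndarray,
                     ) -> ModelMatrix:
    """Build a design matrix (unity column first) from named regressor maps.

    Voxels inside the mask carrying NaN in any regressor are dropped with a
    logged count.
    """
    mask = np.asarray(mask, bool)
    grid_shape = mask.shape
    for name, m in columns.items():
        if np.asarray(m).shape != grid_shape:
            raise ValidationError(
                f"regressor {name!r} shape {np.asarray(m).shape} does not match "
                f"mask shape {grid_shape}"
            )
    index = np.flatnonzero(mask.ravel(order="C"))
    cols = [np.ones(index.size)]
    for m in columns.values():
        cols.append(np.asarray(m, float).ravel(order="C")[index])
    X = np.column_stack(cols)
    valid = np.all(np.isfinite(X), axis=1)
    n_dropped = int(valid.size - valid.sum())
    if n_dropped:
        logger.warning("design matrix: dropped %d masked voxels with invalid "
                       "regressors", n_dropped)
        X = X[valid]
        index = index[valid]
    return ModelMatrix(X=X, index=index, grid_shape=grid_shape,
                       column_names=("intercept",) + tuple(columns),
                       n_dropped=n_dropped)


def build_design_matrix(mt_sat: np.ndarray, r2s: np.ndarray,
                        mask: np.ndarray) -> ModelMatrix:
    """Standard three-column design: unity, MT saturation (p.u.), R2* (s^-1)."""
    return design_from_maps({"mt_sat": mt_sat, "r2s": r2s}, mask)


def _check_conditioning(X: np.ndarray, column_names: tuple[str, ...]) -> None:
    cond = np.linalg.cond(X)
    if not np.isfinite(cond) or cond > CONDITION_LIMIT:
        # identify the most collinear column pair for the error message
        Xc = X - X.mean(0)
        sd = Xc.std(0)
        sd[sd == 0] = 1.0
        corr = (Xc / sd).T @ (Xc / sd) / max(X.shape[0] - 1, 1)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        raise CollinearityError(
            f"design matrix is rank deficient (condition number {cond:.3g} > "
            f"{CONDITION_LIMIT:.0e}); most collinear columns: "
            f"{column_names[i]!r} and {column_names[j]!r}"
        )


def fit_linear_model(r1_map: np.ndarray, m: ModelMatrix) -> ModelFit:
    """Least-squares fit of the relaxometry model over the masked voxels.

    Solves ``min || R1 - M beta ||^2`` with a QR-type solver; rank-deficient
    designs raise :class:`CollinearityError` naming the collinear columns.
    Rows whose measured R1 is invalid (NaN) are dropped with a logged count.
    """
    r1_flat = np.asarray(r1_map, float).ravel(order="C")
    if r1_flat.size != int(np.prod(m.grid_shape)):
        raise ValidationError(
            f"r1 map size {r1_flat.size} does not match design grid {m.grid_shape}"
        )
    y = r1_flat[m.index]
    valid = np.isfinite(y)
    n_bad = int(valid.size - valid.sum())
    X, index = m.X, m.index
    if n_bad:
        logger.warning("fit_linear_model: dropped %d voxels with invalid R1", n_bad)
        X, index, y = X[valid], index[valid], y[valid]
    if X.shape[0] < X.shape[1]:
        raise ValidationError(
            f"need at least {X.shape[1]} valid voxels, got {X.shape[0]}"
        )
    _check_conditioning(X, m.column_names)

    beta, *_ = scipy.linalg.lstsq(X, y, lapack_driver="gelsy")
    synth = X @ beta
    resid = y - synth

    if np.ptp(y) == 0 or np.ptp(synth) == 0:
        pearson = np.nan
    else:
        pearson = float(np.corrcoef(synth, y)[0, 1])

    grid = m.grid_shape
    residual_map = np.full(int(np.prod(grid)), np.nan)
    residual_map[index] = resid
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(y != 0, 100.0 * resid / y, np.nan)
    residual_pct_map = np.full(int(np.prod(grid)), np.nan)
    residual_pct_map[index] = pct

    fitted = ModelMatrix(X=X, index=index, grid_shape=grid,
                         column_names=m.column_names,
                         n_dropped=m.n_dropped + n_bad)
    return ModelFit(beta=beta, column_names=m.column_names, matrix=fitted,
                    residual_map=residual_map.reshape(grid),
                    residual_pct_map=residual_pct_map.reshape(grid),
                    pearson=pearson, n_voxels=X.shape[0])


def synthesize_r1(m: ModelMatrix, beta: np.ndarray) -> np.ndarray:
    """Synthetic R1 map M @ beta written back to the grid; NaN outside mask."""
    beta = np.asarray(beta, float)
    if beta.size != m.X.shape[1]:
        raise ValidationError(
            f"beta length {beta.size} does not match design columns {m.X.shape[1]}"
        )
    out = np.full(int(np.prod(m.grid_shape)), np.nan)
    out[m.index] = m.X @ beta
    return out.reshape(m.grid_shape)


def evaluate_fit(r1_measured: np.ndarray, r1_synth: np.ndarray,
                 mask: np.ndarray,
                 class_labels: np.ndarray | None = None,
                 class_names: tuple[str, ...] | None = None) -> FitReport:
    """Pearson coefficient and normalized residual summaries over a mask.

    Normalized residuals are 100 * (measured - synthesized) / measured, so
    a positive bias means the model synthesizes *lower* R1 than measured.
    Per-class summaries are computed where ``class_labels`` is given.
    """
    meas = np.asarray(r1_measured, float)
    synth = np.asarray(r1_synth, float)
    mask = np.asarray(mask, bool)
    if not (meas.shape == synth.shape == mask.shape):
        raise ValidationError("maps and mask must share a grid")
    sel = mask & np.isfinite(meas) & np.isfinite(synth)
    if not np.any(sel):
        raise ValidationError("mask selects no valid voxels")
    y, s = meas[sel], synth[sel]

    degenerate = bool(np.ptp(y) == 0 or np.ptp(s) == 0)
    pearson = np.nan if degenerate else float(np.corrcoef(s, y)[0, 1])

    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(y != 0, 100.0 * (y - s) / y, np.nan)
    report = FitReport(
        pearson=pearson,
        bias_mean_pct=float(np.nanmean(pct)),
        bias_sd_pct=float(np.nanstd(pct, ddof=1)) if pct.size > 1 else 0.0,
        n_voxels=int(sel.sum()),
        degenerate=degenerate,
    )
    if class_labels is not None:
        labels = np.asarray(class_labels)[sel]
        uniq = np.unique(labels)
        for lab in uniq:
            name = (class_names[lab] if class_names is not None
                    else str(int(lab)))
            p = pct[labels == lab]
            if p.size:
                sd = float(np.nanstd(p, ddof=1)) if p.size > 1 else 0.0
                report.per_class[name] = (float(np.nanmean(p)), sd, int(p.size))
    return report


def free_water_t1(beta0: float) -> float:
    """Longitudinal relaxation time of free water, T1 = 1/b0, in seconds."""
    if beta0 <= 0:
        raise ValidationError("beta0 must be strictly positive")
    return 1.0 / beta0


def macromolecular_relaxivity(beta1: float, mt_wm: float,
                              bound_fraction: float) -> float:
    """Relaxivity at macromolecular sites implied by the MT term.

    The b1*MT product is the bound-fraction-times-relaxivity contribution;
    re-expressing it per unit bound fraction at a representative white
    matter MT value gives ``beta1 * mt_wm / bound_fraction`` (s^-1).  The
    bound fraction must be supplied (e.g. a calorimetric literature value).
    """
    if not (0.0 < bound_fraction < 1.0):
        raise ValidationError("bound_fraction must be in (0, 1)")
    if mt_wm <= 0:
        raise ValidationError("mt_wm must be strictly positive")
    return beta1 * mt_wm / bound_fraction
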