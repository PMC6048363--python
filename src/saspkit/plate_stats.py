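"""Per-plate normalization of screen readouts.

Two statistics are computed per well:

* **B-score** — residual of a two-way median polish of the plate layout,
  scaled by ``1.4826 x MAD`` of the plate's sample-well residuals.  The
  median polish removes additive row and column artifacts (edge effects,
  dispensing gradients); the MAD scaling makes scores comparable across
  plates.  The polish is fitted on sample wells only; control wells are
  scored through the fitted row/column effects so their fixed positions do
  not bias the positional estimates.
* **NPI** — normalized percent inhibition, an affine rescaling of the raw
  value between the plate's negative-control mean (NPI = 1) and
  positive-control mean (NPI = 0).  Values below 1 therefore indicate
  inhibition relative to the scramble controls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, SampleSizeError

MAD_CONSTANT = 1.4826  # consistency constant for normal data


@dataclass
class MedianPolishFit:
    """Additive decomposition value = overall + row + col + residual."""

    overall: float
    row_effects: np.ndarray
    col_effects: np.ndarray
    residuals: np.ndarray  # NaN where input was missing
    iterations: int
    converged: bool

    def fitted(self) -> np.ndarray:
        return (
            self.overall
            + self.row_effects[:, None]
            + self.col_effects[None, :]
        )


def median_polish(
    values: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> MedianPolishFit:
    """Two-way median polish of a row x column matrix with NaN as missing.

    Alternating row/column median sweeps (rows first) until the change in the
    total absolute residual is <= ``tol`` or ``max_iter`` is reached.

    Raises
    ------
    DegenerateInputError
        If any row or column has fewer than 2 non-missing values.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise DegenerateInputError("median_polish expects a 2-D matrix")
    obs = ~np.isnan(x)
    if (obs.sum(axis=1) < 2).any():
        bad = int(np.where(obs.sum(axis=1) < 2)[0][0])
        raise DegenerateInputError(f"row {bad} has fewer than 2 observed values")
    if (obs.sum(axis=0) < 2).any():
        bad = int(np.where(obs.sum(axis=0) < 2)[0][0])
        raise DegenerateInputError(f"column {bad} has fewer than 2 observed values")

    r = x.copy()
    nrow, ncol = x.shape
    overall = 0.0
    row_eff = np.zeros(nrow)
    col_eff = np.zeros(ncol)
    prev_abs = np.nansum(np.abs(r))
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        rm = np.nanmedian(r, axis=1)
        r -= rm[:, None]
        row_eff += rm
        cm = np.nanmedian(row_eff)  # recentre row effects into the overall
        row_eff -= cm
        overall += cm

        cm_col = np.nanmedian(r, axis=0)
        r -= cm_col[None, :]
        col_eff += cm_col
        cm = np.nanmedian(col_eff)
        col_eff -= cm
        overall += cm

        cur_abs = np.nansum(np.abs(r))
        if abs(prev_abs - cur_abs) <= tol:
            converged = True
            break
        prev_abs = cur_abs

    return MedianPolishFit(
        overall=float(overall),
        row_effects=row_eff,
        col_effects=col_eff,
        residuals=r,
        iterations=iterations,
        converged=converged,
    )


def _plate_matrix(plate: pd.DataFrame, readout: str, roles: tuple[str, ...]):
    """Assemble the row x col value matrix of one plate, masking wells whose
    role is not in ``roles``."""
    nrow = int(plate["row"].max())
    ncol = int(plate["col"].max())
    mat = np.full((nrow, ncol), np.nan)
    sel = plate["well_role"].isin(roles)
    rows = plate.loc[sel, "row"].to_numpy() - 1
    cols = plate.loc[sel, "col"].to_numpy() - 1
    mat[rows, cols] = plate.loc[sel, readout].to_numpy(dtype=float)
    return mat


def b_score(
    plate: pd.DataFrame,
    readout: str,
    fit_on: tuple[str, ...] = ("sample",),
    max_iter: int = 100,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """B-scores for one plate (one plate_id/replicate) and one readout.

    The polish is fitted on the wells whose role is in ``fit_on``; every
    non-empty well is then scored through the fitted effects:
    ``b = residual / (1.4826 * MAD of sample-well residuals)``.

    Returns the plate table with columns ``b`` and ``mad_scale`` appended.

    Raises
    ------
    DegenerateInputError
        If the MAD of the sample-well residuals is zero.
    """
    mat = _plate_matrix(plate, readout, fit_on)
    # rows/columns with no fitted wells (e.g. a dedicated control column) are
    # excluded from the polish; their effects are taken as 0, the neutral
    # value of the median-centred effect estimates
    ok_rows = np.where((~np.isnan(mat)).sum(axis=1) >= 2)[0]
    ok_cols = np.where((~np.isnan(mat)).sum(axis=0) >= 2)[0]
    fit = median_polish(mat[np.ix_(ok_rows, ok_cols)], max_iter=max_iter, tol=tol)
    row_eff = np.zeros(mat.shape[0])
    col_eff = np.zeros(mat.shape[1])
    row_eff[ok_rows] = fit.row_effects
    col_eff[ok_cols] = fit.col_effects

    wells = plate[plate["well_role"] != "empty"].copy()
    ri = wells["row"].to_numpy() - 1
    ci = wells["col"].to_numpy() - 1
    resid = wells[readout].to_numpy(dtype=float) - (
        fit.overall + row_eff[ri] + col_eff[ci]
    )
    sample_resid = resid[wells["well_role"].to_numpy() == "sample"]
    mad = np.median(np.abs(sample_resid - np.median(sample_resid)))
    scale = MAD_CONSTANT * mad
    if scale == 0:
        pid = plate["plate_id"].iloc[0]
        raise DegenerateInputError(
            f"plate {pid}: zero MAD of sample residuals for readout {readout}"
        )
    wells["b"] = resid / scale
    wells["mad_scale"] = scale
    return wells


def b_score_run(
    plates: pd.DataFrame,
    readouts: list[str],
    fit_on: tuple[str, ...] = ("sample",),
) -> pd.DataFrame:
    """B-scores for every (plate, replicate, readout) of a whole run.

    Returns a long table: plate_id, replicate, row, col, well_role, sirna_id,
    gene_id, readout, b.
    """
    out = []
    for (pid, rep), plate in plates.groupby(["plate_id", "replicate"], sort=False):
        for readout in readouts:
            scored = b_score(plate, readout, fit_on=fit_on)
            scored = scored[
                ["plate_id", "replicate", "row", "col", "well_role",
                 "sirna_id", "gene_id", "b"]
            ].copy()
            scored["readout"] = readout
            out.append(scored)
    return pd.concat(out, ignore_index=True)


def npi(plate: pd.DataFrame, readout: str) -> pd.DataFrame:
    """Normalized percent inhibition for one plate and readout.

    ``npi(x) = (x - pos_mean) / (neg_mean - pos_mean)`` with arithmetic means
    of the plate's own control wells, so scramble-like wells score 1 and
    positive-control-like wells score 0.
    """
    neg = plate.loc[plate["well_role"] == "negative_control", readout]
    pos = plate.loc[plate["well_role"] == "positive_control", readout]
    if len(neg) < 2 or len(pos) < 2:
        pid = plate["plate_id"].iloc[0]
        raise SampleSizeError(
            f"plate {pid}: need >=2 negative and >=2 positive control wells"
        )
    neg_mean = float(neg.mean())
    pos_mean = float(pos.mean())
    if neg_mean == pos_mean:
        pid = plate["plate_id"].iloc[0]
        raise DegenerateInputError(f"plate {pid}: control means are equal")
    wells = plate[plate["well_role"] != "empty"].copy()
    wells["npi"] = (wells[readout].to_numpy(dtype=float) - pos_mean) / (
        neg_mean - pos_mean
    )
    wells["neg_mean"] = neg_mean
    wells["pos_mean"] = pos_mean
    return wells


def npi_run(plates: pd.DataFrame, readouts: list[str]) -> pd.DataFrame:
    """NPI for every (plate, replicate, readout) of a run; long format."""
    out = []
    for (pid, rep), plate in plates.groupby(["plate_id", "replicate"], sort=False):
        for readout in readouts:
            scored = npi(plate, readout)
            scored = scored[
                ["plate_id", "replicate", "row", "col", "well_role",
                 "sirna_id", "gene_id", "npi"]
            ].copy()
            scored["readout"] = readout
            out.append(scored)
    return pd.concat(out, ignore_index=True)


def scramble_sd_cutoffs(scramble_bscores, k: float = 2.0) -> tuple[float, float]:
    """Hit cutoffs ``mean +/- k*SD`` of the negative (scramble) control
    B-scores (SD with the n-1 denominator)."""
    x = np.asarray(scramble_bscores, dtype=float)
    if x.size < 3:
        raise SampleSizeError("need >=3 scramble B-scores for SD cutoffs")
    m = float(x.mean())
    sd = float(x.std(ddof=1))
    return (m - k * sd, m + k * sd)
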