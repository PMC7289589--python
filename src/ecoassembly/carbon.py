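"""Biolog EcoPlate carbon-metabolism summaries and SOC mineralization kinetics.

AWCD (average well color development) is the mean blank-corrected OD590
across the 31 substrate wells of an EcoPlate, read at a single timepoint
(96 h by default); the six substrate guilds (carbohydrates, carboxylic
acids, amino acids, polymers, phenolic acids, amines) are averaged
separately as well. Cumulative CO2-C efflux is fit with the first-order
kinetic model C_t = C0·(1 − exp(−k·t)), where C0 (mg kg⁻¹) is the
potentially mineralizable carbon pool and k (day⁻¹) the mineralization
rate constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = ["GUILDS", "BiologPlate", "MineralizationSeries", "awcd",
           "fit_mineralization", "SAMPLING_DAYS"]

GUILDS = ("carbohydrates", "carboxylic_acids", "amino_acids", "polymers",
          "phenolic_acids", "amines")

#: Incubation sampling schedule (days) for the CO2 titration series.
SAMPLING_DAYS = (1, 3, 5, 7, 14, 21, 28, 42, 56, 70, 85, 100)


@dataclass
class BiologPlate:
    """OD590 readings for 31 substrate wells plus a blank, over timepoints.

    ``od590`` is wells × timepoints (columns are hours, increasing);
    ``guilds`` maps each substrate well to one of the six guilds;
    ``blank_id`` names the blank well's row.
    """

    od590: pd.DataFrame
    guilds: pd.Series
    blank_id: str = "blank"

    def __post_init__(self) -> None:
        if self.blank_id not in self.od590.index:
            raise ValueError(f"blank well {self.blank_id!r} missing")
        substrates = [w for w in self.od590.index if w != self.blank_id]
        if len(substrates) != 31:
            raise ValueError(f"expected 31 substrate wells, got {len(substrates)}")
        hours = list(self.od590.columns)
        if any(hours[i] >= hours[i + 1] for i in range(len(hours) - 1)):
            raise ValueError("timepoints must be strictly increasing")
        unknown = set(self.guilds.reindex(substrates)) - set(GUILDS)
        if unknown - {np.nan}:
            raise ValueError(f"unknown guild labels: {unknown}")

    @property
    def substrate_ids(self) -> list[str]:
        return [w for w in self.od590.index if w != self.blank_id]


def awcd(plate: BiologPlate, at_hours: float = 96) -> dict:
    """Whole-plate and per-guild AWCD at one timepoint.

    Per-well value = OD_well − OD_blank, negatives clamped to 0. The
    guild-size-weighted mean of the guild AWCDs equals the whole-plate
    value.
    """
    if at_hours not in plate.od590.columns:
        raise ValueError(
            f"timepoint {at_hours} h not measured; available: {list(plate.od590.columns)}"
        )
    col = plate.od590[at_hours]
    corrected = (col.loc[plate.substrate_ids] - col[plate.blank_id]).clip(lower=0.0)
    per_guild = {
        g: float(corrected[plate.guilds.reindex(corrected.index) == g].mean())
        for g in GUILDS
    }
    return {"awcd_total": float(corrected.mean()), "awcd_per_guild": per_guild}


@dataclass
class MineralizationSeries:
    """Cumulative CO2-C (mg kg⁻¹) over incubation days."""

    t: np.ndarray
    ct: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.ct = np.asarray(self.ct, dtype=float)
        if self.t.shape != self.ct.shape:
            raise ValueError("t and ct must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if (self.ct < 0).any():
            raise ValueError("cumulative CO2-C must be non-negative")
        if np.any(np.diff(self.ct) < 0):
            warnings.warn("cumulative CO2-C decreases at some timepoints "
                          "(measurement noise?)")


def _first_order(t, c0, k):
    return c0 * (1.0 - np.exp(-k * t))


def fit_mineralization(series: MineralizationSeries) -> dict[str, float]:
    """Nonlinear least squares fit of C_t = C0·(1 − exp(−k t)), C0, k > 0.

    Initialization is deterministic: C0 starts at 1.1·max(C_t) and k from a
    log-linear regression of 1 − C_t/C0_init on t, so repeated fits are
    bit-identical.
    """
    t, ct = series.t, series.ct
    if t.size < 4:
        raise ValueError("need at least 4 timepoints")
    c0_init = 1.1 * float(ct.max())
    if c0_init <= 0:
        raise ValueError("all-zero series cannot be fit")
    frac = np.clip(1.0 - ct / c0_init, 1e-12, None)
    slope = np.polyfit(t, np.log(frac), 1)[0]
    k_init = max(-slope, 1e-6)
    try:
        popt, pcov = optimize.curve_fit(
            _first_order, t, ct, p0=[c0_init, k_init],
            bounds=([1e-12, 1e-12], [np.inf, np.inf]), maxfev=10000,
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"mineralization fit did not converge (init C0={c0_init:.3g}, "
            f"k={k_init:.3g}): {exc}"
        ) from exc
    resid = ct - _first_order(t, *popt)
    return {"C0": float(popt[0]), "k": float(popt[1]),
            "residual_norm": float(np.linalg.norm(resid))}
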