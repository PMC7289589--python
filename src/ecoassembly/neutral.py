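"""Sloan neutral community model and Levins' habitat niche breadth.

The Sloan model predicts, for a taxon with mean relative abundance ``p`` in
the metacommunity, its expected occurrence frequency across local
communities of size ``N`` under drift–migration balance with migration rate
``m``: the local relative abundance is Beta(Nmp, Nm(1−p))-distributed and the
taxon is detected when it exceeds the detection limit ``d`` (one read,
d = 1/N, by default). ``m`` is estimated by nonlinear least squares of
observed occupancies against this prediction; higher m means communities are
less dispersal-limited.

Levins' niche breadth B_j = 1 / Σ_i P_ij² where P_ij is the fraction of
OTU j's individuals found in community i; B ranges from 1 (restricted to one
community) to N (spread evenly over N communities).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.proportion import proportion_confint

from .community_io import CommunityTable

__all__ = ["NeutralFit", "NicheBreadthResult", "sloan_predict", "fit_sloan",
           "levins_breadth"]


@dataclass
class NeutralFit:
    """Fitted Sloan neutral model."""

    m: float
    N: float
    r_squared: float
    per_otu: pd.DataFrame  # otu_id-indexed: p, occupancy_obs, occupancy_pred, ci_low, ci_high, within_ci
    n_samples: int

    @property
    def frac_within_ci(self) -> float:
        return float(self.per_otu["within_ci"].mean())


@dataclass
class NicheBreadthResult:
    """Levins breadth per OTU and its per-community average."""

    B: pd.Series       # per OTU
    B_com: pd.Series   # per community: mean B over taxa present there


def sloan_predict(p, N: float, m: float, d: float | None = None):
    """Expected occurrence frequency of a taxon under the neutral model.

    freq = 1 − BetaCDF(d; Nmp, Nm(1−p)), the probability that the local
    relative abundance exceeds the detection limit ``d`` (default 1/N).
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("mean relative abundance p must lie strictly in (0, 1)")
    if N < 1:
        raise ValueError("community size N must be >= 1")
    if not 0 < m <= 1:
        raise ValueError("migration rate m must lie in (0, 1]")
    if d is None:
        d = 1.0 / N
    freq = stats.beta.sf(d, N * m * p, N * m * (1.0 - p))
    return float(freq) if freq.ndim == 0 else freq


def fit_sloan(table: CommunityTable, N: float | None = None,
              d: float | None = None) -> NeutralFit:
    """Fit the migration rate m to observed occupancy–abundance data.

    ``N`` defaults to the (common) per-sample read depth; samples should be
    rarefied to a common depth first. OTUs observed in no sample are
    dropped; an error is raised if every OTU is present in every sample
    (occupancy saturated, m unidentifiable).
    """
    counts = table.counts
    n_samples = counts.shape[1]
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    depths = counts.sum(axis=0)
    if N is None:
        N = float(depths.mean())
        rel = counts / depths
    else:
        # explicit community size: abundances are counts per N individuals,
        # so duplicated identical rows do not perturb the fit
        rel = counts / float(N)
    p = rel.mean(axis=1)
    occ = (counts > 0).sum(axis=1) / n_samples
    keep = (p > 0) & (p < 1)
    p, occ = p[keep], occ[keep]
    if len(p) < 2:
        raise ValueError("too few OTUs with usable abundances")
    if (occ == 1).all():
        raise ValueError("saturated occupancy: every OTU in every sample, m unidentifiable")
    if (0 < (occ < 1).sum() < 20):
        import warnings
        warnings.warn("fewer than 20 partially occupying OTUs; fit may be unstable")

    pv = p.to_numpy()
    ov = occ.to_numpy()

    def sse(m: float) -> float:
        pred = sloan_predict(pv, N, m, d)
        return float(((ov - pred) ** 2).sum())

    # bounded scalar minimization with multi-start against local minima
    best = None
    for lo, hi in [(1e-6, 0.05), (0.02, 0.3), (0.2, 1.0)]:
        res = optimize.minimize_scalar(sse, bounds=(lo, hi), method="bounded")
        if best is None or res.fun < best.fun:
            best = res
    m_hat = float(np.clip(best.x, 1e-9, 1.0))

    pred = sloan_predict(pv, N, m_hat, d)
    sst = float(((ov - ov.mean()) ** 2).sum())
    r2 = 1.0 - best.fun / sst if sst > 0 else np.nan
    ci_low, ci_high = proportion_confint(
        np.round(pred * n_samples), n_samples, alpha=0.05, method="wilson"
    )
    per_otu = pd.DataFrame({
        "p": pv, "occupancy_obs": ov, "occupancy_pred": pred,
        "ci_low": ci_low, "ci_high": ci_high,
        "within_ci": (ov >= ci_low) & (ov <= ci_high),
    }, index=p.index)
    return NeutralFit(m=m_hat, N=N, r_squared=float(r2), per_otu=per_otu,
                      n_samples=n_samples)


def levins_breadth(table: CommunityTable, group=None,
                   within_community: bool = False) -> NicheBreadthResult:
    """Levins' niche breadth B per OTU and community-level average B_com.

    By default P_ij is the fraction of OTU j's individuals found in
    community i (Σ_i P_ij = 1), so 1 ≤ B_j ≤ number of communities.
    ``within_community=True`` instead uses the OTU's proportion within each
    community, normalized across communities.
    OTUs absent from the group are excluded. B_com for community i is the
    unweighted mean of B_j over taxa with nonzero count in i.
    """
    counts = table.counts if group is None else table.counts[list(group)]
    totals = counts.sum(axis=1)
    counts = counts.loc[totals > 0]
    totals = totals[totals > 0]
    if counts.empty:
        raise ValueError("no OTUs present in the group")
    if within_community:
        rel = counts / counts.sum(axis=0)
        prop = rel.div(rel.sum(axis=1), axis=0)
    else:
        prop = counts.div(totals, axis=0)
    B = 1.0 / (prop ** 2).sum(axis=1)
    present = counts > 0
    B_com = pd.Series(
        {sid: float(B[present[sid]].mean()) for sid in counts.columns},
        name="B_com",
    )
    return NicheBreadthResult(B=B.rename("B"), B_com=B_com)
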