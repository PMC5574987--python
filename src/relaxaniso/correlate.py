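"""Correlation of MR anisotropy with qPLM reference profiles.

Depth-wise MR anisotropy profiles are correlated per sample with the
qPLM anisotropy and retardation profiles (Pearson r over the common
normalized depth axis, missing depths dropped pairwise), and the
per-sample coefficients averaged on Fisher's variance-stabilized scale:
z = atanh(r), r_mean = tanh(mean z).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .anisotropy import AnisotropyProfile, deep_zone_anisotropy

__all__ = ["pearson", "fisher_mean", "summarize"]

_Z_CLIP = np.arctanh(1.0 - 1e-12)


def pearson(x, y, min_points: int = 3) -> float:
    """Pearson correlation of two profiles with pairwise NaN removal."""
    xv = np.asarray(getattr(x, "values", x), dtype=float)
    yv = np.asarray(getattr(y, "values", y), dtype=float)
    if xv.shape != yv.shape:
        raise ValueError("profiles must share a common depth axis")
    ok = np.isfinite(xv) & np.isfinite(yv)
    if ok.sum() < min_points:
        raise ValueError(f"need at least {min_points} paired points")
    xv, yv = xv[ok], yv[ok]
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("zero variance in a profile")
    return float(stats.pearsonr(xv, yv).statistic)


def fisher_mean(r_values, allow_unit: bool = False) -> float:
    """Fisher-z average of correlation coefficients: tanh(mean atanh(r)).

    With ``allow_unit`` coefficients of magnitude 1 are clipped to the
    representable z range instead of rejected.
    """
    r = np.asarray(r_values, dtype=float)
    if r.size == 0:
        raise ValueError("no correlation values")
    if np.any(np.abs(r) >= 1):
        if not allow_unit:
            raise ValueError("|r| = 1 has infinite Fisher z; pass allow_unit=True")
        z = np.clip(np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12)), -_Z_CLIP, _Z_CLIP)
    else:
        z = np.arctanh(r)
    return float(np.tanh(z.mean()))


def summarize(
    mr_profiles: dict[str, dict[str, AnisotropyProfile]],
    plm: dict[str, dict[str, "object"]],
    deep_roi=(0.40, 0.80),
) -> pd.DataFrame:
    """Study summary: deep-zone anisotropy and qPLM correlations per kind.

    ``mr_profiles[kind][sample]`` are MR anisotropy profiles;
    ``plm[sample]`` holds the qPLM ``anisotropy`` and ``retardation``
    DepthProfiles of that sample.  One row per parameter kind: mean
    (min/max over samples) deep-zone anisotropy in percent, and
    Fisher-z-averaged Pearson r (with per-sample range) against qPLM
    anisotropy and retardation.  Rows are sorted by descending
    anisotropy, ties broken by kind name.
    """
    rows = []
    for kind, per_sample in mr_profiles.items():
        deep, r_a, r_r = [], [], []
        unit_flag = False
        for sample, prof in per_sample.items():
            deep.append(deep_zone_anisotropy(prof, deep_roi))
            ra = pearson(prof.values, plm[sample]["anisotropy"].values)
            rr = pearson(prof.values, plm[sample]["retardation"].values)
            unit_flag |= abs(ra) >= 1 or abs(rr) >= 1
            r_a.append(ra)
            r_r.append(rr)
        rows.append(
            {
                "parameter_kind": kind,
                "anisotropy_mean_pct": np.mean(deep),
                "anisotropy_min_pct": np.min(deep),
                "anisotropy_max_pct": np.max(deep),
                "r_plm_anisotropy": fisher_mean(r_a, allow_unit=True),
                "r_plm_anisotropy_min": np.min(r_a),
                "r_plm_anisotropy_max": np.max(r_a),
                "r_plm_retardation": fisher_mean(r_r, allow_unit=True),
                "r_plm_retardation_min": np.min(r_r),
                "r_plm_retardation_max": np.max(r_r),
                "n_samples": len(per_sample),
                "unit_r_clipped": unit_flag,
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["anisotropy_mean_pct", "parameter_kind"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return df
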