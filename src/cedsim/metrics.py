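"""Delivery-outcome measures computed from simulation snapshots.

Four indexes summarize a regimen: the ECS-volume-weighted spatial average
concentration (accumulation), the distance course of any field about the
infusion site (spatial change), the distribution non-uniformity NUN
(heterogeneity), and the effective distribution volume V_eff where the free
drug exceeds its LD90 (cell-kill coverage).
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def spatial_avg(C, eps_ECS, mask) -> float:
    """ECS-volume-weighted mean concentration over the masked cells.

    avg = sum(C_i * epsECS_i * V_i) / sum(epsECS_i * V_i); uniform cells make
    the cell volume cancel.
    """
    mask = np.asarray(mask, dtype=bool)
    if not np.any(mask):
        raise ValueError("empty mask")
    w = np.asarray(eps_ECS, dtype=float)[mask]
    c = np.asarray(C, dtype=float)[mask]
    wsum = float(w.sum())
    if wsum <= 0:
        raise ValueError("mask carries no ECS volume")
    return float((c * w).sum() / wsum)


def nun(C, eps_ECS, mask) -> float:
    """Distribution non-uniformity: ECS-volume-weighted mean absolute
    deviation from the spatial average, divided by that average."""
    avg = spatial_avg(C, eps_ECS, mask)
    if avg <= 0:
        raise ValueError("NUN undefined for a zero spatial average")
    mask = np.asarray(mask, dtype=bool)
    w = np.asarray(eps_ECS, dtype=float)[mask]
    c = np.asarray(C, dtype=float)[mask]
    return float((np.abs(c - avg) * w).sum() / (avg * w.sum()))


def effective_volume(C, cell_volume_mm3, mask, ld90_M) -> float:
    """Total tissue volume (mm^3) of masked cells with C >= LD90 (inclusive)."""
    if ld90_M <= 0:
        raise ValueError("LD90 must be positive")
    mask = np.asarray(mask, dtype=bool)
    c = np.asarray(C, dtype=float)
    return float(np.sum(mask & (c >= ld90_M)) * cell_volume_mm3)


def distance_course(field, distances_mm, mask, bin_mm=0.9,
                    weights=None) -> pd.DataFrame:
    """Volume-weighted shell averages of ``field`` about the infusion site.

    Cells are grouped into spherical shells [d, d+bin) of their distance to
    the tip; each shell reports the (optionally weighted) mean of the field.
    Empty shells are omitted.  Returns columns (shell_mm, value, n_cells)
    where shell_mm is the shell midpoint.
    """
    if bin_mm <= 0:
        raise ValueError("bin width must be positive")
    mask = np.asarray(mask, dtype=bool)
    if not np.any(mask):
        raise ValueError("empty mask")
    d = np.asarray(distances_mm, dtype=float)[mask]
    f = np.asarray(field, dtype=float)[mask]
    w = np.ones_like(f) if weights is None else np.asarray(weights, dtype=float)[mask]
    k = np.floor(d / bin_mm).astype(int)
    rows = []
    for shell in np.unique(k):
        sel = k == shell
        wsum = float(w[sel].sum())
        if wsum <= 0:
            continue
        rows.append(((shell + 0.5) * bin_mm,
                     float((f[sel] * w[sel]).sum() / wsum),
                     int(sel.sum())))
    return pd.DataFrame(rows, columns=["shell_mm", "value", "n_cells"])


def regimen_summary(C_FD, eps_ECS, cell_volume_mm3, mask, ld90_M) -> dict:
    """The three scalar outcome measures for one snapshot."""
    return {"avg_M": spatial_avg(C_FD, eps_ECS, mask),
            "nun": nun(C_FD, eps_ECS, mask),
            "veff_mm3": effective_volume(C_FD, cell_volume_mm3, mask, ld90_M)}
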