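"""Environmental limiting points and response-summary exports.

Limiting points (tipping points) are the extreme predictor values observed
over the cells predicted suitable: for minimum-type predictors the minimum
(the lower physiological bound), for maximum-type the maximum.  When the
extreme coincides with the predictor raster's own extreme, the predictor is
flagged as imposing no tipping point inside the study region.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .grids import Raster

logger = logging.getLogger(__name__)

_REL_TOL = 1e-9


def _at_raster_extreme(value: float, extreme: float, span: float) -> bool:
    return abs(value - extreme) <= _REL_TOL * max(span, 1.0)


def limiting_points(binary: Raster, predictors,
                    occurrences: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-predictor limiting points over predicted-presence cells.

    Columns: predictor, direction (min/max/both), limit_lo, limit_hi,
    no_tipping_lo/hi flags, and the occurrence range when records are given.
    """
    pres = np.nan_to_num(binary.values, nan=0.0) > 0
    if not pres.any():
        raise ValueError("binary map has no presence cells")
    rows = []
    for p in predictors:
        vals = p.raster.values
        ok = pres & np.isfinite(vals)
        if not ok.any():
            rows.append({"predictor": p.name, "direction": "undefined"})
            continue
        v = vals[ok]
        allv = vals[np.isfinite(vals)]
        span = float(allv.max() - allv.min())
        sign = p.monotone_sign
        direction = {1: "min", -1: "max", 0: "both"}[sign]
        lo = float(v.min()) if sign >= 0 else np.nan
        hi = float(v.max()) if sign <= 0 else np.nan
        rec = {
            "predictor": p.name,
            "direction": direction,
            "limit_lo": lo,
            "limit_hi": hi,
            "no_tipping_lo": (bool(_at_raster_extreme(lo, allv.min(), span))
                              if np.isfinite(lo) else False),
            "no_tipping_hi": (bool(_at_raster_extreme(hi, allv.max(), span))
                              if np.isfinite(hi) else False),
        }
        if occurrences is not None and len(occurrences):
            ov = p.raster.sample(occurrences["lon"].to_numpy(),
                                 occurrences["lat"].to_numpy())
            ov = ov[np.isfinite(ov)]
            if ov.size:
                rec["occ_min"] = float(ov.min())
                rec["occ_max"] = float(ov.max())
        rows.append(rec)
    return pd.DataFrame(rows)


def bean_data(occurrences: pd.DataFrame, predictors) -> pd.DataFrame:
    """Long-format table of predictor values at presence records.

    One row per (record, predictor); records falling off-grid or on missing
    cells are skipped with a warning.
    """
    pres = occurrences[occurrences["label"] == "presence"] \
        if "label" in occurrences.columns else occurrences
    if pres.empty:
        return pd.DataFrame(columns=["record", "lon", "lat", "predictor", "value"])
    lon = pres["lon"].to_numpy()
    lat = pres["lat"].to_numpy()
    out = []
    n_skipped = 0
    for p in predictors:
        vals = p.raster.sample(lon, lat)
        ok = np.isfinite(vals)
        n_skipped += int((~ok).sum())
        for i in np.nonzero(ok)[0]:
            out.append({"record": int(pres.index[i]), "lon": lon[i],
                        "lat": lat[i], "predictor": p.name,
                        "value": float(vals[i])})
    if n_skipped:
        logger.warning("bean_data: skipped %d off-grid/missing lookups", n_skipped)
    return pd.DataFrame(out, columns=["record", "lon", "lat", "predictor", "value"])


def bean_summary(bean: pd.DataFrame) -> pd.DataFrame:
    """min / quartiles / max per predictor."""
    if bean.empty:
        return pd.DataFrame(columns=["predictor", "min", "q25", "median",
                                     "q75", "max", "n"])
    g = bean.groupby("predictor")["value"]
    return pd.DataFrame({
        "min": g.min(), "q25": g.quantile(0.25), "median": g.median(),
        "q75": g.quantile(0.75), "max": g.max(), "n": g.size(),
    }).reset_index()


def partial_dependence_table(members, member_combos, data: pd.DataFrame,
                             n_points: int = 50) -> pd.DataFrame:
    """Partial-dependence curves for every predictor of every ensemble
    member, on a grid spanning the observed range."""
    rows = []
    for mi, (model, combo) in enumerate(zip(members, member_combos)):
        X = data.loc[:, list(combo)].to_numpy(dtype=float)
        for name in combo:
            col = data[name].to_numpy(dtype=float)
            grid = np.linspace(col.min(), col.max(), n_points)
            curve = model.partial_dependence(X, list(combo).index(name), grid)
            for v, q in zip(grid, curve):
                rows.append({"member": mi, "predictor": name,
                             "value": float(v), "response": float(q)})
    return pd.DataFrame(rows, columns=["member", "predictor", "value", "response"])


def plot_beans(bean: pd.DataFrame, path) -> None:
    """One violin per predictor of the presence-value distributions."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    preds = sorted(bean["predictor"].unique())
    fig, axes = plt.subplots(1, max(len(preds), 1),
                             figsize=(2.2 * max(len(preds), 1), 3.2))
    if len(preds) <= 1:
        axes = [axes]
    for ax, name in zip(axes, preds):
        vals = bean.loc[bean["predictor"] == name, "value"]
        ax.violinplot(vals, showmedians=True)
        ax.set_title(name, fontsize=8)
        ax.set_xticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
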