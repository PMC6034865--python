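"""Plot-level diversity proxies: richness, Smith-Wilson evenness, Ellenberg means.

Species richness counts the taxa present in a plot.  Evenness uses the
Smith-Wilson index

    E_var = 1 - (2/pi) * arctan( (1/S) * sum_s (ln x_s - mean ln x)^2 )

computed over the S species present; it is independent of richness and of the
measurement unit of abundance.  The soil-water proxy is the cover-weighted
mean Ellenberg moisture indicator value of the species present.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .vegdata import CommunityMatrix


def species_richness(cover: np.ndarray | pd.Series) -> int:
    """Number of species with strictly positive cover."""
    arr = np.asarray(cover, dtype=float)
    return int((arr > 0).sum())


def evenness_evar(cover: np.ndarray | pd.Series) -> float:
    """Smith-Wilson evenness of the species present in a plot.

    Zeros are excluded before computation.  A single-species plot returns 1.0
    (its log-abundance variance is zero by convention).
    """
    arr = np.asarray(cover, dtype=float)
    x = arr[arr > 0]
    if x.size == 0:
        raise ValueError("evenness undefined for an empty community")
    logs = np.log(x)
    var = np.mean((logs - logs.mean()) ** 2)
    return 1.0 - (2.0 / math.pi) * math.atan(var)


def weighted_ellenberg(
    cover: np.ndarray | pd.Series,
    indicator: np.ndarray | pd.Series,
    presence_weighted: bool = False,
) -> float:
    """Cover-weighted mean indicator value over the species present.

    ``indicator`` holds the per-species Ellenberg value, NaN where undefined;
    species without a value are excluded from both sums.  With
    ``presence_weighted`` every present species counts equally instead of by
    cover.  Returns NaN when no present species has a value.
    """
    c = np.asarray(cover, dtype=float)
    m = np.asarray(indicator, dtype=float)
    if c.shape != m.shape:
        raise ValueError("cover and indicator vectors differ in length")
    mask = (c > 0) & np.isfinite(m)
    if (m[np.isfinite(m)] <= 0).any():
        raise ValueError("indicator values must be positive where defined")
    if not mask.any():
        return float("nan")
    w = np.ones(mask.sum()) if presence_weighted else c[mask]
    return float(np.sum(w * m[mask]) / np.sum(w))


def diversity_table(
    m: CommunityMatrix,
    moisture: pd.Series | None = None,
    presence_weighted_eiv: bool = False,
) -> pd.DataFrame:
    """Per-plot richness, E_var and EIV_M for a community matrix.

    ``moisture`` maps taxon name to its Ellenberg moisture value; taxa not in
    the series are treated as having no value.
    """
    if moisture is not None:
        mvec = moisture.reindex(m.species).astype(float).values
    rows = []
    for plot in m.plots:
        vec = m.cover.loc[plot].values
        rec = {
            "plot_id": plot,
            "richness": species_richness(vec),
            "evenness": evenness_evar(vec) if (vec > 0).any() else np.nan,
        }
        if moisture is not None:
            rec["eiv_m"] = weighted_ellenberg(
                vec, mvec, presence_weighted=presence_weighted_eiv
            )
        rows.append(rec)
    return pd.DataFrame(rows).set_index("plot_id")
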