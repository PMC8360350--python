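"""Population-level summaries of per-pig trait estimates and average-pig selection.

The "average pig" is not a vector of trait means: it is the real individual
whose estimated traits are jointly closest to the population medians, in
summed relative deviation over (BW_m, B, Npm, L_m).  Selecting an actual pig
preserves the within-animal correlations between traits that were estimated
jointly for that animal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

__all__ = [
    "TRAIT_COLUMNS",
    "D_TRAITS",
    "AveragePigSelection",
    "trait_summary",
    "select_average_pig",
]

#: trait columns of a trait table (one row per pig)
TRAIT_COLUMNS = ("BW_m", "B", "Npm", "L_m", "Npin", "L_in")
#: traits entering the average-pig deviation metric
D_TRAITS = ("BW_m", "B", "Npm", "L_m")


@dataclass(frozen=True)
class AveragePigSelection:
    """Result of the average-pig search: the selected id, every pig's summed
    relative deviation D, and the trait medians the deviations were taken
    against."""

    pig_id: str
    D: pd.Series
    medians: dict[str, float]


def _kde_mode(values: np.ndarray) -> float:
    """Mode of a continuous trait, defined as the argmax of a Gaussian KDE
    (Silverman bandwidth) evaluated on a fine grid."""
    values = np.asarray(values, dtype=float)
    if np.ptp(values) == 0:
        return float(values[0])
    kde = gaussian_kde(values, bw_method="silverman")
    pad = 0.5 * values.std()
    grid = np.linspace(values.min() - pad, values.max() + pad, 2048)
    return float(grid[np.argmax(kde(grid))])


def _with_ratio(table: pd.DataFrame) -> pd.DataFrame:
    table = table.copy()
    if "Lm_Npm_ratio" not in table.columns:
        table["Lm_Npm_ratio"] = table["L_m"] / table["Npm"]
    return table


def trait_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Descriptive statistics of each trait across pigs.

    Returns one row per trait with min, median, IQR, mean, SD, mode and max.
    Quantiles use linear interpolation; the mode is the KDE argmax.  The
    derived lipid-to-protein ratio at maturity is summarised alongside the
    six traits.
    """
    if len(table) < 2:
        raise ValueError("trait_summary requires at least 2 pigs")
    table = _with_ratio(table)
    rows = []
    for name in list(TRAIT_COLUMNS) + ["Lm_Npm_ratio"]:
        v = table[name].to_numpy(dtype=float)
        q25, q50, q75 = np.percentile(v, [25, 50, 75])
        rows.append(
            {
                "trait": name,
                "min": v.min(), "median": q50, "iqr": q75 - q25,
                "mean": v.mean(), "sd": v.std(ddof=1),
                "mode": _kde_mode(v), "max": v.max(),
            }
        )
    return pd.DataFrame(rows).set_index("trait")


def select_average_pig(table: pd.DataFrame) -> AveragePigSelection:
    """Pick the pig minimising D_i = sum_j |Y_ij - med_j| / med_j over
    (BW_m, B, Npm, L_m), with med_j the across-pig medians.

    Ties are broken by the lowest pig_id (string order), making the selection
    deterministic.  The selected pig carries its full, correlated trait
    vector downstream.
    """
    if len(table) == 0:
        raise ValueError("empty trait table")
    table = table.copy()
    if "pig_id" in table.columns:
        table = table.set_index("pig_id")
    medians = {j: float(table[j].median()) for j in D_TRAITS}
    D = sum(
        (table[j] - medians[j]).abs() / medians[j] for j in D_TRAITS
    )
    D = D.astype(float)
    d_min = D.min()
    winner = sorted(str(i) for i in D.index[D == d_min])[0]
    # preserve the original index dtype when recovering the winner
    winners = [i for i in D.index if str(i) == winner]
    return AveragePigSelection(pig_id=winners[0], D=D, medians=medians)
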