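"""Bundled reference data: the published QTP case-study weight table.

The table carries, for each of the 15 indicators, the expert (AHP) weight
column and the per-epoch entropy (EEM) and combined weight columns as printed
(4 decimal places) for the Qinghai-Tibet Plateau case study. It serves as a
ready-made weight source for runs without expert judgment matrices and as the
reference for validating the geometric-mean fusion rule.
"""

from __future__ import annotations

import pandas as pd

from .weights import WeightSet

__all__ = ["load_qtp_weights", "qtp_weight_set", "QTP_EPOCHS", "QTP_FIXED_BREAKS"]

QTP_EPOCHS = ("2000", "2010", "2020")

#: Published level breakpoints for the five-level classification of the index.
QTP_FIXED_BREAKS = (0.31, 0.37, 0.46, 0.61)

# code: (ahp, eem_2000, wi_2000, eem_2010, wi_2010, eem_2020, wi_2020)
_QTP_TABLE = {
    "SHDI": (0.1577, 0.2583, 0.2749, 0.2573, 0.2776, 0.2534, 0.2765),
    "RDLS": (0.1577, 0.0107, 0.0559, 0.0111, 0.0575, 0.0107, 0.0568),
    "HQ":   (0.0526, 0.0786, 0.0876, 0.0764, 0.0874, 0.0738, 0.0862),
    "DTPA": (0.1851, 0.0155, 0.0730, 0.0111, 0.0623, 0.0107, 0.0616),
    "NDVI": (0.0169, 0.0544, 0.0413, 0.0613, 0.0444, 0.0592, 0.0438),
    "DTL":  (0.0629, 0.0155, 0.0426, 0.0111, 0.0363, 0.0107, 0.0359),
    "DTR":  (0.0259, 0.0107, 0.0227, 0.0111, 0.0233, 0.0107, 0.0230),
    "DTG":  (0.0771, 0.0058, 0.0289, 0.0060, 0.0297, 0.0058, 0.0294),
    "OC":   (0.0693, 0.0107, 0.0371, 0.0111, 0.0381, 0.0107, 0.0377),
    "PRRI": (0.0563, 0.3117, 0.1804, 0.3226, 0.1858, 0.3116, 0.1832),
    "TEM":  (0.0221, 0.0107, 0.0209, 0.0111, 0.0215, 0.0058, 0.0157),
    "PRE":  (0.0135, 0.1757, 0.0663, 0.1668, 0.0654, 0.1903, 0.0701),
    "TNI":  (0.0074, 0.0155, 0.0146, 0.0161, 0.0150, 0.0155, 0.0148),
    "DTC":  (0.0159, 0.0204, 0.0245, 0.0211, 0.0252, 0.0204, 0.0249),
    "TA":   (0.0796, 0.0058, 0.0293, 0.0060, 0.0302, 0.0107, 0.0404),
}


def load_qtp_weights() -> pd.DataFrame:
    """The printed weight table as a DataFrame indexed by indicator code."""
    cols = ["ahp", "eem_2000", "wi_2000", "eem_2010", "wi_2010", "eem_2020", "wi_2020"]
    return pd.DataFrame.from_dict(_QTP_TABLE, orient="index", columns=cols)


def qtp_weight_set(kind: str, epoch: str | None = None, renormalize: bool = True) -> WeightSet:
    """A WeightSet from one printed column.

    ``kind`` is ``"ahp"``, ``"eem"`` or ``"combined"``; entropy and combined
    columns need an ``epoch`` in {2000, 2010, 2020}. Printed columns are
    rounded to 4 d.p. so they can miss a unit sum by ~1e-4; ``renormalize``
    rescales them (required for the WeightSet unit-sum invariant).
    """
    df = load_qtp_weights()
    if kind == "ahp":
        col = "ahp"
    elif kind in ("eem", "combined"):
        if epoch not in QTP_EPOCHS:
            raise ValueError(f"epoch must be one of {QTP_EPOCHS}, got {epoch!r}")
        col = f"eem_{epoch}" if kind == "eem" else f"wi_{epoch}"
    else:
        raise ValueError(f"unknown kind {kind!r}")
    w = df[col].to_numpy(dtype=float)
    if renormalize:
        w = w / w.sum()
    return WeightSet(kind=kind, weights=dict(zip(df.index, w)), epoch=epoch)
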