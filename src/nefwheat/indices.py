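"""Agronomic nitrogen-efficiency indices.

Eight indices summarise how a variety responds to a nitrogen-stress contrast
(low-N stress N0 vs normal N1, or high-N stress N2 vs normal N1):

* **WY, ANA, WDMM, TGW** — change rates of wheat yield, above-ground nitrogen
  accumulation, dry matter mass and thousand-grain weight:
  (stress − control) / control.
* **NUE** — yield difference per kg of applied nitrogen (kg/ha yield per
  kg/ha N).
* **AENF** — above-ground N-accumulation difference per kg of applied
  nitrogen.
* **NFUE** — dry-matter ratio statistic; by default the centred ratio
  (stress/control − 1), with a ``literal`` mode returning the plain ratio.
* **NT** — nitrogen tolerance coefficient, the yield ratio stress/control.

Replicates are averaged per variety × level first; indices are computed from
those means.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "change_rate",
    "nue",
    "aenf",
    "nfue",
    "nt",
    "index_table",
    "summarize",
    "INDEX_COLUMNS",
    "N_LEVELS",
    "CONTRASTS",
]

INDEX_COLUMNS = ("WY", "ANA", "WDMM", "TGW", "NUE", "AENF", "NFUE", "NT")

#: nitrogen application per level label, kg/ha
N_LEVELS = {"N0": 0.0, "N1": 225.0, "N2": 450.0}

#: contrast name -> (stress level, control level)
CONTRASTS = {"N0_vs_N1": ("N0", "N1"), "N2_vs_N1": ("N2", "N1")}

_TRAITS = {"WY": "WY_raw", "ANA": "ANA_raw", "WDMM": "WDMM_raw", "TGW": "TGW_raw"}


def change_rate(stress_value: float, control_value: float) -> float:
    """(stress − control) / control; control must be positive."""
    if np.any(np.asarray(control_value) <= 0):
        raise ValueError("control value must be > 0")
    return (stress_value - control_value) / control_value


def nue(yield_stress: float, yield_control: float, delta_n_applied: float) -> float:
    """Yield difference per unit of applied nitrogen (kg/ha per kg/ha N)."""
    if delta_n_applied <= 0:
        raise ValueError("applied-nitrogen difference must be > 0")
    return (yield_stress - yield_control) / delta_n_applied


def aenf(ana_stress: float, ana_control: float, delta_n_applied: float) -> float:
    """Above-ground N-accumulation difference per unit of applied nitrogen."""
    if delta_n_applied <= 0:
        raise ValueError("applied-nitrogen difference must be > 0")
    return (ana_stress - ana_control) / delta_n_applied


def nfue(wdmm_stress: float, wdmm_control: float, mode: str = "centered") -> float:
    """Dry-matter ratio statistic.

    ``centered`` (default) returns stress/control − 1 so that "no response"
    maps to 0 like the change rates; ``literal`` returns the plain ratio.
    """
    if np.any(np.asarray(wdmm_control) <= 0):
        raise ValueError("control dry matter must be > 0")
    ratio = wdmm_stress / wdmm_control
    if mode == "centered":
        return ratio - 1.0
    if mode == "literal":
        return ratio
    raise ValueError(f"unknown NFUE mode: {mode!r}")


def nt(yield_stress: float, yield_control: float) -> float:
    """Nitrogen tolerance coefficient: yield ratio stress/control."""
    if np.any(np.asarray(yield_control) <= 0):
        raise ValueError("control yield must be > 0")
    return yield_stress / yield_control


def _level_label(value, n_levels: dict) -> str | None:
    for label, amount in n_levels.items():
        if value == label or value == amount:
            return label
    return None


def index_table(
    pheno: pd.DataFrame,
    contrast: str = "N0_vs_N1",
    nfue_mode: str = "centered",
    n_levels: dict = N_LEVELS,
) -> pd.DataFrame:
    """Compute the eight indices per variety for one stress contrast.

    ``pheno`` has one row per variety × n_level × replicate with columns
    ``variety, n_level, replicate, WY_raw, ANA_raw, WDMM_raw, TGW_raw``;
    ``n_level`` may hold level labels ("N0") or applications (0, 225, 450
    kg/ha). Varieties lacking the stress level (e.g. a reference cultivar
    planted at only two levels) are dropped from the contrast; a variety
    lacking the control level is an error.

    The applied-nitrogen denominator for NUE/AENF is the absolute difference
    in application between the contrast levels (225 kg/ha for both standard
    contrasts).
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast: {contrast!r}")
    stress_label, control_label = CONTRASTS[contrast]
    required = {"variety", "n_level", *_TRAITS.values()}
    missing = required - set(pheno.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    if np.any(pheno[list(_TRAITS.values())].to_numpy(dtype=float) <= 0):
        raise ValueError("raw phenotype values must be > 0")

    pheno = pheno.copy()
    pheno["_level"] = pheno["n_level"].map(lambda v: _level_label(v, n_levels))
    if pheno["_level"].isna().any():
        bad = pheno.loc[pheno["_level"].isna(), "n_level"].unique()
        raise ValueError(f"unrecognised nitrogen levels: {list(bad)}")
    means = (
        pheno.groupby(["variety", "_level"], sort=False)[list(_TRAITS.values())]
        .mean()
        .reset_index()
    )
    by_level = {
        lvl: g.set_index("variety") for lvl, g in means.groupby("_level", sort=False)
    }
    control = by_level.get(control_label)
    if control is None:
        raise ValueError(f"no rows at control level {control_label}")
    stress = by_level.get(stress_label)
    if stress is None:
        raise ValueError(f"no rows at stress level {stress_label}")

    delta_n = abs(n_levels[stress_label] - n_levels[control_label])
    records = []
    for variety in means["variety"].unique():
        if variety not in stress.index:
            continue  # planted only at the other two levels
        if variety not in control.index:
            raise ValueError(
                f"variety {variety!r} has no control ({control_label}) phenotypes"
            )
        s, c = stress.loc[variety], control.loc[variety]
        records.append(
            {
                "variety": variety,
                "WY": change_rate(s["WY_raw"], c["WY_raw"]),
                "ANA": change_rate(s["ANA_raw"], c["ANA_raw"]),
                "WDMM": change_rate(s["WDMM_raw"], c["WDMM_raw"]),
                "TGW": change_rate(s["TGW_raw"], c["TGW_raw"]),
                "NUE": nue(s["WY_raw"], c["WY_raw"], delta_n),
                "AENF": aenf(s["ANA_raw"], c["ANA_raw"], delta_n),
                "NFUE": nfue(s["WDMM_raw"], c["WDMM_raw"], nfue_mode),
                "NT": nt(s["WY_raw"], c["WY_raw"]),
                "contrast": contrast,
            }
        )
    return pd.DataFrame(records).set_index("variety")


def summarize(indices: pd.DataFrame) -> pd.DataFrame:
    """Max / min / sample SD / mean / CV per index over varieties.

    CV = SD/|mean| (reported as a fraction and as a percent); flagged
    undefined (NaN) when the mean is zero. Requires >= 2 varieties.
    """
    cols = [c for c in INDEX_COLUMNS if c in indices.columns]
    if len(indices) < 2:
        raise ValueError("summary requires at least 2 varieties")
    out = {}
    for col in cols:
        x = indices[col].to_numpy(dtype=float)
        mean = x.mean()
        sd = x.std(ddof=1)
        cv = sd / abs(mean) if mean != 0 else np.nan
        out[col] = {
            "max": x.max(),
            "min": x.min(),
            "SD": sd,
            "mean": mean,
            "CV": cv,
            "CV_percent": 100.0 * cv if np.isfinite(cv) else np.nan,
        }
    return pd.DataFrame(out)
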