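"""Synthetic canopy spectra and phenotype generator.

The study design this emulates: a winter-wheat field trial with a panel of
candidate varieties plus two reference cultivars, grown at three nitrogen
applications (0, 225, 450 kg/ha — low-N stress, normal, high-N stress), two
replicate plots per variety × level, and five canopy sampling regions per
plot. Varieties belong to one of three nitrogen-efficiency classes:

* ``low_N_efficient`` — hold or improve phenotypes when nitrogen is withheld;
* ``high_N_efficient`` — respond strongly to extra nitrogen;
* ``inefficient`` — decline under both deficit and excess.

Spectra are smooth vegetation-like reflectance curves (dark visible region,
red-edge rise near 700–750 nm, bright near-infrared plateau) with a class-
and level-dependent reflectance shift confined to designated signature
wavelength windows, plus spatially smoothed noise so that adjacent bands are
strongly collinear — the property that motivates characteristic-band
selection downstream. Phenotypes (yield, above-ground N accumulation, dry
matter, thousand-grain weight) get class-dependent nitrogen responses with
multiplicative noise.

All randomness flows through one seeded :class:`numpy.random.Generator`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .containers import SpectraMatrix

__all__ = [
    "SyntheticDesign",
    "generate_spectra",
    "generate_phenotypes",
    "LOW_N_REFERENCE",
    "HIGH_N_REFERENCE",
    "CLASSES",
]

CLASSES = ("low_N_efficient", "high_N_efficient", "inefficient")

#: reference cultivars anchoring the efficient cluster under each stress
LOW_N_REFERENCE = "Jimai 22"
HIGH_N_REFERENCE = "Shannong 28"

# Canopy "vigor" score per class at each nitrogen level, in effect-size
# units: classes thriving under a stress stand apart spectrally; at the
# normal level all classes look much alike (the reason the stress
# treatments are grown at all). Sampled positionally for non-default level
# sets (low, normal, high in sorted order).
_VIGOR = {
    "low_N_efficient": (1.0, 0.10, -0.25),
    "high_N_efficient": (-0.25, 0.15, 1.0),
    "inefficient": (-0.35, -0.05, -0.35),
}

# sd of the per-variety, per-window multiplicative deviation of the class
# signal: same-class varieties are spectrally similar, not identical, so no
# single window predicts class perfectly and window information is
# partially independent.
_VARIETY_JITTER_SD = 0.3

# Phenotype response multipliers per class at (low-N, normal, high-N).
_PHENO_RESPONSE = {
    "low_N_efficient": {0.0: 1.06, 225.0: 1.0, 450.0: 0.85},
    "high_N_efficient": {0.0: 0.78, 225.0: 1.0, 450.0: 1.28},
    "inefficient": {0.0: 0.80, 225.0: 1.0, 450.0: 0.86},
}

# Variety-mean phenotype scales: yield (kg/ha), above-ground N accumulation
# (g/plant), dry matter (g/plant), thousand-grain weight (g).
_PHENO_BASE = {"WY_raw": 7000.0, "ANA_raw": 2.0, "WDMM_raw": 15.0, "TGW_raw": 45.0}


def _default_class_map(n_varieties: int) -> dict:
    """Assign classes in the study's field proportions (6 : 2 : 4 of 12)."""
    counts = {
        "low_N_efficient": round(n_varieties * 6 / 12),
        "high_N_efficient": max(round(n_varieties * 2 / 12), 1),
    }
    mapping = {}
    order = []
    for cls in ("low_N_efficient", "high_N_efficient"):
        order += [cls] * counts[cls]
    order += ["inefficient"] * (n_varieties - len(order))
    for i in range(n_varieties):
        mapping[f"V{i + 1:02d}"] = order[i]
    return mapping


@dataclass
class SyntheticDesign:
    """Configuration of the simulated trial.

    ``signature_bands`` are (lo, hi) wavelength windows in nm carrying the
    class signal; ``effect_size`` the peak reflectance shift (dimensionless);
    ``noise_sd`` the per-band reflectance noise after spectral smoothing with
    a Gaussian kernel of width ``collinearity_length`` nm; ``pheno_noise_sd``
    the sd of the multiplicative (log-scale) phenotype noise.
    """

    n_varieties: int = 12
    replicates_per_cell: int = 2
    regions_per_plot: int = 5
    n_levels: tuple = (0.0, 225.0, 450.0)
    class_map: dict | None = None
    signature_bands: tuple = ((450.0, 510.0), (610.0, 660.0), (850.0, 900.0))
    effect_size: float = 0.05
    noise_sd: float = 0.01
    pheno_noise_sd: float = 0.03
    collinearity_length: float = 15.0
    include_references: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_varieties < 1 or self.replicates_per_cell < 1 or self.regions_per_plot < 1:
            raise ValueError("counts must be >= 1")
        if self.effect_size < 0 or self.noise_sd < 0 or self.pheno_noise_sd < 0:
            raise ValueError("effect_size and noise sds must be >= 0")
        if self.class_map is None:
            self.class_map = _default_class_map(self.n_varieties)
        bad = set(self.class_map.values()) - set(CLASSES)
        if bad:
            raise ValueError(f"unknown efficiency classes: {sorted(bad)}")
        for lo, hi in self.signature_bands:
            if lo >= hi:
                raise ValueError("signature window must have lo < hi")

    @property
    def varieties(self) -> list:
        return list(self.class_map)

    def class_of(self, variety: str) -> str:
        if variety == LOW_N_REFERENCE:
            return "low_N_efficient"
        if variety == HIGH_N_REFERENCE:
            return "high_N_efficient"
        return self.class_map[variety]

    def rows(self):
        """Yield (variety, n_level, replicate) cells including references.

        The low-N reference is planted only at the low and normal levels, the
        high-N reference only at the normal and high levels, matching the
        control design of the trial.
        """
        levels = sorted(self.n_levels)
        plan = [(v, lv) for v in self.varieties for lv in levels]
        if self.include_references:
            plan += [(LOW_N_REFERENCE, lv) for lv in levels[:2]]
            plan += [(HIGH_N_REFERENCE, lv) for lv in levels[-2:]]
        for v, lv in plan:
            for rep in range(1, self.replicates_per_cell + 1):
                yield v, lv, rep


def _base_curve(wl: np.ndarray) -> np.ndarray:
    """Template vegetation reflectance: green bump, red-edge, NIR plateau."""
    green = 0.045 * np.exp(-0.5 * ((wl - 552.0) / 32.0) ** 2)
    red_edge = 0.42 / (1.0 + np.exp(-(wl - 718.0) / 13.0))
    return 0.04 + green + red_edge


def _window_profile(wl: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Raised-cosine bump, exactly zero outside [lo, hi]."""
    mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
    inside = np.abs(wl - mid) <= half
    prof = np.zeros_like(wl)
    prof[inside] = 0.5 * (1.0 + np.cos(np.pi * (wl[inside] - mid) / half))
    return prof


def _vigor(cls: str, level: float, levels: tuple) -> float:
    position = sorted(levels).index(level) if level in levels else 1
    # reference cultivars appear at levels listed in the design
    position = min(position, len(_VIGOR[cls]) - 1)
    return _VIGOR[cls][position]


def generate_spectra(
    design: SyntheticDesign,
    n_bands: int = 224,
    wl_min: float = 400.0,
    wl_max: float = 1000.0,
) -> SpectraMatrix:
    """Simulate canopy reflectance spectra for every trial cell.

    Emits one spectrum per variety × nitrogen level × replicate × plot
    region on an even ``n_bands`` grid spanning [``wl_min``, ``wl_max``] nm.
    Reflectance is clipped to [0, 1].
    """
    if n_bands < 8:
        raise ValueError("n_bands must be >= 8")
    if wl_min >= wl_max:
        raise ValueError("wl_min must be < wl_max")
    for lo, hi in design.signature_bands:
        if lo < wl_min or hi > wl_max:
            raise ValueError(
                f"signature window ({lo}, {hi}) outside wavelength range "
                f"[{wl_min}, {wl_max}]"
            )
    rng = np.random.default_rng(design.seed)
    wl = np.linspace(wl_min, wl_max, n_bands)
    base = _base_curve(wl)
    profiles = [_window_profile(wl, lo, hi) for lo, hi in design.signature_bands]

    # discrete smoothing kernel norm, to rescale smoothed noise back to noise_sd
    sigma_bands = design.collinearity_length / ((wl_max - wl_min) / (n_bands - 1))
    impulse = np.zeros(n_bands)
    impulse[n_bands // 2] = 1.0
    kernel_norm = float(np.sqrt(np.sum(gaussian_filter1d(impulse, sigma_bands) ** 2)))

    # per-variety, per-window signal deviation (kept well away from zero so
    # the sign of the class signal never flips)
    jitter_varieties = list(design.varieties) + [LOW_N_REFERENCE, HIGH_N_REFERENCE]
    jitter = {
        v: np.clip(
            1.0 + _VARIETY_JITTER_SD * rng.standard_normal(len(profiles)), 0.2, None
        )
        for v in jitter_varieties
    }

    rows, meta = [], []
    for variety, level, rep in design.rows():
        cls = design.class_of(variety)
        vigor = _vigor(cls, level, design.n_levels)
        shift = np.zeros(n_bands)
        for w, prof in enumerate(profiles):
            shift += design.effect_size * vigor * jitter[variety][w] * prof
        for region in range(1, design.regions_per_plot + 1):
            amp = 1.0 + design.noise_sd * rng.standard_normal()
            noise = rng.standard_normal(n_bands)
            if design.noise_sd > 0:
                noise = gaussian_filter1d(noise, sigma_bands) / kernel_norm
            spectrum = amp * base + shift + design.noise_sd * noise
            rows.append(np.clip(spectrum, 0.0, 1.0))
            meta.append(
                {
                    "sample_id": f"{variety}_N{level:g}_r{rep}_p{region}",
                    "variety": variety,
                    "n_level": level,
                    "replicate": rep,
                    "region": region,
                }
            )
    return SpectraMatrix(np.array(rows), wl, pd.DataFrame(meta))


def generate_nonlinear_fixture(
    n: int = 120, n_noise: int = 8, noise: float = 0.3, seed: int = 7
):
    """Two-class fixture with a nonlinear boundary plus irrelevant features.

    Two interleaved half-circles in the first two feature dimensions (the
    classic two-moons geometry), Gaussian jitter, and ``n_noise`` pure-noise
    columns. Used to exercise classifiers whose value lies in modelling
    nonlinear structure; returns ``(X, y)``.
    """
    rng = np.random.default_rng(seed)
    half = n // 2
    t0 = rng.uniform(0, np.pi, half)
    t1 = rng.uniform(0, np.pi, n - half)
    pts = np.vstack(
        [
            np.column_stack([np.cos(t0), np.sin(t0)]),
            np.column_stack([1.0 - np.cos(t1), 0.5 - np.sin(t1)]),
        ]
    )
    X = np.hstack(
        [
            pts + noise * rng.standard_normal(pts.shape),
            rng.standard_normal((n, n_noise)),
        ]
    )
    y = np.array(["arc_a"] * half + ["arc_b"] * (n - half))
    perm = rng.permutation(n)
    return X[perm], y[perm]


def generate_phenotypes(design: SyntheticDesign) -> pd.DataFrame:
    """Simulate the raw phenotype table (one row per trial cell replicate).

    Columns: variety, n_level, replicate, WY_raw, ANA_raw, WDMM_raw, TGW_raw.
    Values are strictly positive: variety base value × class-dependent level
    response × exp(Normal(0, pheno_noise_sd)).
    """
    rng = np.random.default_rng(design.seed + 1)
    all_varieties = list(design.varieties)
    if design.include_references:
        all_varieties += [LOW_N_REFERENCE, HIGH_N_REFERENCE]
    # per-variety base levels (stable across levels/replicates)
    bases = {
        v: {t: b * np.exp(0.08 * rng.standard_normal()) for t, b in _PHENO_BASE.items()}
        for v in all_varieties
    }
    records = []
    for variety, level, rep in design.rows():
        cls = design.class_of(variety)
        resp = _PHENO_RESPONSE[cls]
        mult = resp.get(level, resp[min(resp, key=lambda k: abs(k - level))])
        row = {"variety": variety, "n_level": level, "replicate": rep}
        for trait in _PHENO_BASE:
            noise = np.exp(design.pheno_noise_sd * rng.standard_normal())
            row[trait] = bases[variety][trait] * mult * noise
        records.append(row)
    return pd.DataFrame(records)
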