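"""Default 30-metabolite panel for the beef-aging generator.

Each panel entry carries the concentration trajectory (day-0 and day-28 mean
and within-animal SD, µmol/g wet tissue), which experimental factors move it
(cow-vs-heifer offset, dry-vs-wet slope difference), and the NMR signals it
produces (integration window, proton count, multiplicity, molar mass).

Day-0/day-28 means and SDs of the eight trajectory-defining metabolites
(isoleucine, leucine, phenylalanine, tryptophan, tyrosine, valine,
hypoxanthine, IMP) are the reported beef strip-loin values; the remainder of
the panel uses typical bovine muscle-extract concentrations.  Chemical-shift
windows are literature-style positions, adjusted where necessary so that
quantification windows do not overlap; they are generator metadata, not
assignments of any measured spectrum.

Effect-size conventions (per metabolite, relative to its within-animal SD):

* cattle offset  = 1.0 × pooled within-SD, added for cows, on the 8
  cattle-type metabolites (aspartate, hypoxanthine, inosine, acetic acid,
  succinic acid, carnitine, niacinamide, O-acetyl-L-carnitine);
* aging-type slope difference sized so the day-28 dry mean differs from the
  wet mean by 0.8 × day-28 within-SD, on the 12 aging-type metabolites
  (glutamate, isoleucine, leucine, phenylalanine, tyrosine, tryptophan,
  valine, hypoxanthine, IMP, inosine, creatinine, niacinamide);
* animal random intercept SD = 0.3 ×, aging-run SD = 0.1 × pooled within-SD.

Exactly 28 of the 30 metabolites carry a nonzero day-0→day-28 trend; the
dipeptides carnosine and anserine are flat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .spectra import SignalDefinition

__all__ = [
    "MetaboliteModel",
    "default_panel",
    "default_signal_table",
    "CATTLE_TYPE_METABOLITES",
    "AGING_TYPE_METABOLITES",
    "INCREASING_METABOLITES",
    "MALEIC_ACID",
]

#: metabolites with a cow-vs-heifer concentration offset
CATTLE_TYPE_METABOLITES = (
    "aspartate",
    "hypoxanthine",
    "inosine",
    "acetic acid",
    "succinic acid",
    "carnitine",
    "niacinamide",
    "O-acetylcarnitine",
)

#: metabolites whose aging trajectory differs between dry- and wet-aging
AGING_TYPE_METABOLITES = (
    "glutamate",
    "isoleucine",
    "leucine",
    "phenylalanine",
    "tyrosine",
    "tryptophan",
    "valine",
    "hypoxanthine",
    "IMP",
    "inosine",
    "creatinine",
    "niacinamide",
)

#: the seven strongly increasing free metabolites (r_SP benchmark set)
INCREASING_METABOLITES = (
    "isoleucine",
    "leucine",
    "phenylalanine",
    "tryptophan",
    "tyrosine",
    "valine",
    "hypoxanthine",
)

#: internal standard constants: molar mass g/mol, protons in the singlet
MALEIC_ACID = {
    "name": "maleic acid",
    "molar_mass": 116.07,
    "n_protons": 2,
    "ppm_lo": 6.15,
    "ppm_hi": 6.40,
    "purity": 0.995,
    "mass_mg": 0.0700,
}


@dataclass
class MetaboliteModel:
    """Generative model for one metabolite's concentration and NMR signature."""

    name: str
    mean_day0: float
    mean_day28: float
    within_sd_day0: float
    within_sd_day28: float
    trajectory_shape: str = "linear"  # linear | plateau | decay
    cattle_offset: float = 0.0  # µmol/g added for cows
    agingtype_slope_delta: float = 0.0  # µmol/g per day, added for dry
    animal_re_sd: float = 0.0
    run_re_sd: float = 0.0
    nmr_signals: list[SignalDefinition] = field(default_factory=list)

    def __post_init__(self) -> None:
        for v, what in [
            (self.mean_day0, "mean_day0"),
            (self.mean_day28, "mean_day28"),
            (self.within_sd_day0, "within_sd_day0"),
            (self.within_sd_day28, "within_sd_day28"),
            (self.animal_re_sd, "animal_re_sd"),
            (self.run_re_sd, "run_re_sd"),
        ]:
            if v < 0:
                raise ValueError(f"{self.name}: {what} must be >= 0")
        if self.trajectory_shape not in ("linear", "plateau", "decay"):
            raise ValueError(f"{self.name}: unknown trajectory {self.trajectory_shape!r}")

    @property
    def pooled_within_sd(self) -> float:
        return math.sqrt(0.5 * (self.within_sd_day0**2 + self.within_sd_day28**2))

    def mean_at(self, day: float, max_day: float) -> float:
        """Trajectory mean at a given aging day (no effects, no noise)."""
        if max_day <= 0:
            return self.mean_day0
        f = day / max_day
        m0, m1 = self.mean_day0, self.mean_day28
        if self.trajectory_shape == "linear":
            return m0 + (m1 - m0) * f
        rate = 3.0  # curvature of the exponential shapes; f=0 and f=1 hit m0/m1 exactly
        if self.trajectory_shape == "decay":
            w = (math.exp(-rate * f) - math.exp(-rate)) / (1.0 - math.exp(-rate))
            return m1 + (m0 - m1) * w
        # plateau: fast approach to the day-28 value
        w = (1.0 - math.exp(-rate * f)) / (1.0 - math.exp(-rate))
        return m0 + (m1 - m0) * w

    def within_sd_at(self, day: float, max_day: float) -> float:
        if max_day <= 0:
            return self.within_sd_day0
        f = day / max_day
        return self.within_sd_day0 + (self.within_sd_day28 - self.within_sd_day0) * f


# name: (M, day0 mean, day0 sd, day28 mean, day28 sd, shape,
#        [(lo, hi, N, multiplicity), ...])
_PANEL_SPEC: dict[str, tuple] = {
    "isoleucine": (131.17, 0.21, 0.05, 1.09, 0.26, "linear",
                   [(0.915, 0.965, 3, "d"), (1.395, 1.435, 1, "m")]),
    "leucine": (131.17, 0.32, 0.09, 1.83, 0.42, "linear",
                [(0.975, 1.025, 6, "t"), (1.675, 1.715, 3, "m")]),
    "valine": (117.15, 0.36, 0.08, 1.82, 0.42, "linear",
               [(1.035, 1.085, 6, "d"), (2.245, 2.285, 1, "m")]),
    "phenylalanine": (165.19, 0.53, 0.04, 1.26, 0.19, "linear",
                      [(3.090, 3.130, 2, "m"), (7.300, 7.340, 5, "m")]),
    "tryptophan": (204.23, 0.13, 0.01, 0.27, 0.04, "linear",
                   [(3.620, 3.660, 2, "dd")]),
    "tyrosine": (181.19, 0.30, 0.06, 1.11, 0.22, "linear",
                 [(3.020, 3.060, 2, "dd"), (6.880, 6.920, 2, "d")]),
    "hypoxanthine": (136.11, 1.20, 0.30, 3.97, 0.76, "linear",
                     [(8.160, 8.200, 1, "s"), (8.210, 8.250, 1, "s")]),
    "IMP": (348.21, 3.43, 0.33, 1.25, 0.38, "decay",
            [(8.560, 8.600, 1, "s"), (6.060, 6.100, 1, "d"), (4.470, 4.510, 1, "m")]),
    "inosine": (268.23, 0.35, 0.08, 0.80, 0.16, "linear",
                [(8.330, 8.370, 1, "s"), (6.000, 6.040, 1, "d"), (4.400, 4.440, 1, "m")]),
    "aspartate": (133.10, 0.55, 0.10, 0.80, 0.15, "linear",
                  [(2.780, 2.820, 1, "dd"), (2.640, 2.680, 1, "dd")]),
    "acetic acid": (60.05, 0.80, 0.15, 1.60, 0.30, "linear",
                    [(1.895, 1.935, 3, "s")]),
    "succinic acid": (118.09, 0.25, 0.05, 0.45, 0.09, "linear",
                      [(2.385, 2.425, 2, "s")]),
    "carnitine": (161.20, 0.70, 0.12, 0.88, 0.15, "linear",
                  [(3.200, 3.245, 9, "s")]),
    "niacinamide": (122.12, 0.08, 0.02, 0.14, 0.03, "linear",
                    [(8.700, 8.740, 1, "s"), (8.930, 8.970, 1, "s")]),
    "O-acetylcarnitine": (203.24, 0.30, 0.06, 0.45, 0.09, "linear",
                          [(3.155, 3.195, 9, "s"), (2.115, 2.155, 3, "s")]),
    "glutamate": (147.13, 2.20, 0.30, 3.20, 0.45, "linear",
                  [(2.330, 2.370, 2, "m")]),
    "creatinine": (113.12, 0.35, 0.06, 0.48, 0.09, "linear",
                   [(4.270, 4.310, 2, "s")]),
    "alanine": (89.09, 3.00, 0.40, 4.20, 0.60, "linear",
                [(1.455, 1.495, 3, "d")]),
    "glutamine": (146.15, 2.80, 0.40, 3.50, 0.55, "linear",
                  [(2.435, 2.475, 2, "m")]),
    "methionine": (149.21, 0.25, 0.05, 0.45, 0.08, "linear",
                   [(2.585, 2.625, 2, "t")]),
    "creatine": (131.13, 18.0, 2.0, 20.8, 2.5, "linear",
                 [(3.910, 3.950, 2, "s")]),
    "carnosine": (226.23, 12.0, 1.5, 12.0, 1.5, "linear",
                  [(2.940, 2.980, 2, "m"), (8.070, 8.110, 1, "s")]),
    "anserine": (240.26, 2.50, 0.40, 2.50, 0.40, "linear",
                 [(3.760, 3.800, 3, "s")]),
    "betaine": (117.15, 1.50, 0.20, 1.78, 0.26, "linear",
                [(3.250, 3.290, 9, "s")]),
    "glycine": (75.07, 1.20, 0.20, 1.65, 0.28, "linear",
                [(3.545, 3.585, 2, "s")]),
    "lactic acid": (90.08, 28.0, 3.5, 35.0, 4.5, "linear",
                    [(1.315, 1.360, 3, "d"), (4.100, 4.140, 1, "q")]),
    "beta-glucose": (180.16, 1.80, 0.40, 2.70, 0.60, "linear",
                     [(4.620, 4.660, 1, "d"), (3.460, 3.500, 1, "m")]),
    "fumaric acid": (116.07, 0.040, 0.010, 0.065, 0.015, "linear",
                     [(6.500, 6.540, 2, "s")]),
    "taurine": (125.15, 1.30, 0.20, 1.60, 0.26, "linear",
                [(3.410, 3.450, 2, "t")]),
    "uracil": (112.09, 0.050, 0.012, 0.090, 0.020, "linear",
               [(5.780, 5.820, 1, "d")]),
}

#: aging-type metabolites whose dry-aged trajectory runs *below* the wet one
_AGING_TYPE_NEGATIVE = ("IMP",)


def default_panel(
    cattle_effect_scale: float = 1.0,
    agingtype_effect_scale: float = 1.0,
    animal_re_scale: float = 1.0,
    run_re_scale: float = 1.0,
    max_day: float = 28.0,
) -> list[MetaboliteModel]:
    """Build the default 30-metabolite panel.

    The ``*_scale`` multipliers scale the default effect sizes (1.0 keeps
    the study conditions; 0.0 yields a null panel for calibration work).
    """
    panel: list[MetaboliteModel] = []
    for name, (mm, m0, s0, m28, s28, shape, sigs) in _PANEL_SPEC.items():
        signals = [
            SignalDefinition(name, lo, hi, n, mult, mm) for lo, hi, n, mult in sigs
        ]
        pooled = math.sqrt(0.5 * (s0**2 + s28**2))
        cattle = cattle_effect_scale * pooled if name in CATTLE_TYPE_METABOLITES else 0.0
        if name in AGING_TYPE_METABOLITES and max_day > 0:
            delta = agingtype_effect_scale * 0.8 * s28 / max_day
            if name in _AGING_TYPE_NEGATIVE:
                delta = -delta
        else:
            delta = 0.0
        panel.append(
            MetaboliteModel(
                name=name,
                mean_day0=m0,
                mean_day28=m28,
                within_sd_day0=s0,
                within_sd_day28=s28,
                trajectory_shape=shape,
                cattle_offset=cattle,
                agingtype_slope_delta=delta,
                animal_re_sd=0.3 * animal_re_scale * pooled,
                run_re_sd=0.1 * run_re_scale * pooled,
                nmr_signals=signals,
            )
        )
    names = [m.name for m in panel]
    assert len(names) == len(set(names)) == 30
    return panel


def default_signal_table(panel: list[MetaboliteModel] | None = None) -> list[SignalDefinition]:
    """Designated quantification signal (the first listed) per metabolite."""
    panel = panel if panel is not None else default_panel()
    return [m.nmr_signals[0] for m in panel]
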