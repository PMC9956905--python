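"""Synthetic study designs, concentration tables and raw spectra.

The generator emulates a beef-aging trial: heifers and cows, strip loins
aged dry (unpackaged) and wet (vacuum) for a fixed schedule of days, animals
assigned to aging runs.  Defaults reproduce the study conditions: 8 heifers,
7 cows, days {0, 7, 14, 21, 28}, 4 runs, one observation per
animal × day × aging type.

Concentrations follow the generative mirror of the screening model:

    c = trajectory_mean(day) + cattle_offset·[cow]
        + agingtype_slope_delta·day·[dry]
        + animal intercept + run intercept + residual(day)

with the residual SD interpolated linearly between the day-0 and day-28
within-SDs and negative draws resampled (not clipped), so there is no point
mass at zero.

Spectra are sums of Lorentzian multiplets.  Each signal's analytic
*baseline-corrected* area inside its own integration window (the same
linear-edge-baseline rule quantification uses) equals amount-in-tube (µmol)
× protons × a spectrometer response constant; the maleic-acid
internal-standard singlet is added with the area implied by its weighed
mass and purity, plus Gaussian baseline noise.  Because the correction is
mirrored analytically, the noise-free qNMR round trip is exact to
quadrature precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import MALEIC_ACID, MetaboliteModel, default_panel
from .spectra import SignalDefinition, Spectrum

__all__ = [
    "StudyDesign",
    "AcquisitionSettings",
    "generate_design",
    "simulate_concentrations",
    "simulate_spectrum",
    "simulate_dataset",
]

AGING_TYPES = ("dry", "wet")


@dataclass
class StudyDesign:
    """Sample layout of one aging trial."""

    animals: pd.DataFrame  # animal_id, cattle_type, aging_run
    aging_days: list[int]
    samples: pd.DataFrame  # sample_id, animal_id, cattle_type, aging_day, aging_type, aging_run

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def max_day(self) -> float:
        return float(max(self.aging_days))


@dataclass
class AcquisitionSettings:
    """Synthetic acquisition: axis, line shape, noise and qNMR bookkeeping.

    ``linewidth`` is the Lorentzian half-width at half-maximum in ppm
    (0.003 ppm = 1.2 Hz at 400 MHz).  ``response`` converts µmol-in-tube ×
    protons into intensity·ppm of integrated signal area.  ``noise_sd`` is
    the per-point baseline noise SD in intensity units.
    """

    ppm_min: float = -0.5
    ppm_max: float = 10.0
    n_points: int = 32768
    linewidth: float = 0.0015
    noise_sd: float = 0.02
    response: float = 1.0
    sample_mass_mg: float = 200.0
    extract_fraction: float = 1.0
    j_small: float = 0.004  # multiplet line spacings, ppm
    j_mid: float = 0.006
    j_large: float = 0.012

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if not self.ppm_min < self.ppm_max:
            raise ValueError("ppm_min must be < ppm_max")

    def axis(self) -> np.ndarray:
        return np.linspace(self.ppm_max, self.ppm_min, self.n_points)  # descending


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

def generate_design(
    n_heifers: int = 8,
    n_cows: int = 7,
    days: list[int] | None = None,
    n_runs: int = 4,
    seed: int = 42,
    n_replicates: int = 1,
) -> StudyDesign:
    """Randomly assign animals to aging runs and lay out all samples.

    Every animal contributes one sample per (day, aging type, replicate);
    run sizes differ by at most one.
    """
    days = list(days) if days is not None else [0, 7, 14, 21, 28]
    if n_heifers < 0 or n_cows < 0 or n_heifers + n_cows < 1:
        raise ValueError("need at least one animal")
    if n_runs < 1 or n_runs > n_heifers + n_cows:
        raise ValueError("n_runs must be in [1, n_animals]")
    if len(days) == 0:
        raise ValueError("days must be non-empty")
    if any(d < 0 for d in days):
        raise ValueError("days must be non-negative")
    if sorted(set(days)) != days:
        raise ValueError("days must be strictly increasing and unique")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")

    rng = np.random.default_rng(seed)
    n_animals = n_heifers + n_cows
    ids = [f"H{i + 1:02d}" for i in range(n_heifers)] + [f"C{i + 1:02d}" for i in range(n_cows)]
    types = ["heifer"] * n_heifers + ["cow"] * n_cows
    # balanced random run assignment: shuffle animals, deal round-robin
    order = rng.permutation(n_animals)
    runs = np.empty(n_animals, dtype=object)
    for pos, animal_idx in enumerate(order):
        runs[animal_idx] = f"R{pos % n_runs + 1}"
    animals = pd.DataFrame({"animal_id": ids, "cattle_type": types, "aging_run": runs})

    rows = []
    for _, a in animals.iterrows():
        for day in days:
            for atype in AGING_TYPES:
                for rep in range(1, n_replicates + 1):
                    sid = f"{a.animal_id}-d{day:02d}-{atype}"
                    if n_replicates > 1:
                        sid += f"-r{rep}"
                    rows.append(
                        {
                            "sample_id": sid,
                            "animal_id": a.animal_id,
                            "cattle_type": a.cattle_type,
                            "aging_day": day,
                            "aging_type": atype,
                            "aging_run": a.aging_run,
                        }
                    )
    samples = pd.DataFrame(rows)
    return StudyDesign(animals=animals, aging_days=days, samples=samples)


# ---------------------------------------------------------------------------
# concentrations
# ---------------------------------------------------------------------------

def simulate_concentrations(
    design: StudyDesign,
    panel: list[MetaboliteModel] | None = None,
    seed: int = 42,
) -> pd.DataFrame:
    """Simulate a samples × metabolites concentration table (µmol/g).

    Returns the design covariates followed by one column per metabolite.
    With all SDs and offsets zero the output equals the deterministic
    trajectory means exactly.
    """
    panel = panel if panel is not None else default_panel(max_day=design.max_day)
    if len(panel) == 0:
        raise ValueError("panel must be non-empty")
    names = [m.name for m in panel]
    if len(set(names)) != len(names):
        raise ValueError("metabolite names must be unique")

    rng = np.random.default_rng(seed)
    s = design.samples
    n = len(s)
    max_day = design.max_day
    animal_codes = pd.Categorical(s["animal_id"]).codes
    run_codes = pd.Categorical(s["aging_run"]).codes
    n_animals = animal_codes.max() + 1
    n_runs = run_codes.max() + 1
    is_cow = (s["cattle_type"] == "cow").to_numpy()
    is_dry = (s["aging_type"] == "dry").to_numpy()
    day = s["aging_day"].to_numpy(dtype=float)

    cols: dict[str, np.ndarray] = {}
    for m in panel:
        mean = np.array([m.mean_at(d, max_day) for d in day])
        mean = mean + m.cattle_offset * is_cow + m.agingtype_slope_delta * day * is_dry
        a_re = rng.normal(0.0, m.animal_re_sd, n_animals)[animal_codes] if m.animal_re_sd > 0 else 0.0
        r_re = rng.normal(0.0, m.run_re_sd, n_runs)[run_codes] if m.run_re_sd > 0 else 0.0
        sd = np.array([m.within_sd_at(d, max_day) for d in day])
        base = mean + a_re + r_re
        if np.any(sd > 0):
            vals = base + rng.normal(0.0, 1.0, n) * sd
            # truncate at zero by resampling the residual, not clipping
            for _ in range(200):
                bad = vals < 0
                if not bad.any():
                    break
                vals[bad] = base[bad] + rng.normal(0.0, 1.0, int(bad.sum())) * sd[bad]
            np.maximum(vals, 0.0, out=vals)
        else:
            vals = np.maximum(base, 0.0) if np.ndim(base) else base
        cols[m.name] = vals
    return pd.concat([s.reset_index(drop=True), pd.DataFrame(cols)], axis=1)


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

_MULTIPLET_PATTERNS = {
    "s": ([0.0], [1.0]),
    "d": ([-0.5, 0.5], [1.0, 1.0]),
    "t": ([-1.0, 0.0, 1.0], [1.0, 2.0, 1.0]),
    "q": ([-1.5, -0.5, 0.5, 1.5], [1.0, 3.0, 3.0, 1.0]),
    "dd": ([-1.0, -0.3, 0.3, 1.0], [1.0, 1.0, 1.0, 1.0]),
    "m": ([-2.0, -1.0, 0.0, 1.0, 2.0], [1.0, 2.0, 3.0, 2.0, 1.0]),
}


def _multiplet_peaks(sig: SignalDefinition, acq: AcquisitionSettings) -> tuple[np.ndarray, np.ndarray]:
    """Peak positions (ppm) and relative weights of a signal's multiplet.

    The line spacing is clamped so the outermost lines stay well inside the
    signal's integration window (clear of the baseline margins).
    """
    from .spectra import BASELINE_MARGIN

    offs, wts = _MULTIPLET_PATTERNS.get(sig.multiplicity, _MULTIPLET_PATTERNS["s"])
    offs = np.asarray(offs, dtype=float)
    j = {"d": acq.j_large, "t": acq.j_large, "q": acq.j_large,
         "dd": acq.j_mid}.get(sig.multiplicity, acq.j_small)
    max_off = float(np.max(np.abs(offs))) if np.any(offs) else 0.0
    if max_off > 0:
        budget = 0.5 * (sig.ppm_hi - sig.ppm_lo) - BASELINE_MARGIN - 4.0 * acq.linewidth
        j = min(j, max(budget, 0.0) / max_off)
    pos = sig.center + offs * j
    return pos, np.asarray(wts, dtype=float)


def _window_frac(pos: np.ndarray, wts: np.ndarray, lo: float, hi: float, gamma: float) -> float:
    """Fraction of the multiplet's total Lorentzian area inside [lo, hi]."""
    # Lorentzian CDF: (1/pi)·arctan(x/gamma) + 1/2
    frac = (np.arctan((hi - pos) / gamma) - np.arctan((lo - pos) / gamma)) / np.pi
    return float(np.sum(wts * frac) / np.sum(wts))


def _net_area_factor(
    pos: np.ndarray, wts: np.ndarray, lo: float, hi: float, gamma: float, margin: float
) -> float:
    """Analytic baseline-corrected area fraction of a multiplet in a window.

    Mirrors the linear-edge-baseline integration rule exactly: raw in-window
    area minus the trapezoid under the line through the two edge-margin mean
    heights, all in closed form, so quantification inverts the generator.
    """
    m = min(margin, 0.25 * (hi - lo))
    raw = _window_frac(pos, wts, lo, hi, gamma)
    mean_lo = _window_frac(pos, wts, lo, lo + m, gamma) / m
    mean_hi = _window_frac(pos, wts, hi - m, hi, gamma) / m
    return raw - 0.5 * (mean_lo + mean_hi) * (hi - lo)


_XTALK_CACHE: dict = {}  # geometry-only, so safe to share across samples


def _crosstalk_matrix(
    sigs: list[SignalDefinition],
    peaks: list[tuple[np.ndarray, np.ndarray]],
    gamma: float,
) -> np.ndarray:
    """response[i, j]: baseline-corrected integral of window i per unit area of signal j."""
    from .spectra import BASELINE_MARGIN

    k = len(sigs)
    out = np.empty((k, k))
    for i, win in enumerate(sigs):
        for j, (pos, wts) in enumerate(peaks):
            out[i, j] = _net_area_factor(
                pos, wts, win.ppm_lo, win.ppm_hi, gamma, BASELINE_MARGIN
            )
    return out


def simulate_spectrum(
    sample_conc: dict[str, float],
    shift_table: list[MetaboliteModel] | None = None,
    acq: AcquisitionSettings | None = None,
    seed: int = 42,
    sample_id: str = "synthetic",
) -> Spectrum:
    """Render one synthetic spectrum from a metabolite → µmol/g mapping.

    The in-window analytic area of each signal is exactly
    ``conc × mass_g × extract_fraction × N × response``; the internal
    standard contributes its own singlet in the maleic-acid region.
    """
    acq = acq if acq is not None else AcquisitionSettings()
    shift_table = shift_table if shift_table is not None else default_panel()
    by_name = {m.name: m for m in shift_table}
    missing = [k for k in sample_conc if k not in by_name]
    if missing:
        raise KeyError(f"no signal definition for metabolite(s): {missing}")

    ppm = acq.axis()
    inten = np.zeros_like(ppm)
    gamma = acq.linewidth
    mass_g = acq.sample_mass_mg / 1000.0

    std_sig = SignalDefinition(
        "maleic acid", MALEIC_ACID["ppm_lo"], MALEIC_ACID["ppm_hi"],
        MALEIC_ACID["n_protons"], "s", MALEIC_ACID["molar_mass"],
    )
    std_amount = MALEIC_ACID["mass_mg"] / MALEIC_ACID["molar_mass"] * MALEIC_ACID["purity"] * 1000.0

    sigs: list[SignalDefinition] = [std_sig]
    nominal: list[float] = [std_amount * std_sig.n_protons * acq.response]
    for name, conc in sample_conc.items():
        amount_umol = conc * mass_g * acq.extract_fraction
        for sig in by_name[name].nmr_signals:
            sigs.append(sig)
            nominal.append(amount_umol * sig.n_protons * acq.response)

    # Lorentzian tails overlap neighbouring windows; solve the (analytic)
    # crosstalk system so every window's baseline-corrected integral equals
    # its nominal area exactly in the noise-free spectrum
    peaks = [_multiplet_peaks(s, acq) for s in sigs]
    cache_key = (
        gamma, acq.j_small, acq.j_mid, acq.j_large,
        tuple((s.ppm_lo, s.ppm_hi, s.multiplicity) for s in sigs),
    )
    response = _XTALK_CACHE.get(cache_key)
    if response is None:
        response = _crosstalk_matrix(sigs, peaks, gamma)
        _XTALK_CACHE[cache_key] = response
    areas = np.linalg.solve(response, np.asarray(nominal))

    for (pos, wts), total in zip(peaks, areas):
        amp = total / np.sum(wts)
        for p, w in zip(pos, wts):
            inten[:] += amp * w * (gamma / np.pi) / ((ppm - p) ** 2 + gamma**2)

    if acq.noise_sd > 0:
        rng = np.random.default_rng(seed)
        inten += rng.normal(0.0, acq.noise_sd, inten.size)

    meta = {
        "sample_id": sample_id,
        "standard": dict(MALEIC_ACID),
        "sample_mass_mg": acq.sample_mass_mg,
        "extract_fraction": acq.extract_fraction,
    }
    return Spectrum(ppm, inten, meta)


def simulate_dataset(
    design: StudyDesign | None = None,
    panel: list[MetaboliteModel] | None = None,
    acq: AcquisitionSettings | None = None,
    seed: int = 42,
) -> tuple[StudyDesign, pd.DataFrame, list[Spectrum]]:
    """Full generator: design + concentration table + one spectrum per sample."""
    ss = np.random.SeedSequence(seed)
    s_design, s_conc, s_spec = (int(x) for x in ss.generate_state(3) % (2**31))
    if design is None:
        design = generate_design(seed=s_design)
    panel = panel if panel is not None else default_panel(max_day=design.max_day)
    acq = acq if acq is not None else AcquisitionSettings()
    conc = simulate_concentrations(design, panel, seed=s_conc)
    names = [m.name for m in panel]
    spec_seeds = np.random.SeedSequence(s_spec).generate_state(len(conc)) % (2**31)
    spectra = []
    for i in range(len(conc)):
        row = conc.iloc[i]
        mapping = {n: float(row[n]) for n in names}
        spectra.append(
            simulate_spectrum(
                mapping, panel, acq, seed=int(spec_seeds[i]), sample_id=str(row["sample_id"])
            )
        )
    return design, conc, spectra


def write_dataset(
    outdir,
    design: StudyDesign,
    conc: pd.DataFrame,
    spectra: list[Spectrum],
) -> None:
    """Write metadata TSV, concentration TSV and one spectrum TSV per sample."""
    from pathlib import Path

    from .spectra import write_spectrum

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design.samples.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    conc.to_csv(outdir / "concentrations.tsv", sep="\t", index=False)
    specdir = outdir / "spectra"
    specdir.mkdir(exist_ok=True)
    for sp in spectra:
        write_spectrum(sp, specdir / f"{sp.metadata['sample_id']}.tsv")
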