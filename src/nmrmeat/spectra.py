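"""Containers and I/O for 1-D ¹H-NMR spectra.

A spectrum is a strictly monotone ppm axis with one intensity per point.
Spectra are stored with a *descending* ppm axis internally (the NMR plotting
convention); readers accept either orientation.  Supported on-disk formats
are a two-column ppm/intensity TSV and a minimal JCAMP-DX subset (a single
``##XYDATA=(XY..XY)`` block with explicit x/y pairs).

Integration is plain trapezoidal quadrature on the native grid with linear
interpolation at interval endpoints, which makes it exactly additive over
adjacent intervals.  No phasing, baseline correction or peak fitting is
performed here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Spectrum",
    "SignalDefinition",
    "SpectrumParseError",
    "NonMonotoneAxisError",
    "LengthMismatchError",
    "MissingStandardError",
    "read_spectrum",
    "write_spectrum",
    "read_signal_table",
    "write_signal_table",
    "normalize_to_standard",
    "integrate",
    "MALEIC_ACID_REGION",
]

#: Default integration window for the maleic-acid internal-standard singlet.
MALEIC_ACID_REGION = (6.15, 6.40)

#: Width (ppm) of the edge margins used to anchor the linear local baseline.
BASELINE_MARGIN = 0.006


class SpectrumParseError(ValueError):
    """A spectrum file could not be parsed."""


class NonMonotoneAxisError(SpectrumParseError):
    """The ppm axis is not strictly monotone."""


class LengthMismatchError(SpectrumParseError):
    """Axis and intensity arrays differ in length."""


class MissingStandardError(ValueError):
    """The internal-standard region carries no (positive) integral."""


@dataclass
class Spectrum:
    """One 1-D spectrum: ppm axis, intensities and free-form metadata."""

    ppm: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.intensity.ndim != 1:
            raise SpectrumParseError("ppm and intensity must be 1-D arrays")
        if self.ppm.size != self.intensity.size:
            raise LengthMismatchError(
                f"axis length {self.ppm.size} != intensity length {self.intensity.size}"
            )
        if self.ppm.size < 2:
            raise SpectrumParseError("a spectrum needs at least two points")
        d = np.diff(self.ppm)
        if np.all(d > 0):  # ascending input: store descending
            self.ppm = self.ppm[::-1].copy()
            self.intensity = self.intensity[::-1].copy()
        elif not np.all(d < 0):
            raise NonMonotoneAxisError("ppm axis must be strictly monotone")

    # -- convenience views -------------------------------------------------
    @property
    def ppm_ascending(self) -> np.ndarray:
        return self.ppm[::-1]

    @property
    def intensity_ascending(self) -> np.ndarray:
        return self.intensity[::-1]

    @property
    def ppm_range(self) -> tuple[float, float]:
        return float(self.ppm[-1]), float(self.ppm[0])

    def copy(self) -> "Spectrum":
        return Spectrum(self.ppm.copy(), self.intensity.copy(), dict(self.metadata))


@dataclass(frozen=True)
class SignalDefinition:
    """A quantifiable NMR signal: integration window plus qNMR constants.

    ``n_protons`` is the number of protons contributing to the signal and
    ``molar_mass`` the metabolite's molecular mass in g/mol.
    """

    metabolite: str
    ppm_lo: float
    ppm_hi: float
    n_protons: int
    multiplicity: str = "s"
    molar_mass: float = float("nan")

    def __post_init__(self) -> None:
        if not self.ppm_lo < self.ppm_hi:
            raise ValueError(f"{self.metabolite}: ppm_lo must be < ppm_hi")
        if self.n_protons < 1:
            raise ValueError(f"{self.metabolite}: n_protons must be >= 1")

    @property
    def center(self) -> float:
        return 0.5 * (self.ppm_lo + self.ppm_hi)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_spectrum(path: str | Path) -> Spectrum:
    """Read a spectrum from a two-column TSV or a minimal JCAMP-DX file.

    The format is sniffed: files whose first non-blank line starts with
    ``##`` are treated as JCAMP-DX, anything else as TSV.
    """
    path = Path(path)
    text = path.read_text()
    stripped = text.lstrip()
    if stripped.startswith("##"):
        ppm, inten = _parse_jcamp(text, path)
    else:
        ppm, inten = _parse_tsv(text, path)
    spec = Spectrum(ppm, inten, {"source": str(path)})
    return spec


def _parse_tsv(text: str, path: Path) -> tuple[np.ndarray, np.ndarray]:
    xs: list[float] = []
    ys: list[float] = []
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise SpectrumParseError(f"{path}:{lineno}: expected two columns, got {len(parts)}")
        try:
            xs.append(float(parts[0]))
            ys.append(float(parts[1]))
        except ValueError as exc:
            raise SpectrumParseError(f"{path}:{lineno}: non-numeric value") from exc
    if len(xs) < 2:
        raise SpectrumParseError(f"{path}: fewer than two data points")
    return np.array(xs), np.array(ys)


_JCAMP_PAIR = re.compile(r"([-+]?[\d.]+(?:[eE][-+]?\d+)?)[,\s]+([-+]?[\d.]+(?:[eE][-+]?\d+)?)")


def _parse_jcamp(text: str, path: Path) -> tuple[np.ndarray, np.ndarray]:
    lines = text.splitlines()
    xs: list[float] = []
    ys: list[float] = []
    in_data = False
    xfactor = yfactor = 1.0
    for line in lines:
        line = line.strip()
        if line.startswith("##XFACTOR="):
            xfactor = float(line.split("=", 1)[1])
        elif line.startswith("##YFACTOR="):
            yfactor = float(line.split("=", 1)[1])
        elif line.startswith("##XYDATA="):
            in_data = True
            continue
        elif line.startswith("##END"):
            in_data = False
        elif line.startswith("##"):
            continue
        elif in_data:
            for m in _JCAMP_PAIR.finditer(line):
                xs.append(float(m.group(1)) * xfactor)
                ys.append(float(m.group(2)) * yfactor)
    if len(xs) < 2:
        raise SpectrumParseError(f"{path}: no XYDATA pairs found")
    return np.array(xs), np.array(ys)


def write_spectrum(spectrum: Spectrum, path: str | Path, fmt: str = "tsv") -> Path:
    """Write a spectrum as TSV (default) or the JCAMP-DX subset."""
    path = Path(path)
    if fmt == "tsv":
        lines = [f"{x:.12g}\t{y:.12g}" for x, y in zip(spectrum.ppm, spectrum.intensity)]
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "jcamp":
        head = [
            "##TITLE=" + str(spectrum.metadata.get("sample_id", "spectrum")),
            "##JCAMP-DX=5.00",
            "##DATA TYPE=NMR SPECTRUM",
            "##XUNITS=PPM",
            "##YUNITS=ARBITRARY",
            "##XFACTOR=1.0",
            "##YFACTOR=1.0",
            f"##NPOINTS={spectrum.ppm.size}",
            "##XYDATA=(XY..XY)",
        ]
        body = [f"{x:.12g}, {y:.12g}" for x, y in zip(spectrum.ppm, spectrum.intensity)]
        path.write_text("\n".join(head + body + ["##END="]) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def read_signal_table(path: str | Path) -> list[SignalDefinition]:
    """Read a signal-definition TSV (metabolite, ppm_lo, ppm_hi, N, multiplicity, M)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            SignalDefinition(
                metabolite=str(row.metabolite),
                ppm_lo=float(row.ppm_lo),
                ppm_hi=float(row.ppm_hi),
                n_protons=int(row.n_protons),
                multiplicity=str(getattr(row, "multiplicity", "s")),
                molar_mass=float(getattr(row, "molar_mass", float("nan"))),
            )
        )
    return out


def write_signal_table(signals: list[SignalDefinition], path: str | Path) -> Path:
    import pandas as pd

    df = pd.DataFrame(
        {
            "metabolite": [s.metabolite for s in signals],
            "ppm_lo": [s.ppm_lo for s in signals],
            "ppm_hi": [s.ppm_hi for s in signals],
            "n_protons": [s.n_protons for s in signals],
            "multiplicity": [s.multiplicity for s in signals],
            "molar_mass": [s.molar_mass for s in signals],
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


# ---------------------------------------------------------------------------
# integration and normalization
# ---------------------------------------------------------------------------

def _cum_trapz_at(xs: np.ndarray, ys: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Exact trapezoid cumulative integral of (xs, ys) evaluated at ``pts``.

    ``xs`` must be ascending.  Endpoint intensities are obtained by linear
    interpolation, so the result is additive over adjacent intervals.
    """
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (ys[1:] + ys[:-1]) * np.diff(xs))])
    pts = np.asarray(pts, dtype=float)
    idx = np.clip(np.searchsorted(xs, pts, side="right") - 1, 0, xs.size - 2)
    y_at = np.interp(pts, xs, ys)
    frac = cum[idx] + 0.5 * (ys[idx] + y_at) * (pts - xs[idx])
    return frac


def integrate(
    spectrum: Spectrum,
    ppm_lo: float,
    ppm_hi: float,
    baseline: str = "none",
    margin: float = BASELINE_MARGIN,
) -> float:
    """Trapezoidal integral of the spectrum over the closed interval [lo, hi].

    With ``baseline="linear"`` a local linear baseline is subtracted: the
    mean intensity over the two edge margins (width ``margin``) anchors a
    straight line whose area is removed.  This suppresses the slowly varying
    tails of distant peaks, mimicking manual integral placement.
    """
    if not ppm_lo < ppm_hi:
        raise ValueError("ppm_lo must be < ppm_hi")
    lo, hi = spectrum.ppm_range
    if ppm_lo < lo - 1e-12 or ppm_hi > hi + 1e-12:
        raise ValueError(
            f"interval [{ppm_lo}, {ppm_hi}] outside spectrum range [{lo}, {hi}]"
        )
    xs = spectrum.ppm_ascending
    ys = spectrum.intensity_ascending
    if baseline == "none":
        vals = _cum_trapz_at(xs, ys, np.array([ppm_lo, ppm_hi]))
        return float(vals[1] - vals[0])
    if baseline != "linear":
        raise ValueError(f"unknown baseline mode {baseline!r}")
    m = min(margin, 0.25 * (ppm_hi - ppm_lo))
    pts = np.array([ppm_lo, ppm_lo + m, ppm_hi - m, ppm_hi])
    c = _cum_trapz_at(xs, ys, pts)
    raw = float(c[3] - c[0])
    mean_lo = float(c[1] - c[0]) / m
    mean_hi = float(c[3] - c[2]) / m
    return raw - 0.5 * (mean_lo + mean_hi) * (ppm_hi - ppm_lo)


def integrate_many(spectrum: Spectrum, edges: np.ndarray) -> np.ndarray:
    """Integrals over consecutive intervals defined by ascending ``edges``."""
    xs = spectrum.ppm_ascending
    ys = spectrum.intensity_ascending
    vals = _cum_trapz_at(xs, ys, np.asarray(edges, dtype=float))
    return np.diff(vals)


def normalize_to_standard(
    spectrum: Spectrum,
    standard_region: tuple[float, float] = MALEIC_ACID_REGION,
    target_integral: float = 1.0,
) -> Spectrum:
    """Scale the whole spectrum so the internal-standard region integrates to target.

    This is the global maleic-acid scaling step: one multiplicative factor,
    idempotent by construction, removes any acquisition gain.
    """
    if target_integral <= 0:
        raise ValueError("target_integral must be positive")
    current = integrate(spectrum, *standard_region)
    if current <= 0:
        raise MissingStandardError(
            f"standard region {standard_region} has non-positive integral {current:.3g}"
        )
    factor = target_integral / current
    out = spectrum.copy()
    out.intensity = out.intensity * factor
    out.metadata = {
        **out.metadata,
        "normalized": True,
        "standard_region": tuple(standard_region),
        "standard_integral": target_integral,
        "scale_factor": float(out.metadata.get("scale_factor", 1.0)) * factor,
    }
    return out
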