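"""Spectral bucketing and univariate (auto)scaling.

Two named schemes mirror the study's analysis tracks:

* ``aging_time_scheme``: 250 equal buckets over 0.50-4.67 ppm, no exclusions
  (used for aging-time PLS-R and cattle-type OPLS-DA);
* ``aging_type_scheme``: 200 equal buckets over 1.1-9.0 ppm with the water
  region 4.7-5.2 ppm and the 6.8-8.0 ppm region excluded (used for the
  dry/wet PCA-LDA).  The stated bucket count is the count *before*
  exclusion; buckets overlapping an excluded window are dropped.

"Univariate scaling" is autoscaling: per-bucket mean-centering and division
by the (n-1) SD.  The fitted means/SDs are stored so held-out samples can be
transformed with training-fold statistics only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra import Spectrum, integrate_many

__all__ = [
    "BucketScheme",
    "BucketTable",
    "AGING_TIME_SCHEME",
    "AGING_TYPE_SCHEME",
    "bucket",
    "assemble_bucket_table",
    "univariate_scale",
    "apply_scaling",
]


@dataclass(frozen=True)
class BucketScheme:
    """Equal-width bucketing of a ppm region with optional exclusion windows."""

    ppm_lo: float
    ppm_hi: float
    n_buckets: int
    exclusions: tuple[tuple[float, float], ...] = ()
    name: str = ""

    def __post_init__(self) -> None:
        if not self.ppm_lo < self.ppm_hi:
            raise ValueError("ppm_lo must be < ppm_hi")
        if self.n_buckets < 1:
            raise ValueError("n_buckets must be >= 1")

    @property
    def width(self) -> float:
        return (self.ppm_hi - self.ppm_lo) / self.n_buckets

    def edges(self) -> np.ndarray:
        return np.linspace(self.ppm_lo, self.ppm_hi, self.n_buckets + 1)

    def retained_mask(self) -> np.ndarray:
        """True for buckets that do not overlap any exclusion window."""
        e = self.edges()
        lo, hi = e[:-1], e[1:]
        keep = np.ones(self.n_buckets, dtype=bool)
        for xlo, xhi in self.exclusions:
            keep &= ~((lo < xhi) & (hi > xlo))  # nonzero overlap drops the bucket
        return keep

    def centers(self) -> np.ndarray:
        e = self.edges()
        return 0.5 * (e[:-1] + e[1:])


AGING_TIME_SCHEME = BucketScheme(0.50, 4.67, 250, (), "aging_time")
AGING_TYPE_SCHEME = BucketScheme(1.1, 9.0, 200, ((4.7, 5.2), (6.8, 8.0)), "aging_type")


def bucket(spectrum: Spectrum, scheme: BucketScheme) -> np.ndarray:
    """Integrals of the spectrum over each *retained* bucket of the scheme."""
    lo, hi = spectrum.ppm_range
    if scheme.ppm_lo < lo - 1e-12 or scheme.ppm_hi > hi + 1e-12:
        raise ValueError(
            f"scheme region [{scheme.ppm_lo}, {scheme.ppm_hi}] outside spectrum range"
        )
    vals = integrate_many(spectrum, scheme.edges())
    return vals[scheme.retained_mask()]


@dataclass
class BucketTable:
    """Samples × retained-buckets matrix with ppm annotation and scaling state."""

    values: pd.DataFrame  # index = sample_id, columns = bucket center ppm (str)
    scheme: BucketScheme
    scaled: bool = False
    means: np.ndarray | None = None
    sds: np.ndarray | None = None
    constant_flags: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return len(self.values)

    def to_tsv(self, path) -> None:
        self.values.rename_axis("sample_id").to_csv(path, sep="\t")


def assemble_bucket_table(
    spectra: list[Spectrum],
    scheme: BucketScheme,
    sample_ids: list[str] | None = None,
) -> BucketTable:
    """Bucket every spectrum and stack the rows in input order."""
    if len(spectra) == 0:
        raise ValueError("need at least one spectrum")
    ranges = {s.ppm_range for s in spectra}
    lo = max(r[0] for r in ranges)
    hi = min(r[1] for r in ranges)
    if scheme.ppm_lo < lo - 1e-12 or scheme.ppm_hi > hi + 1e-12:
        raise ValueError("spectra axes do not all cover the scheme region")
    rows = np.vstack([bucket(s, scheme) for s in spectra])
    if sample_ids is None:
        sample_ids = [
            str(s.metadata.get("sample_id", f"S{i + 1}")) for i, s in enumerate(spectra)
        ]
    centers = scheme.centers()[scheme.retained_mask()]
    df = pd.DataFrame(rows, index=sample_ids, columns=[f"{c:.4f}" for c in centers])
    return BucketTable(values=df, scheme=scheme)


def _fit_scale(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    const = sds <= 0
    sds_safe = np.where(const, 1.0, sds)
    return means, sds_safe, const


def univariate_scale(table: BucketTable) -> BucketTable:
    """Autoscale every bucket column (mean 0, SD 1); idempotent.

    Constant columns become all-zero and are flagged.  The fitted means and
    SDs are stored on the returned table for out-of-fold application.
    """
    if table.n_samples < 2:
        raise ValueError("scaling needs at least two samples")
    X = table.matrix
    means, sds, const = _fit_scale(X)
    Z = (X - means) / sds
    Z[:, const] = 0.0
    df = pd.DataFrame(Z, index=table.values.index, columns=table.values.columns)
    return BucketTable(
        values=df,
        scheme=table.scheme,
        scaled=True,
        means=means,
        sds=np.where(const, 0.0, sds),
        constant_flags=const,
        metadata=dict(table.metadata),
    )


def apply_scaling(X_new: np.ndarray, means: np.ndarray, sds: np.ndarray) -> np.ndarray:
    """Apply previously fitted autoscaling (training-fold statistics) to new rows."""
    const = sds <= 0
    sds_safe = np.where(const, 1.0, sds)
    Z = (np.asarray(X_new, dtype=float) - means) / sds_safe
    Z[:, const] = 0.0
    return Z
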