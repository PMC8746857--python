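"""Spectral blinding and binning into the PCA feature matrix.

Six regions irrelevant to oil composition — the low/high-frequency
noise flanks, the TMS reference peak and satellites, and the residual
CHCl3 main peak and satellites — are blinded before analysis.  The
remaining axis is bucketed into regular 0.05 ppm bins with summed
intensity; bin edges sit on the absolute grid of integer multiples of
the bin width so bin identity is reproducible across spectral windows.
A bin that overlaps a blinded region at all is dropped whole.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .spectra import Spectrum1D, SpectrumValidationError

__all__ = [
    "BlindRegion",
    "BinnedVector",
    "FeatureMatrix",
    "default_blind_regions",
    "blind_regions_from_yaml",
    "bin_spectrum",
    "assemble_matrix",
]

DEFAULT_BIN_WIDTH = 0.05


@dataclass(frozen=True)
class BlindRegion:
    """A ppm interval excluded from multivariate analysis."""

    low_ppm: float
    high_ppm: float
    label: str = ""

    def __post_init__(self) -> None:
        lo = min(self.low_ppm, self.high_ppm)
        hi = max(self.low_ppm, self.high_ppm)
        if lo == hi:
            raise SpectrumValidationError("blind region must have low < high")
        object.__setattr__(self, "low_ppm", lo)
        object.__setattr__(self, "high_ppm", hi)

    def overlaps(self, low: float, high: float) -> bool:
        """Positive-length intersection with the half-open bin [low, high)."""
        return low < self.high_ppm and high > self.low_ppm


def default_blind_regions() -> list[BlindRegion]:
    """The six standard blinded regions (bounds stored as min, max)."""
    return [
        BlindRegion(-3.9, -1.0, "low-frequency noise region"),
        BlindRegion(-0.2266, 0.1892, "TMS peak and satellites"),
        BlindRegion(6.995, 7.006, "CDCl3 satellite peak"),
        BlindRegion(7.195, 7.325, "CDCl3 main peak"),
        BlindRegion(7.502, 7.548, "CDCl3 satellite peak"),
        BlindRegion(13.02, 16.17, "high-frequency noise region"),
    ]


def blind_regions_from_yaml(path: str | Path) -> list[BlindRegion]:
    """Load regions from a YAML list of {low, high, label} maps."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [BlindRegion(float(r["low"]), float(r["high"]), r.get("label", ""))
            for r in raw]


@dataclass
class BinnedVector:
    """One sample's binned intensities, labelled by bin centres."""

    values: np.ndarray
    bin_centers: np.ndarray
    bin_width: float
    sample_id: str = ""


def bin_spectrum(spectrum: Spectrum1D,
                 bin_width: float = DEFAULT_BIN_WIDTH,
                 regions: Sequence[BlindRegion] | None = None,
                 sample_id: str = "") -> BinnedVector:
    """Regular binning with summed intensity and drop-whole-bin blinding.

    Bin k covers the half-open interval [k*w, (k+1)*w) on the ascending
    ppm line; a point contributes to exactly one bin.  Only bins fully
    covered by the axis are produced (partial edge bins are discarded,
    so a small referencing shift of the axis cannot change the bin
    identity of a sample).  Bins whose interval intersects any blinded
    region are removed entirely.  Raises if blinding leaves no bins.
    """
    if bin_width <= 0:
        raise SpectrumValidationError("bin_width must be positive")
    regions = default_blind_regions() if regions is None else list(regions)
    ppm = spectrum.ppm
    idx = np.floor(ppm / bin_width + 1e-12).astype(np.int64)
    k_min, k_max = int(idx.min()), int(idx.max())
    sums = np.bincount(idx - k_min, weights=spectrum.intensity,
                       minlength=k_max - k_min + 1)
    ks = np.arange(k_min, k_max + 1)
    lows = ks * bin_width
    step = float(np.abs(np.diff(ppm)).max()) if ppm.size > 1 else bin_width
    keep = (lows >= ppm.min() - step) & (lows + bin_width <= ppm.max() + step)
    for region in regions:
        keep &= ~((lows < region.high_ppm) & (lows + bin_width > region.low_ppm))
    if not keep.any():
        raise SpectrumValidationError("empty feature vector: all bins blinded")
    return BinnedVector(
        values=sums[keep],
        bin_centers=(lows[keep] + bin_width / 2.0),
        bin_width=bin_width,
        sample_id=sample_id,
    )


@dataclass
class FeatureMatrix:
    """Samples x bins intensity sums with bin-centre column labels."""

    values: np.ndarray
    bin_centers: np.ndarray
    sample_ids: list[str]
    bin_width: float = DEFAULT_BIN_WIDTH

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        if self.values.ndim != 2:
            raise SpectrumValidationError("feature matrix must be 2D")
        if self.values.shape[1] != self.bin_centers.size:
            raise SpectrumValidationError("column count != number of bin centres")
        if len(self.sample_ids) != self.values.shape[0]:
            raise SpectrumValidationError("sample_ids length != row count")
        if not np.all(np.isfinite(self.values)):
            raise SpectrumValidationError("feature matrix contains NaN/Inf")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=[f"{c:.3f}" for c in self.bin_centers])

    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        df = self.to_dataframe()
        df.index.name = "sample_id"
        df.to_csv(path)
        return path

    @classmethod
    def read_csv(cls, path: str | Path,
                 bin_width: float = DEFAULT_BIN_WIDTH) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(
            values=df.to_numpy(dtype=float),
            bin_centers=np.array([float(c) for c in df.columns]),
            sample_ids=[str(i) for i in df.index],
            bin_width=bin_width,
        )


def assemble_matrix(vectors: Sequence[BinnedVector],
                    sample_ids: Sequence[str] | None = None) -> FeatureMatrix:
    """Stack binned vectors row-wise, preserving input order.

    All vectors must share identical bin centres (same axis coverage,
    same blinding); mismatches raise an alignment error naming the
    offending samples.
    """
    if not vectors:
        raise SpectrumValidationError("no vectors to assemble")
    ref = vectors[0]
    ids = list(sample_ids) if sample_ids is not None else [
        v.sample_id or f"sample{i}" for i, v in enumerate(vectors)
    ]
    bad = [
        ids[i] for i, v in enumerate(vectors)
        if v.bin_centers.size != ref.bin_centers.size
        or not np.allclose(v.bin_centers, ref.bin_centers)
    ]
    if bad:
        raise SpectrumValidationError(
            "bin centres differ from the first sample for: " + ", ".join(bad)
        )
    return FeatureMatrix(
        values=np.vstack([v.values for v in vectors]),
        bin_centers=ref.bin_centers.copy(),
        sample_ids=ids,
        bin_width=ref.bin_width,
    )
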