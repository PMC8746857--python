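"""End-to-end authenticity screen: simulate -> process -> bin -> fit -> classify.

:class:`OilScreen` bundles the acquisition, processing, binning and
classification settings of one experiment and exposes the study-level
operations: training the reference model on an olive panel, classifying
samples, and measuring detection limits for an adulterant over a series
of v/v fractions.

Reproducibility model: one global seed; every simulated sample draws its
randomness from an independent substream derived by stable hashing of
the sample id, so results do not depend on simulation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import chemometrics, features, preprocess, synth
from .chemometrics import ClassificationResult, EllipseModel, PCAModel
from .features import BlindRegion, FeatureMatrix
from .spectra import Spectrum1D
from .synth import AcquisitionParams, OilComposition

__all__ = ["OilScreen", "TrainedScreen", "PipelineConfig", "load_config"]

DEFAULT_SEED_OIL_REFERENCES = (
    "high_oleic_canola", "hazelnut", "peanut", "high_oleic_safflower",
    "high_oleic_sunflower", "grapeseed", "hempseed",
)


@dataclass
class TrainedScreen:
    """Frozen artifacts of a trained screen."""

    pca: PCAModel
    ellipse: EllipseModel
    reference_centroids: dict[str, tuple[float, float]]
    panel_ids: list[str]


@dataclass
class OilScreen:
    """Configuration + operations of the authenticity screen."""

    acq: AcquisitionParams = field(default_factory=AcquisitionParams)
    proc: preprocess.ProcessingParams = field(
        default_factory=preprocess.ProcessingParams)
    bin_width: float = features.DEFAULT_BIN_WIDTH
    regions: list[BlindRegion] = field(default_factory=features.default_blind_regions)
    confidence: float = 0.95
    chemistry: dict = field(default_factory=synth.load_chemistry)
    composition_table: dict = field(default_factory=synth.load_composition_table)

    # -- single-sample plumbing -------------------------------------------

    def simulate_spectrum(self, oil: OilComposition,
                          rng: np.random.Generator) -> Spectrum1D:
        peaks = synth.composition_to_peaks(oil, self.chemistry)
        fid = synth.simulate_fid(peaks, self.acq, rng=rng)
        return preprocess.process(fid, self.proc)

    def features_of(self, spectrum: Spectrum1D,
                    sample_id: str = "") -> features.BinnedVector:
        return features.bin_spectrum(spectrum, self.bin_width, self.regions,
                                     sample_id=sample_id)

    def simulate_features(self, oil: OilComposition, sample_id: str,
                          seed: int) -> features.BinnedVector:
        rng = synth.rng_for(seed, sample_id)
        return self.features_of(self.simulate_spectrum(oil, rng), sample_id)

    # -- panels ------------------------------------------------------------

    def olive_panel(self, n: int, seed: int,
                    base: str = "olive") -> list[OilComposition]:
        """n authentic olive bottles drawn from the cultivar distribution."""
        base_oil = synth.make_oil(base, table=self.composition_table)
        rel_sd = self.composition_table.get("cultivar_rel_sd", 0.0)
        return [
            synth.sample_cultivar(
                base_oil, synth.rng_for(seed, f"panel/{base}/{i}"),
                rel_sd=rel_sd, label=f"{base}_{i:03d}",
            )
            for i in range(n)
        ]

    def feature_matrix(self, oils: Sequence[OilComposition],
                       seed: int, prefix: str = "") -> FeatureMatrix:
        vectors = [
            self.simulate_features(oil, f"{prefix}{oil.label}", seed)
            for oil in oils
        ]
        return features.assemble_matrix(vectors)

    # -- training ----------------------------------------------------------

    def train(self, n_olive: int = 20, seed: int = 0,
              reference_oils: Sequence[str] = DEFAULT_SEED_OIL_REFERENCES,
              ) -> TrainedScreen:
        """Fit PCA + authenticity ellipse on a simulated olive panel.

        The PCA and the confidence ellipse are both fitted on the
        authentic reference class only.  Pure seed-oil reference
        centroids (one noise-free spectrum each) are projected into the
        fitted plane so flagged samples can be attributed to their
        nearest pure oil.
        """
        panel = self.olive_panel(n_olive, seed)
        matrix = self.feature_matrix(panel, seed, prefix="train/")
        pca = chemometrics.fit_chemometric_model(matrix, n_components=2)
        ellipse = chemometrics.fit_ellipse(pca.scores[:, :2], self.confidence)

        centroids: dict[str, tuple[float, float]] = {}
        quiet = replace(self.acq, noise_sigma=0.0, shift_jitter_sigma=0.0)
        quiet_screen = replace(self, acq=quiet)
        names = [n for n in reference_oils if n in self.composition_table["oils"]]
        for name in names:
            oil = synth.make_oil(name, table=self.composition_table)
            vec = quiet_screen.simulate_features(oil, f"centroid/{name}", seed)
            mat = features.assemble_matrix([vec])
            s = chemometrics.project(pca, mat)[0]
            centroids[name] = (float(s[0]), float(s[1]))
        olive_centroid = ellipse.center
        centroids["olive"] = (float(olive_centroid[0]), float(olive_centroid[1]))
        return TrainedScreen(
            pca=pca, ellipse=ellipse, reference_centroids=centroids,
            panel_ids=list(matrix.sample_ids),
        )

    # -- classification ----------------------------------------------------

    def classify_matrix(self, trained: TrainedScreen,
                        matrix: FeatureMatrix) -> list[ClassificationResult]:
        return chemometrics.classify(trained.pca, trained.ellipse, matrix,
                                     trained.reference_centroids)

    def classify_oils(self, trained: TrainedScreen,
                      oils: Sequence[OilComposition], seed: int,
                      prefix: str = "test/") -> list[ClassificationResult]:
        matrix = self.feature_matrix(oils, seed, prefix=prefix)
        return self.classify_matrix(trained, matrix)

    # -- detection limits ----------------------------------------------------

    def detection_limit(self, trained: TrainedScreen,
                        adulterant: OilComposition,
                        fractions: Sequence[float],
                        replicates: int = 50,
                        flag_rate: float = 0.95,
                        seed: int = 0,
                        base: str = "olive") -> tuple[float | None, pd.DataFrame]:
        """Smallest v/v adulterant fraction flagged at >= flag_rate.

        For each fraction, ``replicates`` adulterated bottles are
        simulated — each with a fresh olive draw from the cultivar
        distribution, fresh noise and fresh shift jitter — classified
        against the trained ellipse, and the flagged proportion
        recorded.  Returns ``(limit, table)`` where ``limit`` is None if
        no fraction reaches the required flag rate, and ``table`` has
        one row per fraction with its empirical flag rate.
        """
        fracs = [float(f) for f in fractions]
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError("fractions must lie in [0, 1]")
        if sorted(fracs) != fracs:
            raise ValueError("fractions must be sorted ascending")
        if replicates < 1:
            raise ValueError("replicates must be >= 1")
        base_oil = synth.make_oil(base, table=self.composition_table)
        rel_sd = self.composition_table.get("cultivar_rel_sd", 0.0)
        rows = []
        limit: float | None = None
        for frac in fracs:
            flagged = 0
            oils = []
            for r in range(replicates):
                tag = f"dl/{adulterant.label}/{frac:g}/{r}"
                olive = synth.sample_cultivar(
                    base_oil, synth.rng_for(seed, tag + "/cv"), rel_sd=rel_sd)
                if frac == 0.0:
                    oils.append(olive)
                elif frac == 1.0:
                    oils.append(adulterant)
                else:
                    oils.append(synth.mix_oils(
                        [(olive, 1.0 - frac), (adulterant, frac)]))
            results = self.classify_oils(
                trained, oils, seed,
                prefix=f"dl/{adulterant.label}/{frac:g}/")
            flagged = sum(1 for r in results if not r.authentic)
            rate = flagged / replicates
            rows.append({"fraction": frac, "flag_rate": rate,
                         "replicates": replicates})
            if limit is None and rate >= flag_rate:
                limit = frac
        return limit, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# YAML pipeline configuration
# ---------------------------------------------------------------------------

class _AcqConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    spectrometer_freq: float = 400.13
    sweep_ppm: float = 20.0
    n_points: int = 65536
    axis_low_ppm: float = -3.9
    axis_high_ppm: float = 16.1
    noise_sigma: float = synth.DEFAULT_NOISE_SIGMA
    shift_jitter_sigma: float = 0.002


class _ProcConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    lb_hz: float = 0.3
    baseline_order: int = 5
    norm_mode: str = "omega3_peak"
    norm_center_ppm: float = 0.975
    norm_window_ppm: float = 0.05
    phase: str = "auto"
    baseline: bool = True
    ref_peak_ppm: float | None = 0.0
    ref_window_ppm: float = 0.05


class _RegionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    low: float
    high: float
    label: str = ""


class PipelineConfig(BaseModel):
    """Validated YAML configuration of the whole pipeline.

    Unknown keys are rejected so config typos fail loudly.
    """

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    acquisition: _AcqConfig = Field(default_factory=_AcqConfig)
    processing: _ProcConfig = Field(default_factory=_ProcConfig)
    bin_width: float = features.DEFAULT_BIN_WIDTH
    blind_regions: list[_RegionConfig] | None = None
    confidence: float = 0.95
    n_olive_train: int = 20
    chemistry_path: str | None = None
    composition_path: str | None = None

    def build_screen(self) -> OilScreen:
        regions = (features.default_blind_regions()
                   if self.blind_regions is None else
                   [BlindRegion(r.low, r.high, r.label)
                    for r in self.blind_regions])
        return OilScreen(
            acq=AcquisitionParams(**self.acquisition.model_dump()),
            proc=preprocess.ProcessingParams(**self.processing.model_dump()),
            bin_width=self.bin_width,
            regions=regions,
            confidence=self.confidence,
            chemistry=synth.load_chemistry(self.chemistry_path),
            composition_table=synth.load_composition_table(self.composition_path),
        )


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load and validate a pipeline YAML (or the defaults when None)."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)
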