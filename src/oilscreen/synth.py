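"""Forward model: fatty-acid composition -> peak list -> FID -> spectrum.

The simulator emulates 1D proton spectra of edible-oil triglycerides as
acquired on a 400 MHz instrument (400.13 MHz, 20 ppm sweep, 65,536
points).  An :class:`OilComposition` maps acyl-chain fractions onto a
table of functional-group resonances; the three signals that carry the
olive-vs-seed-oil contrast are

* the omega-3 terminal methyl triplet at 0.977 ppm (alpha-linolenic
  chains only),
* the terminal methyl triplet of all other chains at 0.881 ppm,
* the bis-allylic methylene signal at 2.78 ppm (2 protons per linoleic
  chain, 4 per linolenic chain).

Each multiplet is rendered as binomial-ratio Lorentzian components; the
FID is the exact sum of decaying complex exponentials plus additive
complex Gaussian noise and a per-sample global chemical-shift jitter.
Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml

from .spectra import FID, SpectrumValidationError

__all__ = [
    "OilComposition",
    "Peak",
    "AcquisitionParams",
    "load_composition_table",
    "load_chemistry",
    "make_oil",
    "mix_oils",
    "sample_cultivar",
    "composition_to_peaks",
    "simulate_fid",
    "render_spectrum",
    "rng_for",
]

_FRACTION_TOL = 1e-9

# Default time-domain noise level.  Chosen so that the processed-spectrum
# signal-to-noise ratio at the 0.881 ppm terminal-methyl peak of an
# olive-like oil is ~5e4:1, which keeps the ~140x weaker omega-3
# normalisation reference peak at a usable ~400:1 — the regime of a
# 64-scan neat-oil acquisition.  See docs/methods.md.
DEFAULT_NOISE_SIGMA = 7.4e-4

_MULTIPLET_RATIOS: dict[str, np.ndarray] = {
    "singlet": np.array([1.0]),
    "doublet": np.array([1.0, 1.0]),
    "triplet": np.array([1.0, 2.0, 1.0]),
    "quartet": np.array([1.0, 3.0, 3.0, 1.0]),
    # first-order stand-in for unresolved multiplets
    "multiplet": np.array([1.0, 4.0, 6.0, 4.0, 1.0]),
}


def rng_for(seed: int, label: str = "") -> np.random.Generator:
    """Deterministic per-label random substream.

    Derives an independent generator from a global seed and a stable
    CRC32 hash of ``label``, so per-sample reproducibility does not
    depend on the order samples are simulated in.
    """
    tag = zlib.crc32(label.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), tag]))


@dataclass(frozen=True)
class OilComposition:
    """Molar acyl-chain fractions of an oil or v/v blend.

    Fractions are nonnegative and sum to 1 (within 1e-9).  ``label``
    carries the oil name or, for blends, the mixing recipe.
    """

    fractions: Mapping[str, float]
    label: str = "custom"

    def __post_init__(self) -> None:
        fracs = {k: float(v) for k, v in self.fractions.items()}
        if not fracs:
            raise SpectrumValidationError("composition has no fatty acids")
        if any(v < 0 for v in fracs.values()):
            raise SpectrumValidationError("fatty-acid fractions must be nonnegative")
        total = sum(fracs.values())
        if abs(total - 1.0) > _FRACTION_TOL:
            raise SpectrumValidationError(
                f"fractions must sum to 1 (got {total:.12g}) for {self.label!r}"
            )
        object.__setattr__(self, "fractions", dict(fracs))

    def fraction(self, acid: str) -> float:
        return self.fractions.get(acid, 0.0)


@dataclass(frozen=True)
class Peak:
    """One resonance: a multiplet centred at ``center_ppm``.

    ``protons`` is the composition-weighted proton count per acyl chain;
    multiplet component amplitudes follow binomial ratios and sum to
    ``protons``.
    """

    center_ppm: float
    protons: float
    multiplicity: str = "singlet"
    j_hz: float = 0.0
    linewidth_hz: float = 1.2
    label: str = ""

    def __post_init__(self) -> None:
        if self.protons < 0:
            raise SpectrumValidationError("peak proton weight must be >= 0")
        if self.linewidth_hz <= 0:
            raise SpectrumValidationError("linewidth must be positive")
        if self.multiplicity not in _MULTIPLET_RATIOS:
            raise SpectrumValidationError(
                f"unknown multiplicity {self.multiplicity!r}"
            )

    def components(self) -> list[tuple[float, float]]:
        """(offset_hz, amplitude) per line; amplitudes sum to protons."""
        ratios = _MULTIPLET_RATIOS[self.multiplicity]
        amps = ratios / ratios.sum() * self.protons
        m = ratios.size
        offsets = (np.arange(m) - (m - 1) / 2.0) * self.j_hz
        return list(zip(offsets.tolist(), amps.tolist()))


@dataclass(frozen=True)
class AcquisitionParams:
    """Acquisition and noise settings of the simulated experiment.

    Defaults follow the emulated instrument: 400.13 MHz, 20 ppm sweep,
    65,536 points, spectral window -3.9 ... 16.1 ppm.
    """

    spectrometer_freq: float = 400.13
    sweep_ppm: float = 20.0
    n_points: int = 65536
    axis_low_ppm: float = -3.9
    axis_high_ppm: float = 16.1
    noise_sigma: float = DEFAULT_NOISE_SIGMA
    shift_jitter_sigma: float = 0.002
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_points < 2 or self.n_points & (self.n_points - 1):
            raise SpectrumValidationError("n_points must be a power of two")
        if abs((self.axis_high_ppm - self.axis_low_ppm) - self.sweep_ppm) > 1e-9:
            raise SpectrumValidationError(
                "axis bounds inconsistent with sweep width"
            )
        if self.noise_sigma < 0 or self.shift_jitter_sigma < 0:
            raise SpectrumValidationError("noise/jitter sigmas must be >= 0")

    @property
    def ppm_offset(self) -> float:
        return 0.5 * (self.axis_low_ppm + self.axis_high_ppm)

    @property
    def sweep_hz(self) -> float:
        return self.sweep_ppm * self.spectrometer_freq

    @property
    def dwell_time(self) -> float:
        return 1.0 / self.sweep_hz


# ---------------------------------------------------------------------------
# configuration tables
# ---------------------------------------------------------------------------

def _load_packaged_yaml(name: str) -> dict:
    with resources.files("oilscreen.data").joinpath(name).open("r") as fh:
        return yaml.safe_load(fh)


def load_composition_table(path: str | None = None) -> dict:
    """Built-in oil composition table (or a user YAML of the same shape)."""
    if path is None:
        return _load_packaged_yaml("compositions.yaml")
    with open(path) as fh:
        return yaml.safe_load(fh)


def load_chemistry(path: str | None = None) -> dict:
    """Peak-assignment chemistry config (groups, protons, extra lines)."""
    if path is None:
        return _load_packaged_yaml("chemistry.yaml")
    with open(path) as fh:
        return yaml.safe_load(fh)


def make_oil(label: str | None = None,
             fractions: Mapping[str, float] | None = None,
             table: dict | None = None) -> OilComposition:
    """Build an :class:`OilComposition` from the built-in table or fractions.

    Exactly one of ``label``-only (table lookup) or ``fractions`` must
    identify the oil; with both given, ``fractions`` wins and ``label``
    names the result.
    """
    if fractions is not None:
        return OilComposition(fractions=fractions, label=label or "custom")
    if label is None:
        raise ValueError("make_oil needs a label or explicit fractions")
    table = table if table is not None else load_composition_table()
    oils = table["oils"]
    if label not in oils:
        known = ", ".join(sorted(oils))
        raise KeyError(f"unknown oil {label!r}; built-ins: {known}")
    return OilComposition(fractions=oils[label], label=label)


def mix_oils(components: Sequence[tuple[OilComposition, float]]) -> OilComposition:
    """Volume-fraction-weighted blend of compositions.

    Volume fractions must sum to 1.  Equal molar volumes are assumed
    across oils, so v/v fractions act directly as chain-fraction
    weights; triglyceride molar volumes differ by only a few percent,
    making this a documented approximation rather than a measured one.
    """
    if not components:
        raise ValueError("mix_oils needs at least one component")
    weights = [float(w) for _, w in components]
    if any(w < 0 for w in weights):
        raise SpectrumValidationError("v/v fractions must be nonnegative")
    if abs(sum(weights) - 1.0) > _FRACTION_TOL:
        raise SpectrumValidationError(
            f"v/v fractions must sum to 1 (got {sum(weights):.12g})"
        )
    mixed: dict[str, float] = {}
    for oil, w in components:
        for acid, f in oil.fractions.items():
            mixed[acid] = mixed.get(acid, 0.0) + w * f
    # renormalise away float rounding so the invariant holds exactly
    total = sum(mixed.values())
    mixed = {k: v / total for k, v in mixed.items()}
    recipe = "+".join(f"{w:g}*{oil.label}" for oil, w in components)
    return OilComposition(fractions=mixed, label=f"mix({recipe})")


OMEGA3_ACIDS = frozenset({"linolenic"})


def sample_cultivar(base: OilComposition,
                    rng: np.random.Generator,
                    rel_sd: Mapping[str, float] | float | None = None,
                    label: str | None = None) -> OilComposition:
    """Draw one bottle from the panel distribution around ``base``.

    Each chain fraction receives independent multiplicative Gaussian
    jitter with the per-acid relative standard deviations from the
    composition table (``cultivar_rel_sd``).  The omega-3 block
    (alpha-linolenic) is jittered around its base share of the whole,
    and the remaining acids are rescaled to fill the rest: the model of
    an authentic class is one whose omega-3 share is tightly regulated
    while the internal balance of the other chains (chiefly the
    oleic/linoleic axis) varies freely between cultivars.  Pass a float
    for a uniform relative sd.
    """
    if rel_sd is None:
        rel_sd = load_composition_table()["cultivar_rel_sd"]

    def sd_of(acid: str) -> float:
        return float(rel_sd) if isinstance(rel_sd, (int, float)) \
            else float(rel_sd.get(acid, 0.0))

    jittered = {
        acid: f * max(rng.normal(1.0, sd_of(acid)), 1e-6)
        for acid, f in base.fractions.items()
    }
    omega3 = {a: v for a, v in jittered.items() if a in OMEGA3_ACIDS}
    others = {a: v for a, v in jittered.items() if a not in OMEGA3_ACIDS}
    omega3_total = sum(omega3.values())
    others_total = sum(others.values())
    if omega3 and others and omega3_total < 1.0 and others_total > 0:
        rescale = (1.0 - omega3_total) / others_total
        fracs = {**omega3, **{a: v * rescale for a, v in others.items()}}
    else:
        total = omega3_total + others_total
        fracs = {a: v / total for a, v in jittered.items()}
    total = sum(fracs.values())
    fracs = {k: v / total for k, v in fracs.items()}
    return OilComposition(fractions=fracs, label=label or f"{base.label}~cv")


# ---------------------------------------------------------------------------
# composition -> peaks
# ---------------------------------------------------------------------------

def composition_to_peaks(oil: OilComposition,
                         chemistry: dict | None = None) -> list[Peak]:
    """Expand a composition into the multiplet peak list of its spectrum.

    Per-group proton weight is the composition-weighted sum of the
    per-chain proton counts in the chemistry table; groups with zero
    weight are kept (at zero amplitude) so peak identity is stable
    across compositions.  Composition-independent extra lines (residual
    solvent, TMS) are appended as configured.
    """
    chemistry = chemistry if chemistry is not None else load_chemistry()
    groups = chemistry["groups"]
    protons = chemistry["protons"]
    lw = float(chemistry.get("linewidth_hz", 1.2))
    missing = [a for a in oil.fractions if a not in protons]
    if missing:
        raise KeyError(
            f"fatty acids missing from chemistry config: {', '.join(missing)}"
        )
    peaks = []
    for gname, g in groups.items():
        weight = sum(
            frac * protons[acid].get(gname, 0.0)
            for acid, frac in oil.fractions.items()
        )
        peaks.append(Peak(
            center_ppm=float(g["center_ppm"]),
            protons=weight,
            multiplicity=g.get("multiplicity", "singlet"),
            j_hz=float(g.get("j_hz", 0.0)),
            linewidth_hz=float(g.get("linewidth_hz", lw)),
            label=gname,
        ))
    for line in chemistry.get("extra_lines", []):
        peaks.append(Peak(
            center_ppm=float(line["center_ppm"]),
            protons=float(line["amplitude"]),
            multiplicity=line.get("multiplicity", "singlet"),
            j_hz=float(line.get("j_hz", 0.0)),
            linewidth_hz=float(line.get("linewidth_hz", lw)),
            label=line.get("label", "extra"),
        ))
    return peaks


# ---------------------------------------------------------------------------
# peaks -> FID
# ---------------------------------------------------------------------------

def _sum_decaying_exponentials(z: np.ndarray, amps: np.ndarray,
                               n: int, dt: float) -> np.ndarray:
    """Sum_c amps_c * exp(z_c * k * dt) for k = 0..n-1.

    Exact block-power factorisation: with k = j*m + i,
    exp(z*t_k) = exp(z*t_i) * exp(z*t_{j*m}), so the full signal is a
    small (m x C) @ (C x n/m) matrix product instead of n*C
    transcendental evaluations.  Identical to the naive sum to float
    rounding.
    """
    m = 1 << ((n - 1).bit_length() // 2)  # ~sqrt(n), divides power-of-two n
    n_blocks = -(-n // m)
    inner = np.exp(np.multiply.outer(np.arange(m) * dt, z))          # (m, C)
    outer = np.exp(np.multiply.outer(z, np.arange(n_blocks) * (m * dt)))  # (C, B)
    sig = (inner * amps) @ outer        # (m, B)
    return sig.reshape(-1, order="F")[:n]


def simulate_fid(peaks: Sequence[Peak],
                 acq: AcquisitionParams,
                 rng: np.random.Generator | None = None) -> FID:
    """Render a peak list into a noisy complex FID.

    The signal is the exact sum over multiplet components of
    ``A * exp(i*2*pi*f*t - t/T2)`` sampled at the dwell time, where
    ``T2 = 1/(pi*linewidth)`` and ``f`` is the offset of the (jittered)
    component from the carrier at the window centre.  Additive complex
    Gaussian noise of ``acq.noise_sigma`` per quadrature completes the
    model.  One global shift jitter draw per FID moves all centres
    together, emulating shim/temperature drift between samples.
    """
    if rng is None:
        rng = np.random.default_rng(acq.seed)
    jitter = rng.normal(0.0, acq.shift_jitter_sigma) if acq.shift_jitter_sigma else 0.0

    freqs: list[float] = []
    decays: list[float] = []
    amps: list[float] = []
    for peak in peaks:
        center = peak.center_ppm + jitter
        if not (acq.axis_low_ppm <= center <= acq.axis_high_ppm):
            raise SpectrumValidationError(
                f"peak {peak.label or peak.center_ppm} at {center:.3f} ppm "
                f"falls outside the {acq.axis_low_ppm}..{acq.axis_high_ppm} ppm window"
            )
        if peak.protons == 0.0:
            continue
        t2 = 1.0 / (math.pi * peak.linewidth_hz)
        base_hz = (center - acq.ppm_offset) * acq.spectrometer_freq
        for off_hz, amp in peak.components():
            freqs.append(base_hz + off_hz)
            decays.append(1.0 / t2)
            amps.append(amp)

    if freqs:
        z = 2j * np.pi * np.asarray(freqs) - np.asarray(decays)  # (ncomp,)
        sig = _sum_decaying_exponentials(
            z, np.asarray(amps, dtype=float), acq.n_points, acq.dwell_time)
    else:
        sig = np.zeros(acq.n_points, dtype=complex)
    if acq.noise_sigma > 0:
        noise = rng.normal(0.0, acq.noise_sigma, size=(2, acq.n_points))
        sig = sig + noise[0] + 1j * noise[1]

    return FID(
        points=sig,
        dwell_time=acq.dwell_time,
        spectrometer_freq=acq.spectrometer_freq,
        ppm_offset=acq.ppm_offset,
        meta={"history": [
            f"simulated: {len(freqs)} components, noise_sigma={acq.noise_sigma}, "
            f"shift_jitter={jitter:.6g} ppm"
        ]},
    )


def render_spectrum(oil: OilComposition,
                    acq: AcquisitionParams | None = None,
                    chemistry: dict | None = None,
                    params=None,
                    rng: np.random.Generator | None = None):
    """Composition -> fully processed spectrum (default processing chain).

    Convenience composition of :func:`composition_to_peaks`,
    :func:`simulate_fid` and :func:`oilscreen.preprocess.process`.
    ``params`` defaults to the standard chain (0.3 Hz apodization,
    automatic phasing, order-5 baseline, omega-3 peak normalisation).
    """
    from . import preprocess  # local import: preprocess depends only on spectra

    acq = acq or AcquisitionParams()
    peaks = composition_to_peaks(oil, chemistry)
    fid = simulate_fid(peaks, acq, rng=rng)
    params = params or preprocess.ProcessingParams()
    spec = preprocess.process(fid, params)
    spec.meta["oil"] = oil.label
    return spec
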