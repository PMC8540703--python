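"""Multichannel and single-channel EEG band-power ratio indices.

The multichannel index family maps a per-epoch feature table to a scalar
per epoch:

    I(e) = sum_ij C_ij F_ij(e) / sum_ij K_ij F_ij(e)

where i runs over the 8 bands, j over the 6 channels, and C, K are
non-negative coefficient matrices (48 numerator + 48 denominator
coefficients).  Two published instances are provided: Index1 (13 non-zero
real coefficients over alpha/alpha1/alpha2 vs delta) and Index2 (five 0/1
addends: frontal+occipital delta over central alpha + occipital high alpha).

Also here: the seven classic single-channel ratio indices (theta/alpha,
beta/alpha, (theta+alpha)/beta, theta/beta, (theta+alpha)/(alpha+beta),
gamma/delta, (gamma+beta)/(delta+alpha)), the 10 % adjacent-epoch clamp,
per-subject min-max normalization, and the discrete-wavelet band energies
used by the two gamma-based baselines.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt

from .band_features import BAND_NAMES, CHANNELS, FeatureTable

__all__ = [
    "IndexSpec",
    "SingleChannelIndexDef",
    "SINGLE_CHANNEL_BANK",
    "IndexSeries",
    "eval_multichannel_index",
    "index1_spec",
    "index2_spec",
    "clamp_series",
    "normalize_unit_interval",
    "eval_single_channel_indices",
    "wavelet_band_energies",
    "dwt_subband_energies",
    "wavelet_feature_table",
]

#: Relative clamp band: adjacent epochs may change by at most 10 %.
CLAMP_FRACTION = 0.1


@dataclass
class IndexSpec:
    """Coefficients of one multichannel ratio index.

    ``C`` and ``K`` are (bands x channels) = (8 x 6) non-negative matrices;
    rows follow :data:`~drowsyindex.band_features.BAND_NAMES`, columns
    :data:`~drowsyindex.band_features.CHANNELS`.
    """

    C: np.ndarray
    K: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        self.K = np.asarray(self.K, dtype=float)
        shape = (len(BAND_NAMES), len(CHANNELS))
        if self.C.shape != shape or self.K.shape != shape:
            raise ValueError(f"C and K must have shape {shape}")
        if np.any(self.C < 0) or np.any(self.K < 0):
            raise ValueError("coefficients must be non-negative")
        if not np.any(self.K > 0):
            raise ValueError("denominator needs at least one positive K")

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.C) + np.count_nonzero(self.K))

    def to_json(self) -> str:
        """Band/channel-keyed JSON; round-trips exactly via repr floats."""
        def keyed(m: np.ndarray) -> dict:
            return {
                b: {ch: m[i, j] for j, ch in enumerate(CHANNELS) if m[i, j] != 0}
                for i, b in enumerate(BAND_NAMES) if np.any(m[i] != 0)
            }
        return json.dumps({"name": self.name, "C": keyed(self.C),
                           "K": keyed(self.K)}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "IndexSpec":
        d = json.loads(text)
        C = np.zeros((len(BAND_NAMES), len(CHANNELS)))
        K = np.zeros_like(C)
        for m, key in ((C, "C"), (K, "K")):
            for b, chans in d.get(key, {}).items():
                for ch, v in chans.items():
                    m[BAND_NAMES.index(b), CHANNELS.index(ch)] = v
        return cls(C=C, K=K, name=d.get("name", ""))


@dataclass
class SingleChannelIndexDef:
    """A single-channel ratio: sum of numerator bands over denominator bands."""

    name: str
    numerator_bands: tuple[str, ...]
    denominator_bands: tuple[str, ...]
    #: True for the two indices historically computed from wavelet sub-band
    #: energies rather than Welch powers.
    wavelet_based: bool = False


#: The seven published single-channel baselines.
SINGLE_CHANNEL_BANK: tuple[SingleChannelIndexDef, ...] = (
    SingleChannelIndexDef("theta/alpha", ("theta",), ("alpha",)),
    SingleChannelIndexDef("beta/alpha", ("beta",), ("alpha",)),
    SingleChannelIndexDef("(theta+alpha)/beta", ("theta", "alpha"), ("beta",)),
    SingleChannelIndexDef("theta/beta", ("theta",), ("beta",)),
    SingleChannelIndexDef(
        "(theta+alpha)/(alpha+beta)", ("theta", "alpha"), ("alpha", "beta")
    ),
    SingleChannelIndexDef("gamma/delta", ("gamma",), ("delta",),
                          wavelet_based=True),
    SingleChannelIndexDef("(gamma+beta)/(delta+alpha)", ("gamma", "beta"),
                          ("delta", "alpha"), wavelet_based=True),
)


@dataclass
class IndexSeries:
    """Per-epoch index values with stage labels and processing variant."""

    values: np.ndarray
    stage_labels: np.ndarray
    variant: str = "raw"  # raw | clamped | normalized
    spec_name: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.stage_labels = np.asarray(self.stage_labels)
        if self.values.ndim != 1:
            raise ValueError("index series must be one-dimensional")
        if len(self.stage_labels) != len(self.values):
            raise ValueError("one stage label per epoch required")

    def __len__(self) -> int:
        return len(self.values)

    def stage_values(self, stage: str) -> np.ndarray:
        return self.values[self.stage_labels == stage]

    def to_csv(self, path, epoch_step_s: float = 2.5) -> None:
        import pandas as pd

        pd.DataFrame({
            "epoch_index": np.arange(len(self)),
            "start_s": np.arange(len(self)) * epoch_step_s,
            "stage": self.stage_labels,
            "value": self.values,
        }).to_csv(path, index=False)


def _apply_ratio(num: np.ndarray, den: np.ndarray,
                 zero_denominator: str) -> np.ndarray:
    """Divide with the configured degenerate-denominator policy."""
    bad = den <= 0
    if np.any(bad):
        if zero_denominator == "error":
            raise ZeroDivisionError(
                f"denominator <= 0 for {int(bad.sum())} epoch(s)"
            )
        floor = 1e-12 * max(float(np.median(den[~bad])) if np.any(~bad) else 1.0,
                            1.0)
        warnings.warn(
            f"denominator <= 0 for {int(bad.sum())} epoch(s); "
            f"floored at {floor:g}"
        )
        den = np.where(bad, floor, den)
    return num / den


def eval_multichannel_index(
    features: FeatureTable,
    spec: IndexSpec,
    zero_denominator: str = "epsilon",
) -> IndexSeries:
    """Evaluate the coefficient-weighted band-power ratio per epoch.

    ``zero_denominator``: ``"epsilon"`` floors a non-positive denominator at
    a tiny fraction of the median denominator (degenerate all-zero epochs
    only, since band powers are non-negative); ``"error"`` raises.
    """
    if features.band_names != BAND_NAMES or features.channel_names != CHANNELS:
        raise ValueError("feature table ordering does not match the spec layout")
    # values: (epochs, channels, bands); C/K: (bands, channels)
    num = np.einsum("ecb,bc->e", features.values, spec.C)
    den = np.einsum("ecb,bc->e", features.values, spec.K)
    vals = _apply_ratio(num, den, zero_denominator)
    return IndexSeries(vals, features.stage_labels, variant="raw",
                       spec_name=spec.name, subject_id=features.subject_id)


def _spec_from_terms(name, num_terms, den_terms) -> IndexSpec:
    C = np.zeros((len(BAND_NAMES), len(CHANNELS)))
    K = np.zeros_like(C)
    for m, terms in ((C, num_terms), (K, den_terms)):
        for band, channel, coeff in terms:
            m[BAND_NAMES.index(band), CHANNELS.index(channel)] = coeff
    return IndexSpec(C=C, K=K, name=name)


def index1_spec() -> IndexSpec:
    """The first published multichannel index (13 non-zero coefficients).

    Numerator: alpha F3 + 4 alpha O2 + 9 alpha1 F3 + 3 alpha1 C3
    + 9 alpha1 C4 + alpha1 O2 + 4 alpha2 O1 + 8 alpha2 O2.
    Denominator: delta F3 + 3 delta F4 + 3 delta C3 + 2 delta C4 + 9 delta O2.
    """
    return _spec_from_terms(
        "Index1",
        [("alpha", "F3", 1), ("alpha", "O2", 4),
         ("alpha1", "F3", 9), ("alpha1", "C3", 3), ("alpha1", "C4", 9),
         ("alpha1", "O2", 1), ("alpha2", "O1", 4), ("alpha2", "O2", 8)],
        [("delta", "F3", 1), ("delta", "F4", 3), ("delta", "C3", 3),
         ("delta", "C4", 2), ("delta", "O2", 9)],
    )


def index2_spec() -> IndexSpec:
    """The second published index: (delta F3 + delta F4 + delta O2) /
    (alpha C3 + alpha2 O2) — five 0/1 addends from a brute-force search."""
    return _spec_from_terms(
        "Index2",
        [("delta", "F3", 1), ("delta", "F4", 1), ("delta", "O2", 1)],
        [("alpha", "C3", 1), ("alpha2", "O2", 1)],
    )


def clamp_values(values: np.ndarray, fraction: float = CLAMP_FRACTION,
                 reference: str = "clamped") -> np.ndarray:
    """Limit adjacent-epoch relative change to ``fraction`` (default 10 %).

    Sequential left-to-right pass; by default each raw value is compared
    against the previous *clamped* output, so a single spike cannot leak
    through rescaled.  ``reference="raw"`` compares against the raw previous
    value instead (the literal reading of the published recurrence).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot clamp an empty series")
    if reference not in ("clamped", "raw"):
        raise ValueError("reference must be 'clamped' or 'raw'")
    out = values.copy()
    hi, lo = 1.0 + fraction, 1.0 - fraction
    for e in range(1, len(values)):
        prev = out[e - 1] if reference == "clamped" else values[e - 1]
        if values[e] > hi * prev:
            out[e] = hi * prev
        elif values[e] < lo * prev:
            out[e] = lo * prev
        else:
            out[e] = values[e]
    return out


def clamp_series(series: IndexSeries, fraction: float = CLAMP_FRACTION,
                 reference: str = "clamped") -> IndexSeries:
    out = clamp_values(series.values, fraction, reference)
    return IndexSeries(out, series.stage_labels, variant="clamped",
                       spec_name=series.spec_name, subject_id=series.subject_id)


def normalize_unit_interval(series: IndexSeries) -> IndexSeries:
    """Per-subject min-max scaling to [0, 1] (removes inter-subject scale)."""
    v = series.values
    lo, hi = float(np.min(v)), float(np.max(v))
    if hi == lo:
        warnings.warn("constant index series; normalized to all 0.5")
        out = np.full_like(v, 0.5)
    else:
        out = (v - lo) / (hi - lo)
    return IndexSeries(out, series.stage_labels, variant="normalized",
                       spec_name=series.spec_name, subject_id=series.subject_id)


def eval_single_channel_indices(
    features: FeatureTable,
    bank: tuple[SingleChannelIndexDef, ...] = SINGLE_CHANNEL_BANK,
    wavelet_features: FeatureTable | None = None,
    zero_denominator: str = "epsilon",
) -> dict[tuple[str, str], IndexSeries]:
    """Evaluate every baseline on every channel: 7 x 6 = 42 series.

    The two gamma-based indices use ``wavelet_features`` (DWT sub-band
    energies, see :func:`wavelet_feature_table`) when provided, matching
    their original wavelet formulation; otherwise they fall back to the
    Welch powers.
    """
    out: dict[tuple[str, str], IndexSeries] = {}
    for idx in bank:
        table = features
        if idx.wavelet_based and wavelet_features is not None:
            table = wavelet_features
        num = sum(table.band(b) for b in idx.numerator_bands)
        den = sum(table.band(b) for b in idx.denominator_bands)
        for j, ch in enumerate(CHANNELS):
            vals = _apply_ratio(num[:, j], den[:, j], zero_denominator)
            out[(idx.name, ch)] = IndexSeries(
                vals, table.stage_labels, variant="raw",
                spec_name=f"{idx.name}@{ch}", subject_id=table.subject_id,
            )
    return out


#: DWT sub-band -> rhythm mapping for a 5-level Daubechies-4 decomposition
#: at 200 Hz.  Approximate dyadic edges: A5 0-3.1 Hz (delta), D5 3.1-6.25
#: (theta), D4 6.25-12.5 (alpha), D3 12.5-25 (beta), D2 25-50 (gamma).
#: A documented approximation of the original wavelet formulation, not a
#: reconstruction of it.
WAVELET_LEVELS = 5
WAVELET_NAME = "db4"
_WAVELET_MAP = {"delta": 0, "theta": 1, "alpha": 2, "beta": 3, "gamma": 4}


def dwt_subband_energies(epoch_signal: np.ndarray) -> list[float]:
    """Energies of all DWT sub-bands [A5, D5, D4, D3, D2, D1].

    With the periodized orthogonal Daubechies-4 transform these sum
    exactly to the signal energy (Parseval).
    """
    x = np.asarray(epoch_signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("epoch_signal must be one-dimensional")
    if x.size < 2 ** WAVELET_LEVELS:
        raise ValueError(
            f"epoch too short for a {WAVELET_LEVELS}-level decomposition"
        )
    block = 2 ** WAVELET_LEVELS
    if x.size % block:  # zero-pad so periodization stays orthogonal
        x = np.concatenate([x, np.zeros(block - x.size % block)])
    coeffs = pywt.wavedec(x, WAVELET_NAME, level=WAVELET_LEVELS,
                          mode="periodization")
    return [float(np.sum(c ** 2)) for c in coeffs]


def wavelet_band_energies(epoch_signal: np.ndarray, fs: float = 200.0,
                          ) -> dict[str, float]:
    """Rhythm-band energies from an orthogonal multilevel DWT.

    Maps the A5/D5/D4/D3/D2 sub-bands to delta/theta/alpha/beta/gamma;
    the residual D1 band (above 50 Hz) carries no named rhythm and is
    dropped here (see :func:`dwt_subband_energies` for the full set).
    """
    energies = dwt_subband_energies(epoch_signal)
    return {band: energies[i] for band, i in _WAVELET_MAP.items()}


def wavelet_band_names() -> tuple[str, ...]:
    return tuple(_WAVELET_MAP)


def wavelet_feature_table(fragment, grid) -> FeatureTable:
    """DWT band energies per epoch/channel, shaped like a FeatureTable.

    Only delta/theta/alpha/beta/gamma carry wavelet energies; the three
    remaining band columns are zero-filled so the table shares the standard
    layout.
    """
    n_per_epoch = int(round(grid.epoch_length * fragment.fs))
    values = np.zeros((grid.n_epochs, len(CHANNELS), len(BAND_NAMES)))
    for e, (_, start) in enumerate(grid.epoch_starts):
        i0 = int(round(start * fragment.fs))
        seg = fragment.samples[:, i0:i0 + n_per_epoch]
        for c in range(len(CHANNELS)):
            en = wavelet_band_energies(seg[c], fragment.fs)
            for band, val in en.items():
                values[e, c, BAND_NAMES.index(band)] = val
    return FeatureTable(values=values, stage_labels=grid.stage_labels,
                        subject_id=fragment.subject_id)
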