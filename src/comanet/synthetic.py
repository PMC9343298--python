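"""Synthetic multimodal pseudo-MRI cohort with known ground truth.

Emulates the study cohort the classifier is built for: 29 comatose
patients and 34 controls, each with six whole-brain index volumes
(GM, T1, FA, MD, and two resting-state seed maps, rsPCC / rsPreCun) on a
common template grid.  Every subject is a smooth low-frequency random
field (shared generator for both classes) inside an ellipsoidal brain
mask, plus white Gaussian noise; patients additionally receive a mean
shift inside an index-specific ellipsoidal ROI.  The shift is
``effect_size * noise_sd`` (a Cohen's-d-like magnitude) and is
attenuated for patients with a favorable 3-month outcome, so those
patients resemble controls — the structure the outcome audit probes.

Randomness is split per (subject, index) through counter-based
seed-sequence keys, so generation is reproducible and independent of
generation order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

from .exceptions import ConfigurationError
from .volume_io import write_volume

INDEX_NAMES = ("GM", "T1", "FA", "MD", "rsPCC", "rsPreCun")

#: fractional ROI centers per index, chosen disjoint and index-specific:
#: deep/central for FA, anterior for MD, posterior-medial for the two
#: resting-state seed maps, superior-lateral for GM and T1.
_ROI_CENTERS = {
    "GM": (0.30, 0.42, 0.62),
    "T1": (0.70, 0.42, 0.62),
    "FA": (0.50, 0.46, 0.30),
    "MD": (0.50, 0.24, 0.52),
    "rsPCC": (0.50, 0.72, 0.40),
    "rsPreCun": (0.50, 0.74, 0.66),
}
_ROI_SEMIAXES = (0.13, 0.13, 0.13)  # fractions of the grid (diffuse footprint)
_MASK_SEMIAXES = (0.42, 0.46, 0.42)
FWHM_TO_SIGMA = 1.0 / 2.3548200450309493  # fwhm = sigma * 2 sqrt(2 ln 2)


@dataclass
class SyntheticConfig:
    """Cohort-level generation parameters; defaults are the study conditions."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    n_controls: int = 34
    n_patients: int = 29
    index_names: tuple[str, ...] = INDEX_NAMES
    effect_size_per_index: dict[str, float] = field(
        default_factory=lambda: {name: 3.0 for name in INDEX_NAMES})
    effect_roi_per_index: dict[str, tuple] = field(default_factory=dict)
    smoothing_fwhm: float = 6.0
    texture_sd: float = 0.5
    noise_sd: float = 1.0
    fraction_favorable_outcome: float = 0.5
    effect_attenuation_for_favorable: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid_shape)
        if not self.effect_roi_per_index:
            self.effect_roi_per_index = {
                name: (tuple(np.round(np.asarray(_ROI_CENTERS[name]) * grid).astype(int)),
                       tuple(np.maximum(np.round(np.asarray(_ROI_SEMIAXES) * grid), 2)
                             .astype(int)))
                for name in self.index_names if name in _ROI_CENTERS}
        missing = [n for n in self.index_names if n not in self.effect_roi_per_index]
        if missing:
            raise ConfigurationError(f"no effect ROI for indices {missing}")
        if not 0.0 <= self.fraction_favorable_outcome <= 1.0:
            raise ConfigurationError("fraction_favorable_outcome must be in [0, 1]")
        if not 0.0 <= self.effect_attenuation_for_favorable <= 1.0:
            raise ConfigurationError("effect_attenuation_for_favorable must be in [0, 1]")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["index_names"] = list(self.index_names)
        d["effect_roi_per_index"] = {
            k: {"center": list(map(int, c)), "semiaxes": list(map(int, s))}
            for k, (c, s) in self.effect_roi_per_index.items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["grid_shape"] = tuple(d["grid_shape"])
        d["index_names"] = tuple(d["index_names"])
        d["effect_roi_per_index"] = {
            k: (tuple(v["center"]), tuple(v["semiaxes"]))
            for k, v in d.get("effect_roi_per_index", {}).items()}
        return cls(**d)


@dataclass
class GroundTruth:
    """What was injected: masks, class/outcome labels, applied magnitudes."""

    brain_mask: np.ndarray
    roi_masks: dict[str, np.ndarray]
    table: pd.DataFrame  # subject_id, class, outcome, attenuation

    def effect_magnitude(self, subject_id: str, index_name: str,
                         config: SyntheticConfig) -> float:
        row = self.table.set_index("subject_id").loc[subject_id]
        if row["class"] != "coma":
            return 0.0
        base = config.effect_size_per_index[index_name] * config.noise_sd
        return float(base * row["attenuation"])


def _ellipsoid(grid_shape, center, semiaxes) -> np.ndarray:
    coords = np.indices(grid_shape, dtype=np.float32)
    r2 = sum(((coords[i] - center[i]) / semiaxes[i]) ** 2 for i in range(3))
    return r2 <= 1.0


def make_brain_mask(grid_shape: tuple[int, int, int], seed: int = 0) -> np.ndarray:
    """Connected ellipsoidal head mask, 30-60% of the grid, seed-jittered axes."""
    if any(d < 8 for d in grid_shape):
        raise ConfigurationError(f"grid {grid_shape} too small for a brain mask "
                                 "(every dimension must be >= 8)")
    rng = np.random.default_rng(seed)
    jitter = 1.0 + 0.02 * rng.uniform(-1, 1, size=3)
    center = [(d - 1) / 2 for d in grid_shape]
    semi = [a * d * j for a, d, j in zip(_MASK_SEMIAXES, grid_shape, jitter)]
    return _ellipsoid(grid_shape, center, semi)


def roi_mask(config: SyntheticConfig, index_name: str) -> np.ndarray:
    center, semi = config.effect_roi_per_index[index_name]
    return _ellipsoid(config.grid_shape, center, semi)


def _subject_rng(seed: int, subject_idx: int, index_idx: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(subject_idx, index_idx)))


def synthesize_subject(config: SyntheticConfig, class_label: str, outcome_label,
                       index_name: str, rng: np.random.Generator,
                       brain_mask: np.ndarray | None = None) -> np.ndarray:
    """One subject's volume for one index; reproducible from ``rng``.

    texture (smoothed unit-SD random field) + attenuated class effect
    inside the index ROI + white noise, zeroed outside the brain mask.
    """
    if index_name not in config.index_names:
        raise KeyError(f"unknown MR index {index_name!r}")
    if brain_mask is None:
        brain_mask = make_brain_mask(config.grid_shape, config.seed)
    sigma = config.smoothing_fwhm * FWHM_TO_SIGMA
    texture = gaussian_filter(rng.standard_normal(config.grid_shape), sigma)
    texture *= config.texture_sd / max(texture.std(), 1e-12)
    vol = texture.astype(np.float32)
    if class_label == "coma":
        atten = (config.effect_attenuation_for_favorable
                 if outcome_label == "favorable" else 1.0)
        magnitude = config.effect_size_per_index[index_name] * config.noise_sd * atten
        if magnitude != 0.0:
            vol = vol + magnitude * roi_mask(config, index_name).astype(np.float32)
    vol = vol + rng.normal(0.0, config.noise_sd, size=config.grid_shape).astype(np.float32)
    vol *= brain_mask
    return vol.astype(np.float32)


def cohort_table(config: SyntheticConfig) -> pd.DataFrame:
    """Subject ids, classes and outcome labels (deterministic from the seed)."""
    ids = ([f"control-{i + 1:02d}" for i in range(config.n_controls)]
           + [f"patient-{i + 1:02d}" for i in range(config.n_patients)])
    classes = ["control"] * config.n_controls + ["coma"] * config.n_patients
    n_fav = int(round(config.fraction_favorable_outcome * config.n_patients))
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed,
                                                       spawn_key=(2 ** 16,)))
    fav_idx = set(rng.permutation(config.n_patients)[:n_fav])
    outcomes = [None] * config.n_controls + [
        "favorable" if i in fav_idx else "unfavorable"
        for i in range(config.n_patients)]
    return pd.DataFrame({"subject_id": ids, "class": classes, "outcome": outcomes})


def synthesize_cohort_arrays(config: SyntheticConfig):
    """In-memory cohort: (table, GroundTruth, {index: (n, *grid) array})."""
    table = cohort_table(config)
    mask = make_brain_mask(config.grid_shape, config.seed)
    volumes = {name: np.empty((len(table), *config.grid_shape), dtype=np.float32)
               for name in config.index_names}
    for si, row in table.iterrows():
        for ii, name in enumerate(config.index_names):
            rng = _subject_rng(config.seed, si, ii)
            volumes[name][si] = synthesize_subject(
                config, row["class"], row["outcome"], name, rng, brain_mask=mask)
    gt_table = table.copy()
    gt_table["attenuation"] = [
        (config.effect_attenuation_for_favorable if o == "favorable" else 1.0)
        if c == "coma" else 0.0
        for c, o in zip(table["class"], table["outcome"])]
    truth = GroundTruth(brain_mask=mask,
                        roi_masks={n: roi_mask(config, n) for n in config.index_names},
                        table=gt_table)
    return table, truth, volumes


def synthesize_cohort(config: SyntheticConfig, out_dir: str | Path):
    """Write the cohort to ``out_dir`` as NIfTI volumes + CSV manifest + YAML config.

    Returns ``(manifest, GroundTruth)``; the manifest has one row per
    (subject, index) with the volume path.
    """
    out_dir = Path(out_dir)
    vol_dir = out_dir / "volumes"
    vol_dir.mkdir(parents=True, exist_ok=True)
    table = cohort_table(config)
    mask = make_brain_mask(config.grid_shape, config.seed)
    rows = []
    for si, row in table.iterrows():
        for ii, name in enumerate(config.index_names):
            rng = _subject_rng(config.seed, si, ii)
            vol = synthesize_subject(config, row["class"], row["outcome"], name,
                                     rng, brain_mask=mask)
            path = vol_dir / f"{row['subject_id']}_{name}.nii"
            write_volume(vol, path)
            rows.append({"subject_id": row["subject_id"], "class": row["class"],
                         "outcome": row["outcome"], "index": name,
                         "path": str(path.relative_to(out_dir))})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    config.to_yaml(out_dir / "config.yaml")
    gt_table = table.copy()
    gt_table["attenuation"] = [
        (config.effect_attenuation_for_favorable if o == "favorable" else 1.0)
        if c == "coma" else 0.0
        for c, o in zip(table["class"], table["outcome"])]
    truth = GroundTruth(brain_mask=mask,
                        roi_masks={n: roi_mask(config, n) for n in config.index_names},
                        table=gt_table)
    write_volume(mask.astype(np.float32), out_dir / "brain_mask.nii")
    for name, m in truth.roi_masks.items():
        write_volume(m.astype(np.float32), out_dir / f"roi_{name}.nii")
    return manifest, truth
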