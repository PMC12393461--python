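"""Analysis configuration: every tunable of the pipeline in one place.

Defaults are the published analysis parameters of the dentate-gyrus
imaging/ephys workflow this package implements: Jia-style ΔF/F windows
(t1 = 3 s smoothing, t2 = 60 s baseline), 3 s.d. / 0.5 s.d. transient
bounds with a <5% duration-based false-positive criterion, 100 × 3 cm
spatial bins with σ = 3 bin Gaussian smoothing and 1,000 circular
shuffles, the 5-consecutive-bin + 25%-of-laps place-field rule, and the
5 ms / 15 ms synchronous/asynchronous release windows.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig", "parse_config", "ConfigError"]


class ConfigError(ValueError):
    """Raised for unknown keys, type mismatches or inconsistent values."""


@dataclass
class AnalysisConfig:
    # acquisition / track geometry
    frame_rate: float = 30.0          # Hz
    track_length: float = 300.0       # cm
    # ΔF/F baseline estimation
    t1_s: float = 3.0                 # boxcar smoothing window, s
    t2_s: float = 60.0                # rolling-minimum baseline window, s
    mask_sd: float = 2.0              # transient-masking threshold, s.d.
    n_mask_iters: int = 2             # mask/recompute passes
    # transient detection
    onset_sd: float = 3.0             # event opens above this many s.d.
    offset_sd: float = 0.5            # event closes below this many s.d.
    fpr_alpha: float = 0.05           # duration-conditional FPR cutoff
    noise_estimator: str = "excise"   # "excise" (iterative) or "mad"
    # spatial tuning
    n_bins: int = 100
    bin_cm: float = 3.0
    speed_thresh: float = 1.0         # cm/s running filter
    smooth_sigma_bins: float = 3.0    # Gaussian smoothing σ, bins
    n_shuffles: int = 1000
    min_shift_s: float = 10.0         # minimum circular-shuffle offset, s
    min_consec_bins: int = 5          # supra-null run length for tuning
    lap_frac: float = 0.25            # minimum lap reliability
    reliability_mode: str = "onset"   # transient-in-field rule (or any_frame)
    min_laps: int = 5                 # sessions need more laps than this
    # activity/velocity cross-correlation
    max_lag_s: float = 5.0
    velocity_smooth_s: float = 0.5    # uniform velocity smoothing window, s
    min_overlap_frames: int = 30      # shortest admissible overlap per shift
    # remapping
    no_change_tol: float = 0.01       # |Δ stability| band for "no change"
    split_half_mode: str = "contiguous"  # or "interleaved"
    # synaptic ephys
    n_pulses: int = 25
    pulse_rate_hz: float = 50.0
    sync_win_ms: float = 5.0
    async_win_ms: float = 15.0
    mipsc_scale_pa: float = 20.0
    n_smooth: int = 20                # Gaussian smoothing repetitions
    smooth_sigma_ms: float = 0.5      # σ per smoothing pass
    deconv_eps: float = 1e-3          # spectral regularization (0 = plain)
    failure_k: float = 3.0            # failure threshold, × baseline noise s.d.
    latency_onset_frac: float = 0.1   # IPSC onset at this fraction of peak
    # intrinsic ephys
    dvdt_thresh: float = 10.0         # mV/ms spike-threshold criterion
    sag_convention: str = "deflection"  # or "raw"
    sag_ss_ms: float = 100.0          # steady-state window at step end
    block_amp_frac: float = 0.5       # depolarization-block exclusion
    leak_frac: float = 0.3            # ramp leak-fit window (depolarized end)
    # reproducibility
    seed: int = 0

    _positive = (
        "frame_rate", "track_length", "t1_s", "t2_s", "mask_sd",
        "onset_sd", "offset_sd", "fpr_alpha", "bin_cm", "speed_thresh",
        "smooth_sigma_bins", "min_shift_s", "lap_frac", "max_lag_s",
        "velocity_smooth_s", "pulse_rate_hz", "sync_win_ms", "async_win_ms",
        "mipsc_scale_pa", "smooth_sigma_ms", "dvdt_thresh", "sag_ss_ms",
        "block_amp_frac", "leak_frac",
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in self._positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive, "
                                  f"got {getattr(self, name)!r}")
        for name in ("n_mask_iters", "n_bins", "n_shuffles",
                     "min_consec_bins", "n_pulses", "n_smooth"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if abs(self.n_bins * self.bin_cm - self.track_length) > 1e-9:
            raise ConfigError(
                f"n_bins * bin_cm = {self.n_bins * self.bin_cm} must equal "
                f"track_length = {self.track_length}")
        if self.noise_estimator not in ("excise", "mad"):
            raise ConfigError(f"unknown noise_estimator {self.noise_estimator!r}")
        if self.split_half_mode not in ("contiguous", "interleaved"):
            raise ConfigError(f"unknown split_half_mode {self.split_half_mode!r}")
        if self.sag_convention not in ("deflection", "raw"):
            raise ConfigError(f"unknown sag_convention {self.sag_convention!r}")
        if self.reliability_mode not in ("onset", "any_frame"):
            raise ConfigError(
                f"unknown reliability_mode {self.reliability_mode!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name: f for f in dataclasses.fields(cls)}
        unknown = [k for k in d if k not in known]
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        coerced = {}
        for k, v in d.items():
            typ = known[k].type
            try:
                if typ in ("float", float):
                    v = float(v)
                elif typ in ("int", int):
                    if isinstance(v, float) and v != int(v):
                        raise ValueError
                    v = int(v)
                elif typ in ("str", str):
                    if not isinstance(v, str):
                        raise ValueError
            except (TypeError, ValueError):
                raise ConfigError(f"config key {k!r}: cannot coerce {v!r} to {typ}")
            coerced[k] = v
        return cls(**coerced)


def parse_config(path: str | Path | None) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML/JSON key-value file.

    Unspecified keys take the published defaults; unknown keys are
    rejected by name.  ``None`` returns the defaults.
    """
    if path is None:
        return AnalysisConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text) if text.strip() else {}
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must hold a key-value mapping")
    return AnalysisConfig.from_dict(data)


def config_to_json(cfg: AnalysisConfig) -> str:
    return json.dumps(cfg.to_dict(), indent=2, sort_keys=True)
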