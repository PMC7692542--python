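"""Pipeline and generator configuration.

Defaults follow the measurement protocol: 30 Hz resampling, second-order
zero-phase Butterworth low-pass at 6 Hz for body streams, synchrony at 10 Hz
over non-overlapping 100-s windows with a 90% per-window validity rule, lag
grids of +-5 s (body) and +-1 s (face) in 0.1-s steps, a 70/30 train/test
partition with five-fold cross-validation, and SVM-RFE down to 23 features.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Unknown key or out-of-range value in a configuration file."""


def _rf_defaults() -> dict:
    return {
        "n_estimators": 500,
        "criterion": "entropy",
        "max_depth": 10,
        "max_features": 20,
        "min_samples_leaf": 7,
        "min_samples_split": 2,
        "bootstrap": True,
        "random_state": 30,
    }


def _mlp_defaults() -> dict:
    return {
        "hidden_layer_sizes": (50,),
        "activation": "logistic",
        "alpha": 0.03,
        "solver": "adam",
        "beta_1": 0.9,
        "beta_2": 0.999,
        "epsilon": 1e-8,
        "learning_rate": "constant",
        "learning_rate_init": 0.001,
        "max_iter": 200,
        "early_stopping": False,
        "shuffle": True,
        "tol": 1e-4,
        "n_iter_no_change": 10,
        "random_state": 30,
    }


@dataclass
class PipelineConfig:
    resample_rate_hz: float = 30.0
    filter_cutoff_hz: float = 6.0
    filter_order: int = 2
    filter_faces: bool = False
    max_gap_s: float = 0.2
    synchrony_rate_hz: float = 10.0
    window_s: float = 100.0
    body_max_lag_s: float = 5.0
    face_max_lag_s: float = 1.0
    lag_step_s: float = 0.1
    min_window_valid_fraction: float = 0.9
    min_overlap_samples: int = 50
    low_variance_threshold: float = 1e-4
    max_missing_feature_fraction: float = 0.5
    min_profile_items: int = 5
    train_fraction: float = 0.7
    cv_folds: int = 5
    rfe_target_k: int = 23
    group_by_dyad: bool = True
    seed: int = 0
    random_forest: dict = field(default_factory=_rf_defaults)
    mlp: dict = field(default_factory=_mlp_defaults)

    def __post_init__(self) -> None:
        for name in (
            "resample_rate_hz", "filter_cutoff_hz", "synchrony_rate_hz",
            "window_s", "body_max_lag_s", "face_max_lag_s", "lag_step_s",
            "max_gap_s",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0 < self.train_fraction < 1:
            raise ConfigError("train_fraction must lie strictly between 0 and 1")
        if not 0 < self.min_window_valid_fraction <= 1:
            raise ConfigError("min_window_valid_fraction must lie in (0, 1]")
        for max_lag in (self.body_max_lag_s, self.face_max_lag_s):
            steps = max_lag / self.lag_step_s
            if abs(steps - round(steps)) > 1e-9:
                raise ConfigError(
                    f"lag_step_s={self.lag_step_s} does not divide max lag {max_lag}"
                )
        if self.filter_cutoff_hz * 2 > self.resample_rate_hz:
            raise ConfigError("filter cutoff must be below the Nyquist rate")


@dataclass
class SynthConfig:
    """Generator settings for synthetic dyad sessions.

    ``coupling_alpha`` sets the shared fraction of the partners' movement
    drives, ``coupling_lag_s`` the lead of participant A over B, and
    ``attraction_effect_size`` the standardized shift of movement features
    between high- and low-attraction dyads.
    """

    duration_s: float = 300.0
    nominal_rate_hz: float = 30.0
    timestamp_jitter_sd_s: float = 0.004
    dropout_fraction: float = 0.03
    dropout_mean_run: float = 5.0
    coupling_alpha: float = 0.6
    coupling_lag_s: float = 0.3
    drive_bandwidth_hz: float = 1.0
    drive_baseline: float = 1.0
    drive_sd: float = 0.3
    displacement_scale_m: float = 0.004
    direction_drift: float = 0.25
    blendshape_event_rate_hz: float = 0.08
    blendshape_event_amplitude: float = 0.7
    blendshape_event_duration_s: float = 1.5
    blendshape_asymmetry_sd: float = 0.05
    head_pose_sd_deg: float = 6.0
    gaze_sd: float = 0.08
    attraction_effect_size: float = 0.0
    attraction_item_slope: float = 0.9
    attraction_item_noise_sd: float = 0.5
    bfi_observer_noise_sd: float = 0.8
    bfi_missing_prob: float = 0.05
    valence_attraction_slope: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.coupling_alpha <= 1:
            raise ConfigError("coupling_alpha must lie in [0, 1]")
        if self.duration_s <= 0 or self.nominal_rate_hz <= 0:
            raise ConfigError("duration and rate must be positive")
        if self.timestamp_jitter_sd_s >= 0.5 / self.nominal_rate_hz:
            raise ConfigError("timestamp jitter must stay below half the frame step")
        if not 0 <= self.dropout_fraction < 1:
            raise ConfigError("dropout_fraction must lie in [0, 1)")


_SECTIONS = {"random_forest", "mlp", "synthetic"}


def load_config(path: str | Path) -> tuple[PipelineConfig, SynthConfig]:
    """Read a YAML config; unspecified keys take the defaults above.

    Unknown keys are rejected rather than silently ignored, so a typo never
    silently reverts a setting to its default.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a key-value mapping")

    pipe_fields = {f.name for f in dataclasses.fields(PipelineConfig)}
    synth_fields = {f.name for f in dataclasses.fields(SynthConfig)}

    pipe_kwargs: dict = {}
    synth_kwargs: dict = {}
    for key, value in raw.items():
        if key == "synthetic":
            if not isinstance(value, dict):
                raise ConfigError("'synthetic' section must be a mapping")
            for skey, sval in value.items():
                if skey not in synth_fields:
                    raise ConfigError(f"unknown synthetic config key: {skey!r}")
                synth_kwargs[skey] = sval
        elif key in ("random_forest", "mlp"):
            if not isinstance(value, dict):
                raise ConfigError(f"'{key}' section must be a mapping")
            merged = (_rf_defaults() if key == "random_forest" else _mlp_defaults())
            for hkey, hval in value.items():
                if hkey not in merged:
                    raise ConfigError(f"unknown {key} hyperparameter: {hkey!r}")
                merged[hkey] = hval
            pipe_kwargs[key] = merged
        elif key in pipe_fields:
            pipe_kwargs[key] = value
        else:
            raise ConfigError(f"unknown config key: {key!r}")

    cfg = PipelineConfig(**pipe_kwargs)
    synth = SynthConfig(**synth_kwargs)
    log.info("effective config: %s", dataclasses.asdict(cfg))
    return cfg, synth


def config_as_dict(cfg: PipelineConfig, synth: SynthConfig | None = None) -> dict:
    out = dataclasses.asdict(cfg)
    if synth is not None:
        out["synthetic"] = dataclasses.asdict(synth)
    return out
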