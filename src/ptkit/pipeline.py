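"""End-to-end convenience: simulate -> detect -> evaluate in one call."""

from __future__ import annotations

from dataclasses import dataclass

from .config import PipelineConfig
from .detect import DetectionResult, detect_full
from .evaluate import EvaluationReport, match_events
from .io import ImuRecording
from .synthetic import GroundTruth, SimulationConfig, benchmark_config, simulate_session


@dataclass
class PipelineResult:
    recording: ImuRecording
    truth: GroundTruth
    detection: DetectionResult
    report: EvaluationReport


def run_pipeline(
    seed: int,
    config: PipelineConfig | None = None,
    sim_config: SimulationConfig | None = None,
) -> PipelineResult:
    """Simulate a benchmark session, run detection, evaluate against truth.

    Deterministic for a fixed seed and configuration.
    """
    cfg = config if config is not None else PipelineConfig()
    if sim_config is None:
        s = cfg.simulate
        sim_config = benchmark_config(
            seed,
            duration=s.duration_s,
            n_triplets=s.n_triplets,
            tilt_peak=s.tilt_peak,
            rise_height=s.rise_height,
            episode_duration=s.episode_duration_s,
            gyro_bias=tuple(s.gyro_bias),
            noise_accel=s.noise_accel,
            noise_gyro=s.noise_gyro,
        )
    rec, truth = simulate_session(sim_config)
    detection = detect_full(rec, cfg)
    report = match_events(
        detection.effective_events, truth.annotation, cfg.evaluate.tolerance_s
    )
    return PipelineResult(rec, truth, detection, report)
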