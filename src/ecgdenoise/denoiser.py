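"""End-to-end spectral denoising pipeline.

Training: noisy sequences are transformed to STFT magnitudes, merged into
8-frame context stacks and normalized with statistics fitted on the
training set; targets are the corresponding clean magnitude frames,
normalized with their own training statistics.  Inference reverses the
chain: noisy sequence -> STFT -> normalize with the *training* statistics
-> network -> denormalize -> clamp negatives to zero -> recombine with the
noisy sequence's own phase -> inverse STFT.

Frames not covered by a prediction (the first context_k - 1 frames for the
causal alignment, plus any tail for a centered one) fall back to the noisy
sequence's own magnitudes, so the output always has the input's length; the
evaluation protocol trims one second from each edge anyway.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ParameterError
from .model import RCEDConfig, TrainConfig, TrainedModel, build_rced, predict, train_rced
from .spectral import (
    NormStats,
    STFTConfig,
    apply_norm,
    fit_normalizer,
    invert_norm,
    istft,
    Spectrogram,
    stack_context,
    stft,
)

logger = logging.getLogger(__name__)


@dataclass
class DenoisingModel:
    """A trained R-CED bundled with everything inference needs."""

    trained: TrainedModel
    stft_config: STFTConfig
    context_k: int
    target_index: int
    norm_predictor: NormStats
    norm_target: NormStats


def min_input_length(cfg: STFTConfig, context_k: int) -> int:
    """Shortest sequence that yields at least one full context stack."""
    return cfg.n_fft + (context_k - 1) * cfg.hop


def build_training_set(
    clean_seqs: Sequence[np.ndarray],
    noisy_seqs: Sequence[np.ndarray],
    stft_config: STFTConfig,
    context_k: int = 8,
    target_index: int | None = None,
) -> tuple[np.ndarray, np.ndarray, NormStats, NormStats]:
    """Normalized (stacks, target frames) plus the fitted statistics."""
    if len(clean_seqs) != len(noisy_seqs) or not clean_seqs:
        raise ParameterError("need equally many (>=1) clean and noisy sequences")
    if target_index is None:
        target_index = context_k - 1
    noisy_mags, clean_frames = [], []
    for clean, noisy in zip(clean_seqs, noisy_seqs):
        if len(clean) != len(noisy):
            raise ParameterError("clean/noisy sequence length mismatch")
        noisy_mags.append(stft(noisy, stft_config).magnitudes)
        clean_frames.append(stft(clean, stft_config).magnitudes)
    norm_predictor = fit_normalizer(np.concatenate(noisy_mags, axis=0))
    norm_target = fit_normalizer(np.concatenate(clean_frames, axis=0))
    stacks, targets = [], []
    for nm, cm in zip(noisy_mags, clean_frames):
        fs_ = stack_context(apply_norm(nm, norm_predictor), context_k, target_index)
        stacks.append(fs_.stacks)
        idx = np.arange(fs_.stacks.shape[0]) + target_index
        targets.append(apply_norm(cm, norm_target)[idx])
    return (
        np.concatenate(stacks, axis=0),
        np.concatenate(targets, axis=0),
        norm_predictor,
        norm_target,
    )


def fit_denoiser(
    clean_seqs: Sequence[np.ndarray],
    noisy_seqs: Sequence[np.ndarray],
    stft_config: STFTConfig | None = None,
    rced_config: RCEDConfig | None = None,
    train_config: TrainConfig | None = None,
) -> DenoisingModel:
    """Train an R-CED denoiser on aligned clean/noisy sequence pairs."""
    stft_config = stft_config or STFTConfig()
    rced_config = rced_config or RCEDConfig()
    train_config = train_config or TrainConfig()
    k = rced_config.context_k
    target_index = k - 1  # causal: predict the most recent frame
    stacks, targets, norm_in, norm_out = build_training_set(
        clean_seqs, noisy_seqs, stft_config, k, target_index
    )
    network = build_rced(rced_config, seed=train_config.seed)
    trained = train_rced(network, stacks, targets, train_config, rced_config)
    return DenoisingModel(
        trained=trained,
        stft_config=stft_config,
        context_k=k,
        target_index=target_index,
        norm_predictor=norm_in,
        norm_target=norm_out,
    )


def denoise_sequence(model: DenoisingModel, noisy: np.ndarray) -> np.ndarray:
    """Denoise one sequence; output has exactly the input's length."""
    noisy = np.asarray(noisy, dtype=float)
    need = min_input_length(model.stft_config, model.context_k)
    if len(noisy) < need:
        raise ParameterError(
            f"sequence of {len(noisy)} samples too short; need at least {need}"
        )
    spec = stft(noisy, model.stft_config)
    mags, phases = spec.magnitudes, spec.phases
    normalized = apply_norm(mags, model.norm_predictor)
    fs_ = stack_context(normalized, model.context_k, model.target_index)
    predicted = predict(model.trained, fs_.stacks)
    denorm = invert_norm(predicted, model.norm_target)
    n_clamped = int(np.sum(denorm < 0))
    if n_clamped:
        logger.debug("clamped %d negative predicted magnitude bins to 0", n_clamped)
    denorm = np.maximum(denorm, 0.0)

    out_mags = mags.copy()  # uncovered frames keep their noisy magnitudes
    covered = np.arange(fs_.stacks.shape[0]) + model.target_index
    out_mags[covered] = denorm
    denoised_spec = Spectrogram(
        frames=out_mags * np.exp(1j * phases),
        config=model.stft_config,
        origin_length=spec.origin_length,
    )
    return istft(denoised_spec)


# ---------------------------------------------------------------------------
# checkpoint container: a NumPy .npz with a JSON header entry
# ---------------------------------------------------------------------------


def save_checkpoint(model: DenoisingModel, path: str | Path) -> None:
    """Single-file checkpoint: weights + configs + norm stats + history."""
    header = {
        "rced_config": {
            "n_blocks": model.trained.rced_config.n_blocks,
            "filter_counts": list(model.trained.rced_config.filter_counts),
            "kernel_widths": list(model.trained.rced_config.kernel_widths),
            "n_bins": model.trained.rced_config.n_bins,
            "context_k": model.trained.rced_config.context_k,
        },
        "stft_config": {
            "n_fft": model.stft_config.n_fft,
            "overlap": model.stft_config.overlap,
            "fs": model.stft_config.fs,
            "window_name": model.stft_config.window_name,
        },
        "context_k": model.context_k,
        "target_index": model.target_index,
        "history": model.trained.history,
    }
    arrays = {f"net.{k}": v for k, v in model.trained.network.state_dict().items()}
    arrays["norm_predictor.mean"] = model.norm_predictor.mean
    arrays["norm_predictor.sd"] = model.norm_predictor.sd
    arrays["norm_target.mean"] = model.norm_target.mean
    arrays["norm_target.sd"] = model.norm_target.sd
    arrays["header_json"] = np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> DenoisingModel:
    with np.load(path) as data:
        header = json.loads(bytes(data["header_json"]).decode())
        rc = RCEDConfig(
            n_blocks=header["rced_config"]["n_blocks"],
            filter_counts=tuple(header["rced_config"]["filter_counts"]),
            kernel_widths=tuple(header["rced_config"]["kernel_widths"]),
            n_bins=header["rced_config"]["n_bins"],
            context_k=header["rced_config"]["context_k"],
        )
        sc = STFTConfig(**header["stft_config"])
        network = build_rced(rc, seed=0)
        network.load_state_dict(
            {k[len("net.") :]: data[k] for k in data.files if k.startswith("net.")}
        )
        trained = TrainedModel(network=network, rced_config=rc, history=list(header["history"]))
        return DenoisingModel(
            trained=trained,
            stft_config=sc,
            context_k=header["context_k"],
            target_index=header["target_index"],
            norm_predictor=NormStats(
                mean=data["norm_predictor.mean"], sd=data["norm_predictor.sd"], fitted=True
            ),
            norm_target=NormStats(
                mean=data["norm_target.mean"], sd=data["norm_target.sd"], fitted=True
            ),
        )
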