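"""Calibration and test-time reconstruction orchestration, plus evaluation.

Calibration (unpaired fiber outputs + reference objects):
  register_stack -> per-pixel histograms -> pooled reference histogram ->
  LUTs -> LUT application + inpainting over the stack -> (optionally)
  Restore-CycleGAN training on the inpainted stack vs the references.

Test-time reconstruction of a single fiber output frame runs exactly four
steps: (1) align to the calibration reference frame, (2) per-pixel LUT
transform, (3) inpainting, (4) generator refinement (when a generator was
trained). Pixels with no observed data after the alignment shift are added to
the inpainting mask — the shift is known, so that region is known exactly.

Evaluation is MAE on the [0, 1] intensity scale against paired ground truth
(pairs exist only for evaluation; calibration never sees them). The
confidence metric is the Pearson correlation between the pre- and post-GAN
images.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from . import gan as restore_gan
from .gan import (CycleGANCheckpoint, GeneratorSpec, LossWeights, TrainConfig,
                  UNetGenerator, translate)
from .inpainting import inpaint
from .registration import (Translation, apply_translation,
                           estimate_translation, fill_mask, register_stack,
                           to_grayscale)
from .standardization import (LUTSet, accumulate_pixel_histograms,
                              apply_lut_set, build_lut_set,
                              pooled_reference_histogram)

__all__ = [
    "CalibrationSettings", "CalibrationBundle", "EvaluationReport",
    "calibrate", "reconstruct", "mae", "evaluate", "confidence",
    "save_bundle", "load_bundle",
]


@dataclass
class CalibrationSettings:
    max_shift: int = 10
    reference_index: int = 0
    inpaint_threshold: int = 10
    train_gan: bool = True
    train_config: TrainConfig = field(default_factory=TrainConfig)
    loss_weights: LossWeights = field(default_factory=LossWeights)


@dataclass
class EvaluationReport:
    per_image_mae: list[float]
    mean_mae: float
    std_mae: float
    n: int


@dataclass
class CalibrationBundle:
    """Everything needed to reconstruct a new fiber output frame."""

    reference_image: np.ndarray  # the calibration registration reference (RGB)
    reference_hash: str
    max_shift: int
    lut_set: LUTSet
    inpaint_threshold: int
    generator: UNetGenerator | None
    translations: list[tuple[int, int]]
    config_snapshot: dict

    @property
    def reference_gray(self) -> np.ndarray:
        return to_grayscale(self.reference_image)


def _content_hash(image: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(image).tobytes()).hexdigest()


def calibrate(fiber_outputs: np.ndarray, references: np.ndarray,
              settings: CalibrationSettings | None = None,
              verbose: bool = False) -> CalibrationBundle:
    """Run the full unsupervised calibration on two unpaired stacks."""
    settings = settings or CalibrationSettings()
    fiber_outputs = np.asarray(fiber_outputs)
    references = np.asarray(references)
    if fiber_outputs.ndim != 4 or len(fiber_outputs) == 0:
        raise ValueError("fiber_outputs must be a non-empty (N, H, W, 3) stack")
    if references.ndim != 4 or len(references) == 0:
        raise ValueError("references must be a non-empty (N, H, W, 3) stack")
    if fiber_outputs.shape[1:] != references.shape[1:]:
        raise ValueError("fiber outputs and references must share the image size")

    registered, translations = register_stack(
        fiber_outputs, settings.reference_index, settings.max_shift)
    histos = accumulate_pixel_histograms(registered)
    reference_dist = pooled_reference_histogram(references)
    lut_set = build_lut_set(histos, reference_dist)

    generator = None
    checkpoint: CycleGANCheckpoint | None = None
    if settings.train_gan:
        fuzzy = np.empty_like(registered)
        for i in range(len(registered)):
            standardized = apply_lut_set(registered[i], lut_set)
            fuzzy[i] = inpaint(standardized, settings.inpaint_threshold,
                               extra_mask=fill_mask(standardized.shape[:2],
                                                    translations[i]),
                               on_full_mask="zero")
        checkpoint = restore_gan.train(fuzzy, references,
                                       settings.train_config,
                                       settings.loss_weights, verbose=verbose)
        generator = checkpoint.g_xy

    reference_image = fiber_outputs[settings.reference_index].copy()
    snapshot = {
        "max_shift": settings.max_shift,
        "reference_index": settings.reference_index,
        "inpaint_threshold": settings.inpaint_threshold,
        "train_gan": settings.train_gan,
        "train_config": asdict(settings.train_config),
        "loss_weights": asdict(settings.loss_weights),
        "n_fiber_outputs": int(len(fiber_outputs)),
        "n_references": int(len(references)),
        "gan_history": checkpoint.history if checkpoint else None,
    }
    return CalibrationBundle(
        reference_image=reference_image,
        reference_hash=_content_hash(reference_image),
        max_shift=settings.max_shift,
        lut_set=lut_set,
        inpaint_threshold=settings.inpaint_threshold,
        generator=generator,
        translations=[t.as_tuple() for t in translations],
        config_snapshot=snapshot,
    )


def reconstruct(fiber_output: np.ndarray, bundle: CalibrationBundle,
                return_stages: bool = False):
    """Reconstruct one fiber output frame with the calibrated bundle.

    Returns the final image, or ``(final, stages)`` with the intermediate
    images (``registered``, ``standardized``, ``inpainted``, ``translation``)
    when ``return_stages`` is set — the inpainted (pre-GAN) stage feeds the
    confidence metric.
    """
    fiber_output = np.asarray(fiber_output)
    if fiber_output.shape != bundle.reference_image.shape:
        raise ValueError("fiber output size does not match the calibration bundle")
    t = estimate_translation(to_grayscale(fiber_output), bundle.reference_gray,
                             bundle.max_shift)
    registered = apply_translation(fiber_output, t)
    standardized = apply_lut_set(registered, bundle.lut_set)
    inpainted = inpaint(standardized, bundle.inpaint_threshold,
                        extra_mask=fill_mask(standardized.shape[:2], t),
                        on_full_mask="zero")
    final = translate(inpainted, bundle.generator) \
        if bundle.generator is not None else inpainted
    if return_stages:
        return final, {"translation": t, "registered": registered,
                       "standardized": standardized, "inpainted": inpainted}
    return final


def mae(reconstruction: np.ndarray, truth: np.ndarray) -> float:
    """Mean absolute error over all pixels/channels, intensities in [0, 1]."""
    reconstruction = np.asarray(reconstruction, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if reconstruction.shape != truth.shape:
        raise ValueError("images must have equal shapes")
    return float(np.mean(np.abs(reconstruction - truth)) / 255.0)


def evaluate(reconstructions: np.ndarray, truths: np.ndarray) -> EvaluationReport:
    """Per-image MAE list with its mean and (population) STD."""
    if len(reconstructions) != len(truths):
        raise ValueError("stacks must have equal lengths")
    maes = [mae(r, t) for r, t in zip(reconstructions, truths)]
    return EvaluationReport(per_image_mae=maes,
                            mean_mae=float(np.mean(maes)),
                            std_mae=float(np.std(maes)),
                            n=len(maes))


def confidence(pre_gan: np.ndarray, post_gan: np.ndarray) -> float:
    """Pearson correlation between pre- and post-GAN images, in [-1, 1].

    A constant input makes the correlation undefined; a warning is issued and
    NaN returned as the degenerate-correlation sentinel.
    """
    a = np.asarray(pre_gan, dtype=np.float64).ravel()
    b = np.asarray(post_gan, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError("images must have equal shapes")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("constant image: correlation undefined", RuntimeWarning,
                      stacklevel=2)
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


# --- bundle serialization -----------------------------------------------------

def save_bundle(bundle: CalibrationBundle, path) -> None:
    """Write a bundle as a directory: JSON manifest + npz array archives."""
    from pathlib import Path
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savez(path / "arrays.npz",
             reference_image=bundle.reference_image,
             lut=bundle.lut_set.lut,
             defective=bundle.lut_set.defective,
             translations=np.asarray(bundle.translations, dtype=np.int64))
    manifest = {
        "reference_hash": bundle.reference_hash,
        "max_shift": bundle.max_shift,
        "inpaint_threshold": bundle.inpaint_threshold,
        "thresholds": list(bundle.lut_set.thresholds),
        "n_frames": bundle.lut_set.n_frames,
        "config_snapshot": bundle.config_snapshot,
        "has_generator": bundle.generator is not None,
    }
    if bundle.generator is not None:
        gen = bundle.generator
        manifest["generator_spec"] = {
            "filter_schedule": list(gen.spec.filter_schedule),
            "input_size": gen.spec.input_size,
            "kernel_size": gen.spec.kernel_size,
            "stride": gen.spec.stride,
            "skip_connections": gen.spec.skip_connections,
        }
        params = {f"p{i}": p.data for i, p in enumerate(gen.parameters())}
        np.savez(path / "generator.npz", **params)
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_bundle(path) -> CalibrationBundle:
    from pathlib import Path
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    arrays = np.load(path / "arrays.npz")
    lut_set = LUTSet(lut=arrays["lut"], defective=arrays["defective"],
                     thresholds=tuple(manifest["thresholds"]),
                     n_frames=manifest["n_frames"])
    generator = None
    if manifest["has_generator"]:
        spec_dict = manifest["generator_spec"]
        spec = GeneratorSpec(
            filter_schedule=tuple(spec_dict["filter_schedule"]),
            input_size=spec_dict["input_size"],
            kernel_size=spec_dict["kernel_size"],
            stride=spec_dict["stride"],
            skip_connections=spec_dict["skip_connections"])
        generator = UNetGenerator(spec)
        params = np.load(path / "generator.npz")
        for i, p in enumerate(generator.parameters()):
            p.data = params[f"p{i}"].copy()
    return CalibrationBundle(
        reference_image=arrays["reference_image"],
        reference_hash=manifest["reference_hash"],
        max_shift=manifest["max_shift"],
        lut_set=lut_set,
        inpaint_threshold=manifest["inpaint_threshold"],
        generator=generator,
        translations=[tuple(t) for t in arrays["translations"].tolist()],
        config_snapshot=manifest["config_snapshot"],
    )
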